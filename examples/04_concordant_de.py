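"""Intersect two differential-expression contrasts by direction.

Simulates DE result tables for two knockouts with a planted co-regulated
subset (138 induced + 74 repressed by both factors), filters each at
FDR <= 0.05 and fold-change >= 2, and intersects them requiring the same
sign of change.
"""

from ribostate import SimulationConfig, concordant_intersect, filter_de, simulate_de

de = simulate_de(SimulationConfig(seed=1))
a = filter_de(de.table_a, fdr=0.05, fold=2.0)
b = filter_de(de.table_b, fdr=0.05, fold=2.0)
summary = concordant_intersect(a, b)

print(f"significant in contrast A: {summary.n_a} genes")
print(f"significant in contrast B: {summary.n_b} genes")
print(f"concordant (same direction in both): {summary.n_concordant} "
      f"= {summary.n_up} up + {summary.n_down} down")

# Concordant genes are candidates for direct co-regulation by both
# factors; discordant or single-contrast genes are dropped. With the KO-
# vs-WT sign convention, "down in both knockouts" means induced by both
# factors in wild-type cells.
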