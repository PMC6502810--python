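"""Check binder calls against an orthogonal CLIP peak set.

Simulates eCLIP-style peaks concentrated on the truly bound transcripts
and asks what fraction of called binders carry at least one peak within
their genomic span — the standard orthogonal-evidence check for a
RIP-derived binder list.
"""

from ribostate import (
    SimulationConfig,
    call_binders,
    clip_coverage,
    rip_enrichment,
    simulate_eclip,
    simulate_ripseq,
)

cfg = SimulationConfig(seed=1)
sim = simulate_ripseq(cfg)
results, _ = rip_enrichment(sim.counts, sim.transcripts)
binders = call_binders(results, cutoff=4.0)

peaks = simulate_eclip(cfg, sim.transcripts, sim.bound)
span = clip_coverage(binders, peaks, sim.transcripts, mode="span")
exonic = clip_coverage(binders, peaks, sim.transcripts, mode="exonic")

print(f"peaks simulated: {len(peaks)}")
print(f"binders with >= 1 peak in span:  {span.n_covered}/{span.n_queried} "
      f"({span.pct_covered}%)")
print(f"binders with >= 1 exonic peak:   {exonic.n_covered}/{exonic.n_queried} "
      f"({exonic.pct_covered}%)")

# Exonic coverage is necessarily a subset of span coverage; a high span
# percentage says the binder list is corroborated by the independent
# crosslinking assay.
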