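"""Classify translation-initiation shifts from polysome-fraction counts.

Simulates fraction-resolved RNA-seq (free / monosome / three polysome
fractions) for wild-type and knockout cells, in which 30% of transcripts
lose 75% of their ribosome-engaged mass to the free fraction in the
knockout. Transcripts whose pooled-poly/free ratio (TE) drops below half
its wild-type value are "group 1" (initiation-impaired); the chi-square
test asks whether group 1 is over-represented among bound transcripts.
"""

import numpy as np

from ribostate import (
    SimulationConfig,
    call_binders,
    classify_shifts,
    normalize_fractions,
    rip_enrichment,
    shift_enrichment,
    simulate_polysome,
    simulate_ripseq,
)

cfg = SimulationConfig(seed=1)
rip = simulate_ripseq(cfg)
results, _ = rip_enrichment(rip.counts, rip.transcripts)
binders = call_binders(results, cutoff=4.0)

poly = simulate_polysome(cfg, rip.bound)
wt = normalize_fractions(poly.wt_counts, cfg.scheme, genotype="WT")
ko = normalize_fractions(poly.ko_counts, cfg.scheme, genotype="KO")
calls = classify_shifts(wt, ko, cfg.scheme, threshold=0.5)

defined = [c for c in calls if c.defined]
enr = shift_enrichment(calls, binders.members & {c.transcript_id for c in defined})

shifted_calls = [c for c in defined if c.transcript_id in poly.shifted]
pm = np.median([c.poly_mono_ko / c.poly_mono_wt for c in shifted_calls])
te = np.median([c.te_ko / c.te_wt for c in shifted_calls])

print(f"group 1 globally:      {enr.pct_group1_global}% of {enr.n_global} mRNAs")
print(f"group 1 among binders: {enr.pct_group1_bound}% of {enr.n_bound} mRNAs")
print(f"chi-square = {enr.test.statistic:.1f}, p = {enr.test.p_value:.3g}")
print(f"shifted transcripts: median TE KO/WT = {te:.3f}, "
      f"median poly:mono KO/WT = {pm:.3f}")

# A tiny p-value says bound mRNAs shift far more often than chance. The
# poly:mono ratio staying near 1 while TE collapses is the signature of a
# block in initiation (fewer mRNAs engage ribosomes) rather than
# elongation (engaged mRNAs keep their ribosome load).
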