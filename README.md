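# ribostate

From RNA binding to translation state: a Python toolkit for the
quantitative analyses that connect an RNA-binding protein's target
repertoire (RIP-seq), its effect on translation initiation (polysome
profiling), orthogonal binding evidence (CLIP peaks) and transcriptional
co-regulation (differential-expression concordance).

The package is aimed at computational biologists who have transcript-level
count tables in hand (RIP IP/control libraries, ribosome-fraction
libraries, DE result tables) and want the downstream classification and
enrichment logic — binder calling, fraction percentages, translation-shift
grouping, set overlaps and the associated chi-square tests — as tested,
composable functions. It deliberately starts at counts: alignment,
counting, peak calling and DE model fitting are upstream tools' jobs.

## What it computes

**RIP-seq binder calling.** Counts are depth-corrected with size factors
*s_j* (median-of-ratios or per-million), length-normalized to adjusted
FPKM, and averaged over replicates within each role. A transcript is
called bound when

&nbsp;&nbsp;&nbsp;&nbsp;FE = (mean adjusted FPKM_IP + 1) / (mean adjusted FPKM_control + 1) > cutoff

with a strict cutoff (default 4) over the universe of detected
transcripts (mean adjusted FPKM ≥ 1 in either role).

**Polysome fraction analytics.** Each gradient fraction (free, 80S
monosome, polysome fractions) is its own sequencing library; after
per-fraction normalization and replicate averaging, every transcript gets
its percentage distribution across fractions, a translation-efficiency
proxy TE = pooled poly / free, and the elongation signature
poly/mono = pooled poly / monosome. A transcript is **group 1**
(initiation-impaired) when TE_KO < 0.5 · TE_WT, strictly; everything else
is group 2.

**Enrichment testing.** Whether group 1 is over-represented among bound
transcripts is a Pearson goodness-of-fit chi-square (df = 1, no
continuity correction) of the bound subset's group-1 count against the
global group-1 proportion.

**Set summaries.** Venn-style intersections of binder sets, transcriptome
shares, and CLIP-peak coverage (a transcript is covered when ≥ 1 peak
overlaps its span or exons by ≥ 1 bp, strand-aware, half-open
coordinates). Percentages are printed rounded to integers; exact counts
are always carried.

**DE concordance.** Two knockout-vs-wild-type DE tables are filtered at
FDR ≤ 0.05 and |log2FC| ≥ log2(2) (inclusive) and intersected requiring
the same sign of change.

**Synthetic data.** `ribostate.simulate` generates every input with
planted ground truth: negative-binomial RIP counts with a bound subset at
a stated fold, fraction-resolved counts in which a knockout moves part of
the engaged mass to the free fraction while preserving poly:mono,
CLIP peaks concentrated on bound transcripts, and DE tables with a
planted concordant subset. All generators are pure functions of their
config and seed.

## Worked example

The bundled demo simulates a full study (2000 transcripts, 100 planted
binders at 8-fold enrichment, 30% of transcripts with a planted
initiation block — binders 3× more likely to be blocked — and a planted
138 + 74 concordant DE subset) and runs every stage:

```sh
$ ribostate demo --seed 1
ribostate pipeline summary
  seed 1, effects on
  binders: 98 of 2000 detected transcripts at fold > 4 (5% of transcriptome); 109 at fold > 2
  recovery: sensitivity 0.980, FDR 0.000
  eCLIP: 94 of 98 binders with >= 1 peak (96%) from 869 peaks
  polysome: 30.1% of mRNAs group 1 (TE dropped > half in KO); 67% among binders (chi-square 64.6, p = 9.09e-16)
  concordant DE: 212 genes (138 up, 74 down) at FDR <= 0.05, fold >= 2
```

Reading the block: 98 of the 100 planted binders are recovered at the
4-fold cutoff with no false calls; the looser 2-fold cutoff can only add
members. 96% of called binders carry an orthogonal CLIP peak. The
knockout pushed 30.1% of mRNAs into group 1 globally but 67% of the
bound mRNAs — the chi-square against the global rate makes that
enrichment overwhelming (p ≈ 9e-16), the signature of the protein acting
directly on initiation of its targets. The DE intersection recovers the
planted 212-gene co-regulated set exactly.

`examples/` holds one short script per capability (binder calling, CLIP
coverage, polysome shifts, DE concordance, poly-C tract scanning); each
prints its numbers with a line of interpretation. The same stages are
available as subcommands (`ribostate simulate | rip-enrich | overlap |
clip-cov | polysome | concord | convert | demo`) for file-based use.

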