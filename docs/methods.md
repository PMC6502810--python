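# Methods

This note documents the models, conventions and design choices behind
`ribostate`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open on the genomic forward
strand. GTF (1-based closed) is converted on read and back on write; BED
passes through unchanged. Exons of a transcript are merged when
overlapping and sorted; transcript length is the summed exon length when
exons are available, otherwise an explicit length must be supplied —
there is no silent fallback. BED records without a strand column are
strand-agnostic: they match either strand even in strand-matched
coverage mode, since public peak sets are not always stranded. Readers
reject malformed input (negative or non-integer counts, start ≥ end,
mixed-strand transcripts) with the offending line or cell named, rather
than clamping.

In sequence utilities U and T are interchangeable and N never matches C;
the poly-C scanner returns maximal, disjoint, left-to-right runs.

## RIP-seq enrichment model

The adjusted FPKM of transcript *t* in sample *j* is

    (count_tj / s_j) * 1e9 / (length_t * libsize_j)

with *s_j* a size factor (median-of-ratios by default; per-million as an
alternative) and libsize_j the raw column total. "Adjusted" therefore
means depth-bias-corrected FPKM: with equal-depth libraries the size
factors absorb composition shifts (an IP library in which bound
transcripts soak up reads deflates every unbound transcript; the
median ratio estimates exactly that deflation). Replicates are averaged
on the FPKM scale, not the log scale.

Fold enrichment is the ratio of pseudocounted role means,
(mean_IP + 1)/(mean_control + 1). The pseudocount (default 1, in
adjusted-FPKM units) stabilizes ratios at low expression and matches the
"+1" of the conventional log2(FPKM + 1) display scale. A transcript is
*detected* when either role mean reaches the detection floor (default
adjusted FPKM ≥ 1); detection defines the binder-calling universe and
the denominator of transcriptome-share percentages. The floor is a
pragmatic noise gate, exposed in `NormalizationConfig`. Binder calls use
a strict inequality (fold > cutoff), so a transcript at exactly the
cutoff is not bound; lowering the cutoff can only grow the set.

No per-transcript statistical test is attempted: the method is a fold
cutoff, and replicate noise enters through the averaged means.

## Polysome fraction analytics

A `FractionScheme` lists the ordered gradient fractions and maps each to
a class: `free`, `mono` (the 80S fraction), or `poly`. The default
scheme is free / mono / poly1–3 with all poly fractions pooled by
summation. If a gradient includes 40S/60S fractions they should be
mapped to `free` (no ribosome-engaged mRNA), which the scheme makes
explicit rather than hard-coding.

Each fraction sample is treated as its own library: per-sample
normalization (per-million by default), replicate means per fraction,
then per-transcript percentages across fractions (summing to 100
whenever the transcript is seen at all). Pooled ratios add a pseudocount
of 1e-6 of the transcript's total to the denominator, so an empty free
fraction yields a large finite TE instead of infinity; a transcript with
zero total in a genotype has no defined ratios and its shift call is
withheld with a reason code (`zero_total_wt`/`zero_total_ko`) and
excluded from enrichment counts.

Group 1 is TE_KO < threshold · TE_WT with threshold 0.5 and strict
inequality — "decreased by more than half" — so boundary equality is
group 2, and raising the threshold toward 1 can only grow group 1.
Because TE is a ratio of sums, calls are invariant under rescaling
either genotype's profile.

Without spike-ins, per-fraction normalization measures *within-fraction
composition*, and a genotype that moves many transcripts into the free
fraction rescales every transcript's apparent fraction profile. The
effect in practice is conservative for the shift classification
(unshifted transcripts' apparent TE rises slightly in the knockout,
pushing them away from the group-1 boundary) and cancels in the
poly/mono ratio (both engaged libraries shrink by the same factor).
Spike-in normalization, which would remove the effect entirely, is out
of scope; the TE-recovery test quantifies the residual bias against the
planted truth.

## Enrichment test

`goodness_of_fit_chisq((k, n), p)` is the Pearson chi-square of the
two-class count (k, n − k) against expected (np, n(1 − p)), df = 1, no
continuity correction, upper-tail p-value. It is used with p = the
global group-1 proportion and (k, n) = the bound subset's group-1 count,
i.e. "is the bound subset's rate what the transcriptome-wide rate
predicts". A 2×2 contingency test would model the joint table instead;
the one-sample form matches the "expected percentage from global mRNAs"
framing and is what the package reports. If the global rate is
degenerate (0 or 1) and the bound subset matches it, the test reports
statistic 0 and p = 1 rather than failing, which keeps null pipelines
runnable.

## DE concordance

Tables are knockout-vs-wild-type (positive log2FC = up in knockout);
the sign convention is part of the contract so that "induced by the
factor" (down in KO) cannot silently flip. Filters are inclusive
(padj ≤ FDR, |log2FC| ≥ log2(fold)); ambiguity at the boundary is
resolved toward inclusion. The concordant set requires significance in
both contrasts and matching sign, and always partitions exactly into up
+ down.

## Synthetic-data generators

The generators emulate the statistical structure each stage assumes, not
any particular dataset:

* **RIP-seq**: baseline means lognormal (median ≈ base_mean·e^{−σ²/2},
  σ = 1 — a realistic several-decade expression range), counts negative
  binomial with dispersion 0.1 (Var = μ + 0.1μ², typical for biological
  replicates), 3 replicates per role, 2000 transcripts with 100 bound at
  8-fold. Every library's expected depth is fixed (base_mean·n reads),
  so counts measure composition and size factors must undo the
  IP-library composition bias — as in real sequencing.
* **Polysome**: per-transcript fraction proportions are Dirichlet around
  uniform class means (concentration 50), drawn once and shared between
  genotypes so unshifted transcripts differ only by counting noise. The
  initiation block moves shift_strength = 0.75 of the *engaged*
  (mono + poly) mass to the free fraction, scaling mono and poly by the
  same factor — poly:mono is preserved exactly by construction, which is
  the mechanistic signature separating an initiation block from an
  elongation defect. 30% of transcripts are shifted, with bound
  transcripts weighted 3× in the shifted draw. The planted mass and
  proportions are returned as truth so tests can compute exact expected
  values.
* **eCLIP**: Poisson peak counts (rates 3.0 bound / 0.3 unbound), peaks
  30–80 bp inside the span on the transcript's strand, 70% of them
  starting in the 3'-most 30% of the span (the UTR-like end,
  strand-aware).
* **DE**: the planted concordant genes (defaults 138 up + 74 down) pass
  both filters with matching signs; every decoy fails exactly one
  condition (FDR in one contrast, fold in one contrast, discordant
  signs, or significant in neither), so recovery is exact by
  construction and the interesting check is that the filters' boundary
  behavior matches the generator's.

What the generators do *not* emulate: GC/length biases, overdispersion
heterogeneity across transcripts, correlated replicates, multimapping
artifacts, partial ribosome run-off, or any real fraction-boundary
blurring. Passing recovery tests therefore demonstrates that the
analysis logic is correct under its stated model, not that the model
captures every failure mode of real libraries.

## Problem sizes and numerical choices

The default simulations (2000 transcripts × 6–30 libraries, 3000 genes)
keep the full test suite under ~10 seconds and the acceptance script
under ~5 while leaving the recovery margins wide (binder recall ≥ 0.95,
null false-positive rates at 0). Percentages are reported rounded half
away from zero, matching how such figures are conventionally printed;
exact counts and full-precision values are retained in every summary
object. All randomness flows through `numpy.random.default_rng` seeded
from the config; sub-generators use fixed small offsets of the seed so
stages are independently reproducible.

## Known limitations

* The fold-enrichment caller has no per-transcript error model; weakly
  expressed transcripts rely on the pseudocount and detection floor.
* Per-fraction normalization is compositional (see above); absolute
  translation-efficiency changes are not identifiable without spike-ins.
* CLIP coverage is binary (≥ 1 bp of ≥ 1 peak); no peak-strength
  weighting or minimum-overlap fraction is applied by default.
* The chi-square enrichment test treats transcripts as independent;
  co-regulated transcript families violate that assumption in real data.
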