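"""Set algebra over binder sets, CLIP-peak coverage, and the chi-square
goodness-of-fit test used for gene-set enrichment summaries.

Percentages are reported rounded to the nearest integer (half away from
zero), matching how such overlaps are conventionally printed; the exact
counts are always carried alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from intervaltree import IntervalTree
from scipy import stats

from ribostate.annotations import IntervalSet, TranscriptTable
from ribostate.ripseq import BinderSet

CoverageMode = Literal["span", "exonic"]
StrandMode = Literal["matched", "ignore"]


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (90.5 -> 91)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class OverlapSummary:
    """Venn-style summary of two transcript sets from a shared universe."""

    size_a: int
    size_b: int
    size_intersection: int
    pct_of_a: int
    pct_of_b: int
    universe_size: int


@dataclass(frozen=True)
class CoverageSummary:
    """How many queried transcripts carry >= 1 overlapping peak."""

    n_queried: int
    n_covered: int
    pct_covered: int
    mode: CoverageMode
    strand_mode: StrandMode


@dataclass(frozen=True)
class EnrichmentTestResult:
    """Pearson goodness-of-fit result for a two-class count."""

    observed: tuple[int, int]
    expected: tuple[float, float]
    statistic: float
    df: int
    p_value: float


def intersect_binders(a: BinderSet, b: BinderSet) -> OverlapSummary:
    """Exact intersection of two binder sets with rounded percentages.

    Percentages are of each parent set (e.g. shared/|a|); an empty parent
    set makes them undefined and is an error.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("overlap percentage undefined for an empty binder set")
    shared = a.members & b.members
    universe = max(a.universe_size, b.universe_size)
    return OverlapSummary(
        size_a=len(a),
        size_b=len(b),
        size_intersection=len(shared),
        pct_of_a=round_half_away(100.0 * len(shared) / len(a)),
        pct_of_b=round_half_away(100.0 * len(shared) / len(b)),
        universe_size=universe,
    )


def transcriptome_fraction(binders: BinderSet) -> int:
    """Share of the detected transcriptome in the set, as a rounded percent."""
    return round_half_away(100.0 * len(binders) / binders.universe_size)


def _build_trees(peaks: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for peak in peaks:
        trees.setdefault(peak.chrom, IntervalTree()).addi(
            peak.start, peak.end, peak.strand
        )
    return trees


def clip_coverage(
    query: BinderSet,
    peaks: IntervalSet,
    transcripts: TranscriptTable,
    mode: CoverageMode = "span",
    strand_mode: StrandMode = "matched",
) -> CoverageSummary:
    """Count query transcripts with at least one overlapping CLIP peak.

    A transcript is covered when >= 1 peak overlaps its genomic span
    (``mode="span"``) or any exon (``mode="exonic"``) by >= 1 bp, with
    half-open semantics (a peak abutting the span end does not overlap).
    With ``strand_mode="matched"``, a stranded peak must lie on the
    transcript's strand; strand-agnostic peaks (``.``) match either.
    """
    if mode not in ("span", "exonic"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    if strand_mode not in ("matched", "ignore"):
        raise ValueError(f"unknown strand mode {strand_mode!r}")
    missing = [t for t in query.members if t not in transcripts]
    if missing:
        raise KeyError(f"query transcripts without coordinates: {sorted(missing)[:5]}")
    trees = _build_trees(peaks)
    n_covered = 0
    for tid in query.members:
        rec = transcripts[tid]
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        windows = (
            rec.exons
            if mode == "exonic" and rec.exons
            else ((rec.span_start, rec.span_end),)
        )
        hit = False
        for start, end in windows:
            for iv in tree.overlap(start, end):
                if (
                    strand_mode == "ignore"
                    or iv.data == "."
                    or iv.data == rec.strand
                ):
                    hit = True
                    break
            if hit:
                break
        n_covered += hit
    n_queried = len(query.members)
    return CoverageSummary(
        n_queried=n_queried,
        n_covered=n_covered,
        pct_covered=round_half_away(100.0 * n_covered / n_queried)
        if n_queried
        else 0,
        mode=mode,
        strand_mode=strand_mode,
    )


def goodness_of_fit_chisq(
    observed: tuple[int, int], expected_proportion: float
) -> EnrichmentTestResult:
    """Pearson chi-square of an observed two-class count (k out of n)
    against an expected proportion, df = 1, no continuity correction.

    This is the test behind "is the bound subset's rate different from
    the global rate": expected counts are (n*p, n*(1-p)) and the p-value
    is the upper tail of chi-square with one degree of freedom.
    """
    k, n = observed
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    p = expected_proportion
    if not 0.0 < p < 1.0:
        raise ValueError("expected_proportion must be in (0, 1)")
    expected = (n * p, n * (1.0 - p))
    if min(expected) == 0:
        raise ValueError("expected count of zero: test undefined")
    statistic, p_value = stats.chisquare(f_obs=[k, n - k], f_exp=list(expected))
    return EnrichmentTestResult(
        observed=(k, n - k),
        expected=expected,
        statistic=float(statistic),
        df=1,
        p_value=float(p_value),
    )
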