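"""Polysome-profiling fraction analytics and translation-shift calls.

A sucrose gradient separates mRNA by ribosome load into free, monosome
(80S) and polysome fractions. For each transcript we compute its
percentage distribution across fractions, the pooled poly/free ratio
(the translation-efficiency proxy, TE) and the pooled poly/mono ratio
(the elongation signature). A transcript whose TE drops below half of
its wild-type value in the knockout is a "group 1" (initiation-impaired)
transcript; everything else is group 2. Enrichment of group 1 inside a
binder set is tested with the chi-square goodness of fit against the
global group-1 rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ribostate.annotations import CountMatrix
from ribostate.overlap import EnrichmentTestResult, goodness_of_fit_chisq, round_half_away
from ribostate.ripseq import BinderSet, SizeFactorMethod, size_factors

FractionClass = Literal["free", "mono", "poly"]


@dataclass(frozen=True)
class FractionScheme:
    """Ordered gradient fractions and their free/mono/poly classes.

    The pooling rule is fixed: the poly signal of a transcript is the sum
    over all poly-class fractions (likewise mono and free, which usually
    have one fraction each).
    """

    labels: tuple[str, ...]
    classes: Mapping[str, FractionClass]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate fraction labels")
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"fractions without a class: {sorted(unknown)}")
        bad = {c for c in self.classes.values() if c not in ("free", "mono", "poly")}
        if bad:
            raise ValueError(f"unknown fraction classes: {sorted(bad)}")
        for cls in ("free", "mono", "poly"):
            if not any(self.classes[l] == cls for l in self.labels):
                raise ValueError(f"scheme has no {cls!r} fraction")

    def labels_of(self, cls: FractionClass) -> list[str]:
        return [l for l in self.labels if self.classes[l] == cls]


def default_scheme() -> FractionScheme:
    """Free + 80S monosome + three pooled polysome fractions."""
    labels = ("free", "mono", "poly1", "poly2", "poly3")
    classes = {
        "free": "free",
        "mono": "mono",
        "poly1": "poly",
        "poly2": "poly",
        "poly3": "poly",
    }
    return FractionScheme(labels=labels, classes=classes)


@dataclass(frozen=True)
class FractionProfile:
    """Normalized per-fraction abundance of one transcript in one genotype.

    ``percentages`` is the share of the transcript's total in each
    fraction; it sums to 100 whenever the total is positive.
    """

    transcript_id: str
    genotype: str
    abundance: Mapping[str, float]
    percentages: Mapping[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.abundance.values()))


class PooledRatios(NamedTuple):
    te: float  # pooled poly / free
    poly_mono: float  # pooled poly / mono


@dataclass(frozen=True)
class ShiftCall:
    """Translation-initiation shift call for one transcript (KO vs WT).

    ``group`` is 1 when te_ko < threshold * te_wt (strictly), 2 otherwise,
    and None when a TE was undefined (zero total abundance), in which case
    ``reason`` says why the call was withheld.
    """

    transcript_id: str
    te_wt: float | None
    te_ko: float | None
    poly_mono_wt: float | None
    poly_mono_ko: float | None
    group: int | None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.group is not None


class UndefinedRatioError(ValueError):
    """Pooled ratios are undefined (transcript absent from the gradient)."""


def normalize_fractions(
    counts: CountMatrix,
    scheme: FractionScheme,
    genotype: str = "WT",
    method: SizeFactorMethod = "per_million",
) -> dict[str, FractionProfile]:
    """Fraction-resolved profiles from a per-genotype count matrix.

    Every sample must carry a ``fraction:<label>`` role with the label in
    the scheme. Each fraction sample is treated as its own library: size
    factors are computed per sample, replicate means are taken per
    fraction, and percentages are the per-transcript share across
    fractions.
    """
    labels_in_data = counts.fraction_labels()
    if not labels_in_data:
        raise ValueError("count matrix has no fraction:<label> samples")
    unknown = set(labels_in_data) - set(scheme.labels)
    if unknown:
        raise ValueError(f"fractions absent from scheme: {sorted(unknown)}")
    missing = set(scheme.labels) - set(labels_in_data)
    if missing:
        raise ValueError(f"scheme fractions absent from data: {sorted(missing)}")
    non_fraction = [
        s for s, role in counts.samples if not role.startswith("fraction:")
    ]
    if non_fraction:
        raise ValueError(f"non-fraction samples in polysome matrix: {non_fraction}")

    factors = size_factors(counts, method)
    normed = counts.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    normed = pd.DataFrame(normed, index=counts.counts.index, columns=counts.counts.columns)

    per_fraction = pd.DataFrame(
        {
            label: normed[
                [s for s, role in counts.samples if role == f"fraction:{label}"]
            ].mean(axis=1)
            for label in scheme.labels
        }
    )
    totals = per_fraction.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = per_fraction.div(totals, axis=0) * 100.0
    pct[totals == 0] = 0.0

    profiles: dict[str, FractionProfile] = {}
    for tid in per_fraction.index:
        profiles[tid] = FractionProfile(
            transcript_id=tid,
            genotype=genotype,
            abundance={l: float(per_fraction.at[tid, l]) for l in scheme.labels},
            percentages={l: float(pct.at[tid, l]) for l in scheme.labels},
        )
    return profiles


def pooled_ratios(
    profile: FractionProfile,
    scheme: FractionScheme,
    epsilon_fraction: float = 1e-6,
) -> PooledRatios:
    """TE (pooled poly/free) and pooled poly/mono ratios of one profile.

    A pseudocount of ``epsilon_fraction`` of the transcript's total is
    added to each denominator so that an empty fraction yields a large
    finite ratio rather than infinity. A transcript with zero total
    abundance has no defined ratios and raises
    :class:`UndefinedRatioError`.
    """
    missing = set(scheme.labels) - set(profile.abundance)
    if missing:
        raise ValueError(f"profile missing scheme fractions: {sorted(missing)}")
    total = profile.total
    if total <= 0:
        raise UndefinedRatioError(
            f"{profile.transcript_id}: zero total abundance across fractions"
        )
    eps = epsilon_fraction * total
    free = sum(profile.abundance[l] for l in scheme.labels_of("free"))
    mono = sum(profile.abundance[l] for l in scheme.labels_of("mono"))
    poly = sum(profile.abundance[l] for l in scheme.labels_of("poly"))
    return PooledRatios(te=poly / (free + eps), poly_mono=poly / (mono + eps))


def classify_shift(
    wt: FractionProfile,
    ko: FractionProfile,
    scheme: FractionScheme,
    threshold: float = 0.5,
) -> ShiftCall:
    """Group-1/group-2 call for one transcript from its WT and KO profiles.

    Group 1 means the poly/free ratio dropped strictly below
    ``threshold`` times its WT value in the knockout — the signature of
    blocked initiation. Ratios are scale-free, so profiles need not share
    normalization. An undefined TE in either genotype withholds the call.
    """
    if wt.transcript_id != ko.transcript_id:
        raise ValueError(
            f"profile mismatch: {wt.transcript_id} vs {ko.transcript_id}"
        )
    if not 0 < threshold:
        raise ValueError("threshold must be > 0")
    try:
        ratios_wt = pooled_ratios(wt, scheme)
    except UndefinedRatioError:
        return ShiftCall(wt.transcript_id, None, None, None, None, None,
                         reason="zero_total_wt")
    try:
        ratios_ko = pooled_ratios(ko, scheme)
    except UndefinedRatioError:
        return ShiftCall(wt.transcript_id, ratios_wt.te, None,
                         ratios_wt.poly_mono, None, None,
                         reason="zero_total_ko")
    group = 1 if ratios_ko.te < threshold * ratios_wt.te else 2
    return ShiftCall(
        transcript_id=wt.transcript_id,
        te_wt=ratios_wt.te,
        te_ko=ratios_ko.te,
        poly_mono_wt=ratios_wt.poly_mono,
        poly_mono_ko=ratios_ko.poly_mono,
        group=group,
    )


def classify_shifts(
    wt_profiles: Mapping[str, FractionProfile],
    ko_profiles: Mapping[str, FractionProfile],
    scheme: FractionScheme,
    threshold: float = 0.5,
) -> list[ShiftCall]:
    """Shift calls for every transcript present in both genotypes."""
    shared = [t for t in wt_profiles if t in ko_profiles]
    return [
        classify_shift(wt_profiles[t], ko_profiles[t], scheme, threshold)
        for t in shared
    ]


@dataclass(frozen=True)
class ShiftEnrichmentSummary:
    """Group-1 rates globally and within the bound subset, plus the test."""

    n_global: int
    n_group1_global: int
    pct_group1_global: int
    n_bound: int
    n_group1_bound: int
    pct_group1_bound: int
    test: EnrichmentTestResult


def shift_enrichment(
    calls: Sequence[ShiftCall], bound: BinderSet | Iterable[str]
) -> ShiftEnrichmentSummary:
    """Is group 1 over-represented among bound transcripts?

    The global group-1 proportion (over all defined calls) is the
    expected value; the observed count is group-1 calls among the bound
    transcripts, tested with the chi-square goodness of fit. When the
    global rate is degenerate (0 or 1) and the bound subset matches it,
    the test is reported as a zero statistic with p = 1.
    """
    members = bound.members if isinstance(bound, BinderSet) else frozenset(bound)
    defined = [c for c in calls if c.defined]
    if not defined:
        raise ValueError("no defined shift calls")
    by_id = {c.transcript_id: c for c in defined}
    missing = members - set(by_id)
    if missing:
        raise ValueError(
            f"bound transcripts without a shift call: {sorted(missing)[:5]}"
        )
    if not members:
        raise ValueError("empty bound set")
    n_global = len(defined)
    k_global = sum(c.group == 1 for c in defined)
    bound_calls = [by_id[t] for t in members]
    n_bound = len(bound_calls)
    k_bound = sum(c.group == 1 for c in bound_calls)
    p_global = k_global / n_global
    if p_global in (0.0, 1.0):
        if k_bound == round(p_global * n_bound):
            test = EnrichmentTestResult(
                observed=(k_bound, n_bound - k_bound),
                expected=(p_global * n_bound, (1 - p_global) * n_bound),
                statistic=0.0,
                df=1,
                p_value=1.0,
            )
        else:
            raise ValueError(
                "degenerate global group-1 rate with a deviating bound subset"
            )
    else:
        test = goodness_of_fit_chisq((k_bound, n_bound), p_global)
    return ShiftEnrichmentSummary(
        n_global=n_global,
        n_group1_global=k_global,
        pct_group1_global=round_half_away(100.0 * k_global / n_global),
        n_bound=n_bound,
        n_group1_bound=k_bound,
        pct_group1_bound=round_half_away(100.0 * k_bound / n_bound),
        test=test,
    )


def calls_frame(calls: Iterable[ShiftCall]) -> pd.DataFrame:
    """Tabular view of shift calls (one row per transcript)."""
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "te_wt": c.te_wt,
                "te_ko": c.te_ko,
                "poly_mono_wt": c.poly_mono_wt,
                "poly_mono_ko": c.poly_mono_ko,
                "group": c.group,
                "reason": c.reason,
            }
            for c in calls
        ]
    ).set_index("transcript_id")
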