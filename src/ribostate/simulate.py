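"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the statistical structure each analysis assumes:

* RIP-seq: negative-binomial counts over lognormal baseline means, with
  a planted bound subset whose IP mean is multiplied by a stated fold.
* Polysome profiling: per-transcript mass split across gradient
  fractions (Dirichlet around class means); the knockout moves part of
  the ribosome-engaged mass of a planted subset into the free fraction
  while preserving the poly:mono balance of what stays engaged — the
  signature of a translation-initiation block (elongation untouched).
* eCLIP: Poisson peak counts per transcript, concentrated on bound
  transcripts and biased toward the 3' end of the span.
* Differential expression: two contrasts with a planted
  direction-concordant subset and decoys that each fail exactly one
  filter.

Every generator is a pure function of its config (seed included): the
same config yields byte-identical outputs. Truth sets are returned
alongside the data and are meant for assertions only, never as pipeline
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from ribostate.annotations import (
    CountMatrix,
    GenomicInterval,
    IntervalSet,
    TranscriptRecord,
    TranscriptTable,
)
from ribostate.polysome import FractionScheme, default_scheme


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs of all generators; defaults are the study conditions.

    ``bound_fold`` is the planted IP enrichment of bound transcripts;
    ``shift_strength`` is the share of ribosome-engaged (mono+poly) mass
    the knockout moves to the free fraction for shifted transcripts;
    ``binder_shift_multiplier`` makes bound transcripts that much more
    likely to be shifted; ``de_concordant`` plants (n_up, n_down)
    same-direction significant genes in both DE contrasts.
    """

    seed: int = 0
    n_transcripts: int = 2000
    n_bound: int = 100
    bound_fold: float = 8.0
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    base_mean: float = 200.0
    base_sigma: float = 1.0
    scheme: FractionScheme = field(default_factory=default_scheme)
    fraction_concentration: float = 50.0
    shift_fraction: float = 0.3
    shift_strength: float = 0.75
    binder_shift_multiplier: float = 3.0
    n_genes: int = 3000
    de_concordant: tuple[int, int] = (138, 74)
    peak_rate_bound: float = 3.0
    peak_rate_unbound: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.n_bound <= self.n_transcripts:
            raise ValueError("n_bound must be in [0, n_transcripts]")
        if self.bound_fold <= 0 or self.nb_dispersion <= 0:
            raise ValueError("bound_fold and nb_dispersion must be > 0")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate per role")
        if not 0.0 <= self.shift_fraction <= 1.0:
            raise ValueError("shift_fraction must be in [0, 1]")
        if not 0.0 <= self.shift_strength <= 1.0:
            raise ValueError("shift_strength must be in [0, 1]")
        if self.binder_shift_multiplier < 1.0:
            raise ValueError("binder_shift_multiplier must be >= 1")
        if self.peak_rate_bound < 0 or self.peak_rate_unbound < 0:
            raise ValueError("peak rates must be >= 0")
        if sum(self.de_concordant) > self.n_genes:
            raise ValueError("planted concordant genes exceed n_genes")


def _transcript_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"t{i:0{width}d}" for i in range(1, n + 1)]


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _synthetic_annotation(
    rng: np.random.Generator, ids: list[str]
) -> TranscriptTable:
    """Lay transcripts along synthetic chromosomes with 1-3 exons each."""
    records = []
    cursor: dict[str, int] = {}
    for i, tid in enumerate(ids):
        chrom = f"chr{(i % 4) + 1}"
        length = int(rng.integers(500, 5001))
        n_exons = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1,
                                  replace=False)) if n_exons > 1 else np.array([], dtype=int)
        exon_lengths = np.diff(np.concatenate(([0], cuts, [length])))
        start = cursor.get(chrom, 1000)
        exons = []
        pos = start
        for exon_len in exon_lengths:
            exons.append((pos, pos + int(exon_len)))
            pos += int(exon_len) + int(rng.integers(100, 1001))  # intron gap
        span_end = exons[-1][1]
        cursor[chrom] = span_end + 1000
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=tid.replace("t", "g", 1),
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                span_start=start,
                span_end=span_end,
                exons=tuple(exons),
            )
        )
    return TranscriptTable(records)


class RipSim(NamedTuple):
    counts: CountMatrix
    transcripts: TranscriptTable
    bound: frozenset[str]


def simulate_ripseq(config: SimulationConfig) -> RipSim:
    """RIP-seq IP/control counts with a planted bound subset.

    Baseline means are lognormal; IP samples multiply the means of the
    ``n_bound`` planted transcripts by ``bound_fold``. Counts are
    negative binomial with the configured dispersion; fully reproducible
    from the seed.
    """
    rng = np.random.default_rng(config.seed)
    ids = _transcript_ids(config.n_transcripts)
    transcripts = _synthetic_annotation(rng, ids)
    mu = config.base_mean * rng.lognormal(
        mean=-0.5 * config.base_sigma**2, sigma=config.base_sigma,
        size=config.n_transcripts,
    )
    bound_idx = rng.choice(config.n_transcripts, size=config.n_bound, replace=False)
    bound = frozenset(ids[i] for i in bound_idx)
    ip_mu = mu.copy()
    ip_mu[bound_idx] *= config.bound_fold

    # each library is sequenced to the same expected depth: counts measure
    # composition, and size factors must undo the resulting bias (as in
    # real sequencing)
    depth = config.base_mean * config.n_transcripts
    ip_mu *= depth / ip_mu.sum()
    control_mu = mu * (depth / mu.sum())

    columns: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    for rep in range(1, config.n_replicates + 1):
        columns[f"ip_{rep}"] = _nb_counts(rng, ip_mu, config.nb_dispersion)
        roles[f"ip_{rep}"] = "ip"
    for rep in range(1, config.n_replicates + 1):
        columns[f"control_{rep}"] = _nb_counts(rng, control_mu, config.nb_dispersion)
        roles[f"control_{rep}"] = "control"
    counts = CountMatrix(pd.DataFrame(columns, index=ids), roles)
    return RipSim(counts=counts, transcripts=transcripts, bound=bound)


class PolysomeSim(NamedTuple):
    wt_counts: CountMatrix
    ko_counts: CountMatrix
    shifted: frozenset[str]
    # planted truth for construction checks: per-transcript total mass and
    # fraction proportions (transcripts x fraction labels)
    mass: "pd.Series"
    wt_props: "pd.DataFrame"
    ko_props: "pd.DataFrame"


def simulate_polysome(
    config: SimulationConfig, truth_bound: frozenset[str] | set[str] = frozenset()
) -> PolysomeSim:
    """Fraction-resolved WT/KO counts with a planted initiation block.

    Each transcript's mass is split across the scheme's fractions by a
    Dirichlet draw around uniform class means (shared between genotypes,
    so unshifted transcripts differ only by counting noise). For shifted
    transcripts the KO moves ``shift_strength`` of the engaged
    (mono + poly) mass into the free fraction, scaling every engaged
    fraction by the same factor — poly:mono is preserved exactly, the
    poly/free ratio drops. The shifted subset is drawn with sampling
    weight ``binder_shift_multiplier`` for members of ``truth_bound`` so
    that binders are enriched among shifted transcripts.
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = _transcript_ids(config.n_transcripts)
    scheme = config.scheme
    n_frac = len(scheme.labels)
    engaged = [
        i for i, l in enumerate(scheme.labels) if scheme.classes[l] != "free"
    ]
    free_ix = [
        i for i, l in enumerate(scheme.labels) if scheme.classes[l] == "free"
    ]

    mass = config.base_mean * rng.lognormal(
        mean=-0.5 * config.base_sigma**2, sigma=config.base_sigma,
        size=config.n_transcripts,
    )
    alpha = np.full(n_frac, config.fraction_concentration / n_frac)
    props_wt = rng.dirichlet(alpha, size=config.n_transcripts)

    n_shift = int(round(config.shift_fraction * config.n_transcripts))
    weights = np.ones(config.n_transcripts)
    bound_mask = np.array([tid in truth_bound for tid in ids])
    weights[bound_mask] = config.binder_shift_multiplier
    shifted_idx = rng.choice(
        config.n_transcripts, size=n_shift, replace=False,
        p=weights / weights.sum(),
    )
    shifted = frozenset(ids[i] for i in shifted_idx)

    props_ko = props_wt.copy()
    if config.shift_strength > 0 and n_shift:
        sel = np.zeros(config.n_transcripts, dtype=bool)
        sel[shifted_idx] = True
        engaged_mass = props_ko[np.ix_(sel, engaged)].sum(axis=1)
        moved = config.shift_strength * engaged_mass
        props_ko[np.ix_(sel, engaged)] *= 1.0 - config.shift_strength
        props_ko[np.ix_(sel, free_ix)] += (moved / len(free_ix))[:, None]

    # every fraction library is sequenced to the same expected depth (its
    # counts measure within-fraction composition, as in real libraries)
    depth = config.base_mean * config.n_transcripts / n_frac

    def genotype_counts(props: np.ndarray, genotype: str) -> CountMatrix:
        columns: dict[str, np.ndarray] = {}
        roles: dict[str, str] = {}
        for j, label in enumerate(scheme.labels):
            frac_mean = mass * props[:, j]
            frac_mean = frac_mean * (depth / frac_mean.sum())
            for rep in range(1, config.n_replicates + 1):
                name = f"{genotype}_{label}_{rep}"
                columns[name] = _nb_counts(rng, frac_mean, config.nb_dispersion)
                roles[name] = f"fraction:{label}"
        return CountMatrix(pd.DataFrame(columns, index=ids), roles)

    wt_counts = genotype_counts(props_wt, "WT")
    ko_counts = genotype_counts(props_ko, "KO")
    return PolysomeSim(
        wt_counts=wt_counts,
        ko_counts=ko_counts,
        shifted=shifted,
        mass=pd.Series(mass, index=ids, name="mass"),
        wt_props=pd.DataFrame(props_wt, index=ids, columns=scheme.labels),
        ko_props=pd.DataFrame(props_ko, index=ids, columns=scheme.labels),
    )


class DESim(NamedTuple):
    table_a: pd.DataFrame
    table_b: pd.DataFrame
    truth_up: tuple[str, ...]
    truth_down: tuple[str, ...]


def simulate_de(
    config: SimulationConfig, fdr: float = 0.05, fold: float = 2.0
) -> DESim:
    """Two DE contrasts with a planted direction-concordant subset.

    The first ``n_up + n_down`` genes pass both filters with matching
    signs; the remaining genes cycle through decoy classes — fail FDR in
    one contrast, fail the fold filter in one contrast, discordant signs
    (passing both filters), or significant in neither — so the planted
    subset is recovered exactly at the stated thresholds.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_up, n_down = config.de_concordant
    genes = _gene_ids(config.n_genes)
    lfc_cut = np.log2(fold)

    def sig_padj(size: int) -> np.ndarray:
        return 10.0 ** rng.uniform(-8, np.log10(fdr), size=size)

    def null_padj(size: int) -> np.ndarray:
        return rng.uniform(fdr * 4, 1.0, size=size)

    def strong_lfc(sign: np.ndarray, size: int) -> np.ndarray:
        return sign * rng.uniform(lfc_cut + 0.2, lfc_cut + 2.0, size=size)

    def weak_lfc(size: int) -> np.ndarray:
        return rng.uniform(-0.9, 0.9, size=size) * lfc_cut

    n_planted = n_up + n_down
    sign = np.concatenate([np.ones(n_up), -np.ones(n_down)])
    rows_a = {
        "gene_id": genes[:n_planted],
        "log2fc": strong_lfc(sign, n_planted),
        "padj": sig_padj(n_planted),
    }
    rows_b = {
        "gene_id": genes[:n_planted],
        "log2fc": strong_lfc(sign, n_planted),
        "padj": sig_padj(n_planted),
    }
    table_a = [pd.DataFrame(rows_a)]
    table_b = [pd.DataFrame(rows_b)]

    decoys = genes[n_planted:]
    n_dec = len(decoys)
    kind = np.arange(n_dec) % 4
    dec_sign = np.where(rng.random(n_dec) < 0.5, 1.0, -1.0)
    a_lfc = strong_lfc(dec_sign, n_dec)
    b_lfc = strong_lfc(dec_sign, n_dec)
    a_padj = sig_padj(n_dec)
    b_padj = sig_padj(n_dec)
    # kind 0: fails FDR in a; kind 1: fails fold in b; kind 2: discordant
    # signs passing both filters; kind 3: significant in neither.
    a_padj[kind == 0] = null_padj((kind == 0).sum())
    b_lfc[kind == 1] = weak_lfc((kind == 1).sum())
    b_lfc[kind == 2] = -b_lfc[kind == 2]
    a_padj[kind == 3] = null_padj((kind == 3).sum())
    b_padj[kind == 3] = null_padj((kind == 3).sum())
    table_a.append(pd.DataFrame({"gene_id": decoys, "log2fc": a_lfc, "padj": a_padj}))
    table_b.append(pd.DataFrame({"gene_id": decoys, "log2fc": b_lfc, "padj": b_padj}))

    return DESim(
        table_a=pd.concat(table_a, ignore_index=True),
        table_b=pd.concat(table_b, ignore_index=True),
        truth_up=tuple(genes[:n_up]),
        truth_down=tuple(genes[n_up:n_planted]),
    )


def simulate_eclip(
    config: SimulationConfig,
    transcripts: TranscriptTable,
    truth_bound: frozenset[str] | set[str],
) -> IntervalSet:
    """CLIP peak intervals concentrated on bound transcripts.

    Peak counts per transcript are Poisson with rate ``peak_rate_bound``
    for bound transcripts and ``peak_rate_unbound`` otherwise. Peaks lie
    within the transcript span, on its strand, and 70% of them start in
    the 3'-most 30% of the span (the 3'-UTR-like end, strand-aware).
    """
    rng = np.random.default_rng(config.seed + 3)
    intervals: list[GenomicInterval] = []
    for rec in transcripts:
        rate = (
            config.peak_rate_bound
            if rec.transcript_id in truth_bound
            else config.peak_rate_unbound
        )
        n_peaks = int(rng.poisson(rate))
        span = rec.span_end - rec.span_start
        for k in range(n_peaks):
            width = min(int(rng.integers(30, 81)), span)
            last_start = rec.span_end - width
            three_prime_len = max(1, int(0.3 * span))
            if rng.random() < 0.7:
                if rec.strand == "+":
                    lo = max(rec.span_start, rec.span_end - three_prime_len)
                    hi = last_start
                else:
                    lo = rec.span_start
                    hi = min(rec.span_start + three_prime_len, last_start)
            else:
                lo, hi = rec.span_start, last_start
            if hi < lo:
                lo, hi = rec.span_start, last_start
            start = int(rng.integers(lo, hi + 1))
            intervals.append(
                GenomicInterval(
                    chrom=rec.chrom,
                    start=start,
                    end=start + width,
                    strand=rec.strand,
                    name=f"{rec.transcript_id}_peak{k + 1}",
                    score=float(np.round(rng.uniform(100, 1000), 1)),
                )
            )
    return IntervalSet(intervals)
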