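"""RIP-seq normalization and fold-enrichment binder calling.

The classification logic mirrors the standard RIP-seq scatter analysis:
counts from IP and control libraries are depth-corrected (size factors),
length-normalized to FPKM, averaged over replicates, and a transcript is
called bound when its pseudocounted IP/control ratio exceeds a fold
cutoff (strictly), among transcripts passing a detection floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from ribostate.annotations import CountMatrix, TranscriptTable

SizeFactorMethod = Literal["median_of_ratios", "per_million"]


@dataclass(frozen=True)
class NormalizationConfig:
    """Knobs of the adjusted-FPKM / fold-enrichment computation.

    ``pseudocount`` is added to both role means before the ratio (and is
    the "+1" of the log2 display scale); ``detection_floor`` is the
    minimum mean adjusted FPKM (in either role) for a transcript to count
    as detected, i.e. to enter the binder-calling universe.
    """

    size_factor_method: SizeFactorMethod = "median_of_ratios"
    pseudocount: float = 1.0
    detection_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be >= 0")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-transcript quantities behind one dot of the IP-vs-control scatter."""

    transcript_id: str
    mean_ip: float
    mean_control: float
    fold_enrichment: float
    log2_ip: float
    log2_control: float
    detected: bool


@dataclass(frozen=True)
class BinderSet:
    """Transcripts whose fold enrichment strictly exceeds ``cutoff``.

    ``universe_size`` is the number of detected transcripts the set was
    called from; it is the denominator of transcriptome-share summaries.
    """

    cutoff: float
    members: frozenset[str]
    universe_size: int

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.universe_size < 1:
            raise ValueError("universe_size must be >= 1")
        if len(self.members) > self.universe_size:
            raise ValueError("binder set larger than its universe")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.members


def size_factors(
    counts: CountMatrix | pd.DataFrame,
    method: SizeFactorMethod = "median_of_ratios",
) -> pd.Series:
    """Per-sample depth correction factors.

    ``median_of_ratios`` is the DESeq-style estimator: per sample, the
    median over transcripts (with all-positive counts) of the ratio of
    the count to the transcript's geometric mean across samples.
    ``per_million`` is the column sum divided by 1e6.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 1:
        raise ValueError("need at least one sample")
    values = df.to_numpy(dtype=float)
    if values.sum() == 0:
        raise ValueError("all-zero count matrix: size factors undefined")
    if method == "per_million":
        factors = values.sum(axis=0) / 1e6
    elif method == "median_of_ratios":
        positive = (values > 0).all(axis=1)
        if not positive.any():
            raise ValueError(
                "median_of_ratios needs >= 1 transcript with nonzero counts "
                "in every sample"
            )
        sub = values[positive]
        geomean = np.exp(np.log(sub).mean(axis=1))
        factors = np.median(sub / geomean[:, None], axis=0)
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    if (factors <= 0).any():
        raise ValueError("non-positive size factor computed")
    return pd.Series(factors, index=df.columns, name="size_factor")


def adjusted_fpkm(
    counts: CountMatrix,
    transcripts: TranscriptTable,
    factors: pd.Series,
) -> pd.DataFrame:
    """Size-factor-corrected FPKM per transcript and sample.

    value = (count / factor) * 1e9 / (length_nt * raw library size),
    i.e. ordinary FPKM computed on depth-adjusted counts. Deterministic
    and non-negative; a transcript without a usable length is an error.
    """
    df = counts.counts
    missing = [t for t in df.index if t not in transcripts]
    if missing:
        raise KeyError(f"transcripts without annotation: {missing[:5]}")
    lengths = pd.Series(
        {t: transcripts[t].length_nt for t in df.index}, name="length_nt"
    )
    no_len = lengths[lengths.isna()]
    if len(no_len):
        raise ValueError(f"no length for transcript {no_len.index[0]!r}")
    lib_sizes = df.sum(axis=0).astype(float)
    if (lib_sizes == 0).any():
        empty = lib_sizes.index[lib_sizes == 0][0]
        raise ValueError(f"sample {empty!r} has zero total counts")
    adjusted = df.to_numpy(dtype=float) / factors.reindex(df.columns).to_numpy()
    fpkm = adjusted * 1e9 / (
        lengths.to_numpy(dtype=float)[:, None] * lib_sizes.to_numpy()[None, :]
    )
    return pd.DataFrame(fpkm, index=df.index, columns=df.columns)


def enrichment(
    ip_expr: pd.DataFrame,
    control_expr: pd.DataFrame,
    config: NormalizationConfig = NormalizationConfig(),
) -> list[EnrichmentResult]:
    """Per-transcript IP/control fold enrichment on replicate-mean FPKM.

    Replicates are averaged on the FPKM scale (arithmetic mean); the fold
    is (mean_ip + pseudocount) / (mean_control + pseudocount). A
    transcript is ``detected`` when either role's mean reaches the
    detection floor. Both expression frames must cover the same
    transcripts in the same order.
    """
    if ip_expr.shape[1] == 0 or control_expr.shape[1] == 0:
        raise ValueError("need >= 1 IP and >= 1 control sample")
    if not ip_expr.index.equals(control_expr.index):
        raise ValueError("IP and control expression cover different transcripts")
    mean_ip = ip_expr.mean(axis=1)
    mean_control = control_expr.mean(axis=1)
    pc = config.pseudocount
    fold = (mean_ip + pc) / (mean_control + pc)
    detected = (mean_ip >= config.detection_floor) | (
        mean_control >= config.detection_floor
    )
    log2_ip = np.log2(mean_ip + 1.0)
    log2_control = np.log2(mean_control + 1.0)
    return [
        EnrichmentResult(
            transcript_id=t,
            mean_ip=float(mean_ip[t]),
            mean_control=float(mean_control[t]),
            fold_enrichment=float(fold[t]),
            log2_ip=float(log2_ip[t]),
            log2_control=float(log2_control[t]),
            detected=bool(detected[t]),
        )
        for t in ip_expr.index
    ]


def call_binders(
    results: Sequence[EnrichmentResult], cutoff: float
) -> BinderSet:
    """Call bound transcripts at a strict fold-enrichment cutoff.

    Members are the detected transcripts with fold_enrichment > cutoff;
    the universe is all detected transcripts.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if not results:
        raise ValueError("no enrichment results to call binders from")
    detected = [r for r in results if r.detected]
    if not detected:
        raise ValueError("no detected transcripts: binder universe is empty")
    members = frozenset(
        r.transcript_id for r in detected if r.fold_enrichment > cutoff
    )
    return BinderSet(cutoff=cutoff, members=members, universe_size=len(detected))


def rip_enrichment(
    counts: CountMatrix,
    transcripts: TranscriptTable,
    config: NormalizationConfig = NormalizationConfig(),
) -> tuple[list[EnrichmentResult], pd.Series]:
    """Counts-to-enrichment convenience pipeline.

    Computes size factors over all samples jointly, adjusted FPKM, and
    per-transcript enrichment of role ``ip`` over role ``control``.
    Returns (results, size_factors).
    """
    ip_samples = counts.samples_with_role("ip")
    control_samples = counts.samples_with_role("control")
    if not ip_samples or not control_samples:
        raise ValueError("count matrix needs samples with roles 'ip' and 'control'")
    factors = size_factors(counts, config.size_factor_method)
    expr = adjusted_fpkm(counts, transcripts, factors)
    results = enrichment(expr[ip_samples], expr[control_samples], config)
    return results, factors


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per transcript)."""
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "mean_ip": r.mean_ip,
                "mean_control": r.mean_control,
                "fold_enrichment": r.fold_enrichment,
                "log2_ip": r.log2_ip,
                "log2_control": r.log2_control,
                "detected": r.detected,
            }
            for r in results
        ]
    ).set_index("transcript_id")
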