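"""Readers, writers and sequence utilities shared by every analysis stage.

All coordinates inside the package are 0-based half-open, on the genomic
forward strand. GTF (1-based closed) is converted on read and back on
write; BED is already 0-based half-open and passes through unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file violates its declared format (bad coordinate, type, or id)."""


# ---------------------------------------------------------------------------
# transcript annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: identity, genomic placement and exon structure.

    ``span_start``/``span_end`` and every exon are 0-based half-open.
    ``length_nt`` is the summed exon length when exons are given.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    exons: tuple[tuple[int, int], ...] = ()
    gene_symbol: str | None = None
    length_nt: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.span_start < self.span_end:
            raise FormatError(
                f"{self.transcript_id}: span_start must be < span_end "
                f"({self.span_start}, {self.span_end})"
            )
        prev_end = None
        for start, end in self.exons:
            if not (self.span_start <= start < end <= self.span_end):
                raise FormatError(
                    f"{self.transcript_id}: exon ({start}, {end}) outside span "
                    f"({self.span_start}, {self.span_end}) or empty"
                )
            if prev_end is not None and start < prev_end:
                raise FormatError(
                    f"{self.transcript_id}: exons overlap or are unsorted at {start}"
                )
            prev_end = end
        if self.exons:
            exonic = sum(end - start for start, end in self.exons)
            if self.length_nt is None:
                object.__setattr__(self, "length_nt", exonic)
            elif self.length_nt != exonic:
                raise FormatError(
                    f"{self.transcript_id}: length_nt {self.length_nt} != summed "
                    f"exon length {exonic}"
                )
        if self.length_nt is not None and self.length_nt < 1:
            raise FormatError(f"{self.transcript_id}: length_nt must be >= 1")


class TranscriptTable:
    """Ordered, id-indexed collection of :class:`TranscriptRecord`."""

    def __init__(self, records: Iterable[TranscriptRecord]):
        self._records: dict[str, TranscriptRecord] = {}
        for rec in records:
            if rec.transcript_id in self._records:
                raise FormatError(f"duplicate transcript_id {rec.transcript_id}")
            self._records[rec.transcript_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self._records.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._records

    def __getitem__(self, transcript_id: str) -> TranscriptRecord:
        try:
            return self._records[transcript_id]
        except KeyError:
            raise KeyError(f"unknown transcript_id {transcript_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def lengths(self) -> pd.Series:
        """Transcript lengths in nt; raises if any record lacks a length."""
        missing = [r.transcript_id for r in self if r.length_nt is None]
        if missing:
            raise FormatError(
                "no length available (no exons and no explicit length) for: "
                + ", ".join(missing[:5])
            )
        return pd.Series(
            {r.transcript_id: r.length_nt for r in self}, name="length_nt"
        )


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

_VALID_ROLES = ("ip", "control", "bulk")


def _check_role(role: str) -> None:
    if role in _VALID_ROLES or role.startswith("fraction:"):
        return
    raise FormatError(
        f"unknown sample role {role!r}; expected one of {_VALID_ROLES} "
        "or 'fraction:<label>'"
    )


@dataclass
class CountMatrix:
    """Raw integer counts, transcripts x samples, with a role per sample.

    ``counts`` is a pandas DataFrame indexed by transcript_id with one
    column per sample_id; ``roles`` maps sample_id to its role
    (``ip``, ``control``, ``bulk`` or ``fraction:<label>``).
    """

    counts: pd.DataFrame
    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate transcript_id {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        missing = set(self.counts.columns) - set(self.roles)
        if missing:
            raise FormatError(f"samples without a role: {sorted(missing)}")
        for role in self.roles.values():
            _check_role(role)
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                r, c = np.argwhere(values != np.round(values))[0]
                raise FormatError(
                    f"non-integer count at transcript {self.counts.index[r]!r}, "
                    f"sample {self.counts.columns[c]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at transcript {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )

    @property
    def transcripts(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[tuple[str, str]]:
        return [(s, self.roles[s]) for s in self.counts.columns]

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.counts.columns if self.roles[s] == role]

    def fraction_labels(self) -> list[str]:
        """Distinct fraction labels among the samples, in column order."""
        labels: list[str] = []
        for s in self.counts.columns:
            role = self.roles[s]
            if role.startswith("fraction:"):
                label = role.split(":", 1)[1]
                if label not in labels:
                    labels.append(label)
        return labels


def read_counts(path: str | Path, role_map: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count table (transcript_id first column, header row).

    Every sample column must appear in ``role_map``. Non-integer or
    negative cells raise :class:`FormatError` naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "transcript_id":
        df = df.rename(columns={df.columns[0]: "transcript_id"})
    df = df.set_index("transcript_id")
    for col in df.columns:
        try:
            as_num = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric count in sample {col!r}: {exc}") from None
        df[col] = as_num
    missing = set(df.columns) - set(role_map)
    if missing:
        raise FormatError(f"role_map missing samples: {sorted(missing)}")
    return CountMatrix(df, {s: role_map[s] for s in df.columns})


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def read_gtf(path: str | Path) -> TranscriptTable:
    """Parse a GTF into transcript records via exon features.

    Exons are grouped by ``transcript_id``, sorted, merged when
    overlapping, and converted from GTF 1-based closed to 0-based
    half-open coordinates. An exon without a ``transcript_id`` attribute,
    or a transcript whose exons disagree on strand or chromosome, is an
    error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_transcript: dict[str, dict] = {}
    for exon in db.features_of_type("exon", order_by=("seqid", "start")):
        attrs = dict(exon.attributes)
        if "transcript_id" not in attrs or not attrs["transcript_id"]:
            raise FormatError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} lacks transcript_id"
            )
        tid = attrs["transcript_id"][0]
        gid = attrs.get("gene_id", [tid])[0]
        symbol = attrs.get("gene_name", [None])[0]
        entry = by_transcript.setdefault(
            tid,
            {"gene_id": gid, "gene_symbol": symbol, "chrom": exon.seqid,
             "strand": exon.strand, "exons": []},
        )
        if entry["chrom"] != exon.seqid:
            raise FormatError(f"{tid}: exons on multiple chromosomes")
        if entry["strand"] != exon.strand:
            raise FormatError(f"{tid}: mixed strands across exons")
        entry["exons"].append((exon.start - 1, exon.end))  # to half-open
    records = []
    for tid, entry in by_transcript.items():
        exons = _merge_intervals(entry["exons"])
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=entry["gene_id"],
                gene_symbol=entry["gene_symbol"],
                chrom=entry["chrom"],
                strand=entry["strand"],
                span_start=exons[0][0],
                span_end=exons[-1][1],
                exons=tuple(exons),
            )
        )
    return TranscriptTable(records)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def write_gtf(table: TranscriptTable, path: str | Path, source: str = "ribostate") -> None:
    """Write exon features back to GTF (1-based closed coordinates)."""
    with open(path, "w") as handle:
        for rec in table:
            exons = rec.exons or ((rec.span_start, rec.span_end),)
            for start, end in exons:
                attrs = f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}";'
                if rec.gene_symbol:
                    attrs += f' gene_name "{rec.gene_symbol}";'
                handle.write(
                    f"{rec.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t"
                    f"{rec.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A peak or other interval, 0-based half-open. Strand ``.`` matches both."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise FormatError("interval with empty chromosome name")
        if not self.start < self.end:
            raise FormatError(
                f"interval start must be < end ({self.chrom}:{self.start}-{self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class IntervalSet:
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6 (native 0-based half-open). Empty files are allowed.

    A record with start >= end raises :class:`FormatError` with its line
    number; records lacking a strand column are strand-agnostic (``.``).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: fewer than 3 BED fields")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start >= end:
                raise FormatError(f"line {lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise FormatError(f"line {lineno}: bad strand {strand!r}")
            intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

_SEQ_ALPHABET = set("ACGTUN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {name: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def find_polyc_tracts(sequence: str, min_run: int) -> list[tuple[int, int]]:
    """Locate maximal poly-C runs of length >= ``min_run``.

    Poly-C tracts are the binding determinant of poly-C-binding hnRNPs;
    runs are reported left to right as 0-based half-open (start, end)
    pairs. The scan is case-insensitive, treats U and T as equivalent
    (neither matches C), and never counts N as C.
    """
    if min_run < 1:
        raise ValueError(f"min_run must be >= 1, got {min_run}")
    upper = sequence.upper()
    bad = set(upper) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return [
        (m.start(), m.end())
        for m in re.finditer("C{%d,}" % min_run, upper)
    ]
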