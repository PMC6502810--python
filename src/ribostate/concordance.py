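"""Direction-concordant intersection of two differential-expression
contrasts.

The package consumes DE result tables (gene_id, log2fc, padj) produced
by an external fitter such as DESeq; it does not refit the model. Genes
passing an FDR and fold-change filter in both contrasts, with the same
sign of change, form the concordant (co-regulated) set. The sign
convention is fixed as knockout-vs-wild-type throughout: a gene induced
by the factor is *down* in the knockout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ribostate.annotations import FormatError

REQUIRED_COLUMNS = ("gene_id", "log2fc", "padj")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE result TSV with columns gene_id, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"DE table missing columns: {sorted(missing)}")
    return validate_de_table(df)


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Enforce the DE-table contract: one row per gene, padj in [0, 1]."""
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene_id {dup!r} in DE table")
    if table["padj"].isna().any():
        bad = table.loc[table["padj"].isna(), "gene_id"].iloc[0]
        raise FormatError(f"missing padj for gene {bad!r}")
    if ((table["padj"] < 0) | (table["padj"] > 1)).any():
        bad = table.loc[(table["padj"] < 0) | (table["padj"] > 1), "gene_id"].iloc[0]
        raise FormatError(f"padj outside [0, 1] for gene {bad!r}")
    return table


def filter_de(
    table: pd.DataFrame, fdr: float = 0.05, fold: float = 2.0
) -> pd.DataFrame:
    """Significant genes with their direction of change.

    Keeps genes with padj <= fdr and |log2fc| >= log2(fold), both
    thresholds inclusive; returns a frame with gene_id and direction
    (+1 up in KO, -1 down in KO).
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    validate_de_table(table)
    lfc_cut = math.log2(fold)
    keep = (table["padj"] <= fdr) & (table["log2fc"].abs() >= lfc_cut)
    out = table.loc[keep, ["gene_id", "log2fc"]].copy()
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class ConcordanceSummary:
    """Same-direction intersection of two filtered gene sets."""

    n_a: int
    n_b: int
    n_concordant: int
    n_up: int
    n_down: int
    genes_up: tuple[str, ...]
    genes_down: tuple[str, ...]


def concordant_intersect(
    a: pd.DataFrame, b: pd.DataFrame
) -> ConcordanceSummary:
    """Intersect two filtered gene sets, requiring matching direction.

    Inputs are the frames produced by :func:`filter_de` (gene_id +
    direction). Genes significant in both contrasts but with opposite
    signs are excluded from the concordant set.
    """
    dir_a = dict(zip(a["gene_id"], a["direction"]))
    dir_b = dict(zip(b["gene_id"], b["direction"]))
    up = sorted(g for g, d in dir_a.items() if d > 0 and dir_b.get(g, 0) > 0)
    down = sorted(g for g, d in dir_a.items() if d < 0 and dir_b.get(g, 0) < 0)
    return ConcordanceSummary(
        n_a=len(dir_a),
        n_b=len(dir_b),
        n_concordant=len(up) + len(down),
        n_up=len(up),
        n_down=len(down),
        genes_up=tuple(up),
        genes_down=tuple(down),
    )
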