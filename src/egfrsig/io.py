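"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel either as dense TSV (genes as rows) or as an
MatrixMarket triplet with row/column name sidecars; gene sets as standard
GMT; per-cell annotations, clinical tables and CRISPR log-fold-change
matrices as TSV.  Blank cells in a CRISPR TSV mean "not measured in that
screen".
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import InputError
from .score import GeneSet

__all__ = [
    "read_expression", "write_expression",
    "read_expression_mtx", "write_expression_mtx",
    "read_gmt", "write_gmt", "load_builtin_gene_sets",
    "read_annotation", "write_annotation",
    "read_clinical", "write_clinical",
    "read_crispr", "write_crispr",
]

MIN_SURVIVAL_DAYS = 30


# --------------------------------------------------------------------------
# expression matrices

def read_expression(path: str | Path) -> pd.DataFrame:
    """Dense TSV, genes as rows, first column = gene identifier."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise InputError(f"{path}: duplicate gene identifiers")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression_mtx(prefix: str | Path) -> pd.DataFrame:
    """MTX triplet ``<prefix>.mtx`` with ``<prefix>.rownames`` / ``.colnames``."""
    prefix = Path(prefix)
    mat = scipy.io.mmread(prefix.with_suffix(".mtx"))
    rows = prefix.with_suffix(".rownames").read_text().split()
    cols = prefix.with_suffix(".colnames").read_text().split()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if dense.shape != (len(rows), len(cols)):
        raise InputError(f"{prefix}: sidecar names do not match matrix shape")
    return pd.DataFrame(dense, index=rows, columns=cols)


def write_expression_mtx(expr: pd.DataFrame, prefix: str | Path) -> None:
    prefix = Path(prefix)
    scipy.io.mmwrite(prefix.with_suffix(".mtx"), scipy.sparse.csr_matrix(expr.to_numpy()))
    prefix.with_suffix(".rownames").write_text("\n".join(map(str, expr.index)) + "\n")
    prefix.with_suffix(".colnames").write_text("\n".join(map(str, expr.columns)) + "\n")


# --------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Standard GMT: tab-separated ``name<TAB>description<TAB>gene...`` lines."""
    sets: list[GeneSet] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(f"{path}: GMT line with fewer than 3 fields: {line[:60]!r}")
        name, _desc, *genes = fields
        sets.append(GeneSet(name, tuple(g for g in genes if g.strip())))
    if not sets:
        raise InputError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    lines = [
        "\t".join([s.name, descriptions.get(s.name, "na"), *s.genes]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_builtin_gene_sets() -> dict[str, GeneSet]:
    """Packaged synthetic stand-in gene sets (see ``data/`` docnote).

    Contains ``EGFR_RELATED`` (36 genes, the enrichment-scoring set) and
    ``EGFR_SIG`` (32 genes, the derived-signature stand-in whose four
    CRISPR-verified members are MAT2A, JUNB, C12orf57 and NR4A1).
    """
    ref = importlib.resources.files("egfrsig").joinpath("data/egfr_sets_synthetic.gmt")
    with importlib.resources.as_file(ref) as path:
        return {s.name: s for s in read_gmt(path)}


# --------------------------------------------------------------------------
# annotations / clinical / CRISPR

def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="cell_id")
    required = {"label", "mito_fraction", "genes_detected"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: annotation table must have columns {sorted(required)}")
    return df


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="cell_id")


def read_clinical(path: str | Path, min_days: int = MIN_SURVIVAL_DAYS) -> pd.DataFrame:
    """Clinical TSV; patients with follow-up <= ``min_days`` days are dropped.

    The short-follow-up filter mirrors the cohort inclusion rule applied to
    the survival endpoints upstream of every survival analysis.
    """
    df = pd.read_csv(path, sep="\t", index_col="patient_id")
    if "time_days" not in df.columns or "event" not in df.columns:
        raise InputError(f"{path}: clinical table needs time_days and event columns")
    return df[df["time_days"] > min_days].copy()


def write_clinical(clin: pd.DataFrame, path: str | Path) -> None:
    clin.to_csv(path, sep="\t", index_label="patient_id")


def read_crispr(path: str | Path) -> pd.DataFrame:
    """Gene x screen log-fold-change TSV; empty cells become NaN (missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_crispr(lfc: pd.DataFrame, path: str | Path) -> None:
    lfc.to_csv(path, sep="\t", index_label="gene", na_rep="")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
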