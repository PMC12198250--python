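"""Single-sample gene-set enrichment scoring (ssGSEA-style).

A sample's enrichment score for a gene set is computed from the ranked
expression profile of that sample alone: genes are ordered by decreasing
expression and the score is the running difference between a weighted
empirical CDF over in-set genes and an unweighted ECDF over out-of-set
genes, summed over all positions.  With weight exponent ``alpha = 0`` the
score depends only on the within-sample gene ranks and is therefore
invariant to any strictly monotone transform of a sample's expression.

The same scorer serves wherever a per-sample pathway-activity score is
needed: EGFR activity per cell, immune-infiltration abundance per bulk
sample, and hallmark-pathway scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ScoringError

logger = logging.getLogger(__name__)

__all__ = ["GeneSet", "ssgsea_score", "minmax_normalize"]


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique, uppercase gene symbols.

    Symbols are uppercased on construction; duplicates (after casefolding)
    and empty sets are rejected.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(g.strip().upper() for g in self.genes)
        if not genes:
            raise ScoringError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if list(genes).count(g) > 1})
            raise ScoringError(f"gene set {self.name!r} has duplicate symbols: {dupes}")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


def _sample_es(x: np.ndarray, in_set: np.ndarray, name_rank: np.ndarray, alpha: float) -> float:
    """Enrichment score of one expression vector.

    Walk genes in decreasing-expression order (ties broken by gene
    identifier so the score never depends on row order) and accumulate the
    difference between the weighted in-set ECDF and the uniform out-set
    ECDF.  Weights are rank magnitudes ``(N + 1 - descending average
    rank) ** alpha``, so the most highly expressed gene has magnitude ~N.
    """
    n = x.size
    order = np.lexsort((name_rank, -x))
    desc_rank = rankdata(-x, method="average")
    magnitude = (n + 1.0 - desc_rank) ** alpha

    in_ordered = in_set[order]
    w_ordered = np.where(in_ordered, magnitude[order], 0.0)
    w_total = w_ordered.sum()
    n_out = n - int(in_set.sum())

    p_in = np.cumsum(w_ordered) / w_total
    p_out = np.cumsum(~in_ordered) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_score(expr: pd.DataFrame, gene_set: GeneSet, alpha: float = 0.25) -> pd.Series:
    """Score every sample (column) of ``expr`` against ``gene_set``.

    Parameters
    ----------
    expr
        Expression matrix, genes as rows, samples as columns.
    gene_set
        The set to score. Members absent from the matrix are dropped with a
        logged warning.
    alpha
        Non-negative rank-weight exponent (0.25 by default; 0 gives a pure
        rank statistic).
    """
    if alpha < 0:
        raise ScoringError(f"alpha must be >= 0, got {alpha}")
    if expr.shape[0] < 2:
        raise ScoringError("expression matrix must contain at least 2 genes")

    rows = expr.index.astype(str).str.upper()
    members = [g for g in gene_set.genes if g in set(rows)]
    missing = set(gene_set.genes) - set(members)
    if missing:
        logger.warning(
            "gene set %r: %d of %d genes absent from matrix and dropped",
            gene_set.name, len(missing), len(gene_set),
        )
    if not members:
        raise ScoringError(f"gene set {gene_set.name!r} has no genes in the matrix")
    if len(members) == expr.shape[0]:
        raise ScoringError(
            f"gene set {gene_set.name!r} covers every matrix row; out-set is empty"
        )

    in_set = np.asarray(rows.isin(members))
    # Deterministic tie-break key: rank of the gene identifier.
    name_rank = rankdata(rows.to_numpy(), method="ordinal")
    values = expr.to_numpy(dtype=float)

    scores = np.empty(expr.shape[1])
    for j in range(expr.shape[1]):
        scores[j] = _sample_es(values[:, j], in_set, name_rank, alpha)
    out = pd.Series(scores, index=expr.columns, name=gene_set.name)
    if not np.isfinite(out.to_numpy()).all():
        raise ScoringError("non-finite enrichment score produced")
    return out


def minmax_normalize(scores: pd.Series) -> pd.Series:
    """Affinely map scores onto [0, 1]; a constant vector maps to all 0.5."""
    if scores.size < 2:
        raise ScoringError("need at least 2 samples to normalize")
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        return pd.Series(0.5, index=scores.index, name=scores.name)
    return (scores - lo) / (hi - lo)
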