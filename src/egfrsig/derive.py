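"""Cross-cohort signature derivation.

Per single-cell dataset, two gene filters are applied to malignant cells:

* ``Gx`` — genes whose expression correlates positively with the per-cell
  EGFR activity score (Spearman rho > 0.2 at FDR < 0.05);
* ``Gy`` — genes up-regulated in malignant cells versus all other cells
  (mean log2 difference >= 0.5 at Wilcoxon FDR < 0.05).

Their intersection ``Gn`` is the dataset's signature contribution. Across
datasets, each gene's retained Spearman coefficients are combined by
geometric mean, and genes with geometric-mean rho > 0.4 (moderate to
strong correlation) form the merged signature.

Threshold strictness is deliberate and pinned: the correlation threshold
is strict (rho > 0.2), the fold-change threshold is inclusive
(log2fc >= 0.5), both FDR cuts are strict (q < 0.05), and the merge cut is
strict (geometric mean > 0.4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, PipelineError
from .score import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetSignature", "Signature",
    "qc_filter", "bh_adjust", "spearman_table", "malignant_upregulated",
    "dataset_signature", "merge_signatures",
]


@dataclass
class DatasetSignature:
    """One dataset's Gn gene set with the retained Spearman coefficients."""

    dataset_id: str
    rho: pd.Series  # index: gene, values: Spearman rho (all passed Gx and Gy)

    @property
    def genes(self) -> list[str]:
        return list(self.rho.index)

    def __len__(self) -> int:
        return len(self.rho)


@dataclass
class Signature:
    """Merged signature: per-gene geometric-mean rho and dataset support."""

    name: str
    table: pd.DataFrame = field(repr=False)  # columns: gm_rho, n_datasets

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def as_gene_set(self) -> GeneSet:
        return GeneSet(self.name, tuple(self.table.index))

    def __len__(self) -> int:
        return len(self.table)


def qc_filter(cohort, min_genes: int = 300, max_mito: float = 0.20):
    """Drop low-quality cells.

    A cell is removed when it has fewer than ``min_genes`` detected genes or
    a mitochondrial-read fraction above ``max_mito`` (defaults 300 / 20%).
    """
    keep = (cohort.genes_detected >= min_genes) & (cohort.mito_fraction <= max_mito)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise PipelineError(
            f"QC removed all {len(keep)} cells "
            f"(min_genes={min_genes}, max_mito={max_mito})"
        )
    if n_removed:
        logger.info("QC removed %d of %d cells", n_removed, len(keep))
    return cohort.subset(cohort.expr.columns[keep.to_numpy()])


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputError("p must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_table(expr: pd.DataFrame, scores: pd.Series) -> pd.DataFrame:
    """Spearman correlation of every gene against a per-cell score.

    ``expr`` is genes x cells (malignant cells only, by convention of the
    derivation procedure) and ``scores`` aligns to its columns. Returns a
    table with columns ``rho``, ``p``, ``q``, ``n``. Constant genes (or a
    constant score vector) are recorded as rho = 0, p = 1 rather than
    undefined, so a genome-wide scan never aborts.
    """
    scores = scores.reindex(expr.columns)
    if scores.isna().any():
        raise InputError("scores are not aligned to the expression columns")
    n = expr.shape[1]
    if n < 3:
        raise InputError(f"need >= 3 cells for correlation, got {n}")

    x = scipy.stats.rankdata(expr.to_numpy(dtype=float), axis=1)
    y = scipy.stats.rankdata(scores.to_numpy(dtype=float))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())

    degenerate = (sx == 0) | (sy == 0)
    denom = np.where(degenerate, 1.0, sx * sy)
    rho = np.where(degenerate, 0.0, xc @ yc / denom)
    rho = np.clip(rho, -1.0, 1.0)

    # Two-sided p via the t approximation (as in the usual Spearman test).
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = np.where(np.isinf(t), 0.0, 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(degenerate, 1.0, p)

    return pd.DataFrame(
        {"rho": rho, "p": p, "q": bh_adjust(p), "n": n}, index=expr.index
    )


def malignant_upregulated(cohort) -> pd.DataFrame:
    """Malignant-versus-rest differential expression.

    ``log2fc`` is the difference of mean log2 expression (malignant minus
    rest); the p-value is a two-sided Wilcoxon rank-sum test, adjusted by
    Benjamini–Hochberg across genes. All-tied genes get p = 1.
    """
    is_mal = (cohort.cell_labels == "malignant").to_numpy()
    if is_mal.sum() < 2 or (~is_mal).sum() < 2:
        raise PipelineError(
            f"need >= 2 cells per group, got {int(is_mal.sum())} malignant / "
            f"{int((~is_mal).sum())} other"
        )
    values = cohort.expr.to_numpy(dtype=float)
    mal, rest = values[:, is_mal], values[:, ~is_mal]
    log2fc = mal.mean(axis=1) - rest.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.mannwhitneyu(
            mal, rest, axis=1, alternative="two-sided", method="asymptotic"
        )
    p = np.asarray(res.pvalue, dtype=float)
    # Zero-variance (all-tied) genes yield NaN from the tie-corrected
    # normal approximation; no evidence against the null.
    p = np.where(np.isnan(p), 1.0, p)

    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": bh_adjust(p)}, index=cohort.expr.index
    )


def dataset_signature(
    corr: pd.DataFrame,
    de: pd.DataFrame,
    dataset_id: str = "dataset",
    rho_min: float = 0.2,
    lfc_min: float = 0.5,
    q_max: float = 0.05,
) -> DatasetSignature:
    """Intersect the correlation (Gx) and up-regulation (Gy) filters.

    Gx membership requires rho strictly above ``rho_min`` at q < ``q_max``;
    Gy membership requires log2fc >= ``lfc_min`` (inclusive) at q < ``q_max``.
    """
    if not corr.index.equals(de.index):
        common = corr.index.intersection(de.index)
        if len(common) == 0:
            raise InputError("correlation and DE tables share no genes")
        logger.warning(
            "correlation/DE gene universes differ; using %d common genes", len(common)
        )
        corr, de = corr.loc[common], de.loc[common]

    gx = (corr["rho"] > rho_min) & (corr["q"] < q_max)
    gy = (de["log2fc"] >= lfc_min) & (de["q"] < q_max)
    keep = gx & gy
    return DatasetSignature(dataset_id, corr.loc[keep, "rho"].copy())


def merge_signatures(
    parts: list[DatasetSignature],
    gm_min: float = 0.4,
    min_datasets: int = 1,
    name: str = "EGFR.Sig",
) -> Signature:
    """Geometric-mean merge of per-dataset signatures.

    For each gene the geometric mean of its Spearman coefficients is taken
    over the datasets where it passed both filters (not over all datasets);
    genes with geometric mean strictly above ``gm_min`` and support in at
    least ``min_datasets`` datasets are retained. ``n_datasets`` is reported
    so stricter support policies can be applied post hoc.
    """
    if not parts:
        raise InputError("need at least one dataset signature to merge")
    rhos: dict[str, list[float]] = {}
    for part in parts:
        for gene, r in part.rho.items():
            if r <= 0:
                # The Gx filter guarantees rho > rho_min > 0.
                raise InputError(
                    f"non-positive rho {r} for {gene} in {part.dataset_id}; "
                    "upstream filter violated"
                )
            rhos.setdefault(gene, []).append(float(r))

    records = {
        gene: (float(scipy.stats.gmean(vals)), len(vals)) for gene, vals in rhos.items()
    }
    table = pd.DataFrame.from_dict(records, orient="index", columns=["gm_rho", "n_datasets"])
    table = table[(table["gm_rho"] > gm_min) & (table["n_datasets"] >= min_datasets)]
    return Signature(name, table.sort_index())
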