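"""Hub-signature subtype analysis.

Consensus clustering follows the resampling procedure of Monti et al.:
repeatedly subsample the samples, cluster each subsample with k-means, and
record for every sample pair the fraction of co-sampled runs in which the
pair landed in the same cluster.  The resulting consensus matrix is near
block-structured when the clustering is stable; final assignments come
from average-linkage hierarchical clustering of 1 - consensus, and the
proportion of ambiguous clustering (PAC) summarizes sharpness per k.

Principal coordinate analysis (classical multidimensional scaling) embeds
a distance matrix via the eigendecomposition of the double-centered Gram
matrix; axes with negative eigenvalues (non-Euclidean distance parts) are
reported but dropped from the coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from sklearn.cluster import KMeans

from .errors import InputError
from .score import GeneSet
from .derive import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult", "consensus_cluster", "pcoa", "compare_groups",
    "hypergeom_enrich", "pac_score",
]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, assignments and PAC sharpness summaries."""

    matrices: dict        # k -> samples x samples DataFrame in [0, 1]
    assignments: dict     # k -> pd.Series of cluster labels (1-based)
    pac: dict             # k -> proportion of ambiguous clustering
    k_range: tuple

    @property
    def best_k(self) -> int:
        return min(self.pac, key=lambda k: (self.pac[k], k))


def pac_score(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Fraction of off-diagonal consensus entries in the ambiguous band."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = consensus[iu]
    return float(np.mean((vals > lower) & (vals < upper)))


def consensus_cluster(
    features: pd.DataFrame,
    k_range=range(2, 7),
    resample_fraction: float = 0.8,
    n_resamples: int = 100,
    seed: int = 0,
) -> ConsensusResult:
    """Monti-style consensus clustering of samples (rows) by k-means.

    ``features`` is samples x features (e.g. hub-gene expression).  For
    each k, ``n_resamples`` subsamples of ``resample_fraction`` of the
    samples are clustered with k-means (10 restarts); the consensus entry
    for a pair is its co-clustering count divided by its co-sampling
    count.  Assignments cut an average-linkage tree of 1 - consensus.
    """
    n = features.shape[0]
    k_range = tuple(k_range)
    if n < max(k_range) * 3:
        raise InputError(f"need >= {max(k_range) * 3} samples for k up to {max(k_range)}")
    if features.drop_duplicates().shape[0] < max(k_range):
        raise InputError("fewer distinct samples than clusters requested")
    X = features.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    m = max(2, int(round(resample_fraction * n)))

    matrices, assignments, pac = {}, {}, {}
    for k in k_range:
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(n_clusters=k, n_init=10,
                        random_state=int(rng.integers(2 ** 31)))
            labels = km.fit_predict(X[idx])
            sampled[np.ix_(idx, idx)] += 1.0
            for c in range(k):
                members = idx[labels == c]
                together[np.ix_(members, members)] += 1.0
        with np.errstate(invalid="ignore"):
            cons = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0

        link = sch.linkage(cons[np.triu_indices(n, k=1)] * -1 + 1, method="average")
        labels = sch.fcluster(link, t=k, criterion="maxclust")
        matrices[k] = pd.DataFrame(cons, index=features.index, columns=features.index)
        assignments[k] = pd.Series(labels, index=features.index, name=f"k{k}")
        pac[k] = pac_score(cons)
    return ConsensusResult(matrices, assignments, pac, k_range)


def pcoa(distances: pd.DataFrame | np.ndarray):
    """Classical scaling of a symmetric distance matrix.

    Returns ``(coordinates, eigenvalues)``: coordinates span the axes with
    positive eigenvalues (ordered decreasing), scaled so squared
    inter-point distances reproduce the input when it is Euclidean;
    eigenvalues include any negative ones for diagnostics.
    """
    index = distances.index if isinstance(distances, pd.DataFrame) else None
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise InputError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise InputError("distance matrix must have a zero diagonal")

    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    pos = eigval > max(1e-12, 1e-9 * abs(eigval).max(initial=1.0))
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    coords_df = pd.DataFrame(coords, index=index, columns=cols)
    return coords_df, eigval


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(scores: pd.DataFrame, groups, test: str = "wilcoxon") -> pd.DataFrame:
    """Per-feature two-group comparison with BH correction and star codes.

    ``scores`` is samples x features; ``groups`` a binary label per sample.
    ``test`` is ``wilcoxon`` (rank-sum, default) or ``ttest``.  Constant
    features get p = 1.
    """
    g = pd.Series(groups).reindex(scores.index)
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise InputError(f"need exactly 2 groups, got {levels}")
    a = scores[g == levels[0]].to_numpy(dtype=float)
    b = scores[g == levels[1]].to_numpy(dtype=float)
    diff = a.mean(axis=0) - b.mean(axis=0)

    if test == "wilcoxon":
        with np.errstate(invalid="ignore", divide="ignore"):
            p = scipy.stats.mannwhitneyu(a, b, axis=0, alternative="two-sided").pvalue
    elif test == "ttest":
        with np.errstate(invalid="ignore", divide="ignore"):
            p = scipy.stats.ttest_ind(a, b, axis=0).pvalue
    else:
        raise InputError(f"unknown test {test!r}")
    p = np.where(np.isnan(p), 1.0, np.asarray(p, dtype=float))
    constant = scores.std(axis=0, ddof=0).to_numpy() == 0
    p = np.where(constant, 1.0, p)

    q = bh_adjust(p)
    return pd.DataFrame(
        {"difference": diff, "p": p, "q": q, "stars": [_stars(v) for v in p]},
        index=scores.columns,
    )


def hypergeom_enrich(query: GeneSet, pathways: list[GeneSet],
                     universe: GeneSet) -> pd.DataFrame:
    """One-sided hypergeometric pathway over-representation test.

    Query and pathways are intersected with the universe; for each pathway
    the upper-tail probability P(X >= k) of the overlap under sampling
    without replacement is computed, with BH adjustment across pathways.
    Pathways disjoint from the universe are excluded with a warning.
    """
    uni = set(universe.genes)
    q_genes = set(query.genes) & uni
    if not q_genes:
        raise InputError("query has no genes in the universe")
    N, n = len(uni), len(q_genes)

    rows = {}
    for pw in pathways:
        members = set(pw.genes) & uni
        if not members:
            logger.warning("pathway %r disjoint from universe; excluded", pw.name)
            continue
        K = len(members)
        k = len(members & q_genes)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows[pw.name] = {"k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)}
    if not rows:
        raise InputError("no pathway overlaps the universe")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values("p")
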