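"""Immunotherapy response prediction and consensus hub-gene selection.

The harness trains classifiers on signature-gene expression (per-cohort
gene-standardized) with repeated stratified k-fold cross-validation and
hyperparameter tuning inside each training fold, reports the pooled
out-of-fold AUC averaged over repeats, benchmarks multiple signatures on
holdout cohorts, ranks per-gene importance with five different methods,
and retains as hub genes those selected by at least three of the five
(majority-vote consensus).

AUC is computed by the rank (Mann–Whitney) formula with half credit for
tied scores, so it equals the normalized U statistic exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .errors import FitError, InputError
from .score import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig", "AUCResult", "HubSet", "evaluate_auc", "partition_indices",
    "split_cohort", "train_response_classifier", "benchmark_signatures",
    "rank_feature_importance", "consensus_hub", "IMPORTANCE_METHODS",
]

IMPORTANCE_METHODS = (
    "univariate_auc", "l1_selection_frequency", "permutation_importance",
    "greedy_forward", "nb_loglik",
)


@dataclass
class CVConfig:
    """Repeated stratified cross-validation settings (one seed per repeat)."""

    folds: int = 5
    repeats: int = 10
    seeds: tuple[int, ...] | None = None
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise InputError("folds must be >= 2")
        if self.seeds is None:
            self.seeds = tuple(range(self.repeats))
        self.seeds = tuple(int(s) for s in self.seeds)
        if len(self.seeds) != self.repeats:
            raise InputError("need exactly one seed per repeat")


@dataclass
class AUCResult:
    auc: float
    roc_points: np.ndarray  # (fpr, tpr) rows
    n_pos: int
    n_neg: int


@dataclass
class TrainResult:
    model: object
    auc: float
    auc_per_repeat: list[float]
    folds: int
    repeats: int
    genes: list[str]


@dataclass
class HubSet:
    votes: pd.Series
    min_votes: int

    @property
    def retained(self) -> list[str]:
        return sorted(self.votes.index[self.votes >= self.min_votes])


def _binary_labels(labels) -> np.ndarray:
    y = pd.Series(labels)
    if set(y.unique()) <= {"R", "NR"}:
        y = (y == "R").astype(int)
    y = y.astype(int).to_numpy()
    if set(np.unique(y)) != {0, 1}:
        raise FitError("both classes must be present")
    return y


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    r = rankdata(scores, method="average")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_auc(scores, labels) -> AUCResult:
    """AUC as the normalized Mann–Whitney U statistic, plus the ROC sweep."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    return AUCResult(
        auc=_rank_auc(scores, y),
        roc_points=np.column_stack([fpr, tpr]),
        n_pos=int(y.sum()),
        n_neg=int(y.size - y.sum()),
    )


def partition_indices(n: int, train_fraction: float = 0.8, seed: int = 0):
    """Random train/validation partition with round-to-nearest train size.

    A merged cohort of 772 patients yields a 618-patient training
    partition under the 80/20 convention (0.8 x 772 = 617.6 rounds up).
    """
    if not (0.0 < train_fraction < 1.0):
        raise InputError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(train_fraction * n + 0.5))
    if n_train == 0 or n_train == n:
        raise InputError("partition would leave an empty split")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def split_cohort(cohort, train_fraction: float = 0.8, seed: int = 0):
    """Split a ResponseCohort into training and validation cohorts."""
    tr, va = partition_indices(len(cohort.patients), train_fraction, seed)
    return cohort.subset(cohort.patients[tr]), cohort.subset(cohort.patients[va])


def _feature_matrix(cohort, genes) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Patients x genes features, gene-standardized within each cohort."""
    present = [g for g in genes if g in cohort.expr.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.warning("%d signature genes absent from cohort and dropped", len(missing))
    if len(present) < 2:
        raise FitError(f"fewer than 2 usable signature genes ({len(present)})")
    X = cohort.expr.loc[present].T.astype(float)
    for _, idx in X.groupby(cohort.cohort_id).groups.items():
        block = X.loc[idx]
        sd = block.std(ddof=0).replace(0.0, 1.0)
        X.loc[idx] = (block - block.mean()) / sd
    y = _binary_labels(cohort.response)
    return X, y, present


def _make_estimator(algo: str, seed: int):
    if algo == "logistic":
        return LogisticRegression(max_iter=2000, solver="liblinear"), \
            {"C": [0.01, 0.1, 1.0, 10.0]}
    if algo == "knn":
        return KNeighborsClassifier(), {"n_neighbors": [5, 15, 25]}
    if algo == "naive_bayes":
        return GaussianNB(), {"var_smoothing": [1e-9, 1e-3]}
    if algo == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed), \
            {"max_depth": [None, 4]}
    raise InputError(f"unknown algorithm {algo!r}")


def _tuned(algo: str, seed: int) -> GridSearchCV:
    est, grid = _make_estimator(algo, seed)
    inner = StratifiedKFold(3, shuffle=True, random_state=seed)
    return GridSearchCV(est, grid, scoring="roc_auc", cv=inner, n_jobs=1)


def _proba(model, X) -> np.ndarray:
    return model.predict_proba(X)[:, list(model.classes_).index(1)]


def train_response_classifier(cohort, sig, algo: str = "logistic",
                              cv: CVConfig | None = None) -> TrainResult:
    """Repeated stratified CV with nested hyperparameter tuning.

    For each repeat, samples are split into ``cv.folds`` stratified folds;
    within each training fold hyperparameters are tuned by an inner
    3-fold grid search, out-of-fold probabilities are pooled, and the
    repeat's AUC is computed from them.  The reported AUC is the mean over
    repeats; the returned model is the tuned estimator refit on all data.
    """
    cv = cv or CVConfig()
    genes = sig.genes if hasattr(sig, "genes") else list(sig)
    X, y, used = _feature_matrix(cohort, genes)
    Xn = X.to_numpy()

    aucs = []
    for seed in cv.seeds:
        skf = StratifiedKFold(cv.folds, shuffle=True, random_state=seed)
        oof = np.full(len(y), np.nan)
        for train, test in skf.split(Xn, y):
            if len(np.unique(y[train])) < 2:
                raise FitError("a training fold lost a class")
            gs = _tuned(algo, seed).fit(Xn[train], y[train])
            oof[test] = _proba(gs, Xn[test])
        aucs.append(_rank_auc(oof, y))

    final = _tuned(algo, cv.seeds[0]).fit(Xn, y)
    return TrainResult(
        model=final, auc=float(np.mean(aucs)), auc_per_repeat=aucs,
        folds=cv.folds, repeats=cv.repeats, genes=used,
    )


def benchmark_signatures(train, holdouts, sigs, algo: str = "logistic",
                         cv: CVConfig | None = None) -> pd.DataFrame:
    """Train one model per signature; evaluate AUC on each holdout cohort.

    Models are trained once on the training cohort and applied to every
    holdout; a signature whose trained genes are absent from a holdout is
    recorded as NaN for that cohort.  Rows are ordered by mean holdout AUC.
    """
    cv = cv or CVConfig()
    if not sigs or not holdouts:
        raise InputError("need at least one signature and one holdout")
    rows = {}
    for sig in sigs:
        name = sig.name if hasattr(sig, "name") else str(sig)
        X, y, used = _feature_matrix(train, sig.genes if hasattr(sig, "genes") else sig)
        model = _tuned(algo, cv.seeds[0]).fit(X.to_numpy(), y)
        row = {}
        for i, hold in enumerate(holdouts):
            hid = str(hold.cohort_id.iloc[0]) if hasattr(hold, "cohort_id") else f"holdout{i}"
            if not set(used) <= set(hold.expr.index):
                row[hid] = float("nan")
                continue
            Xh, yh, _ = _feature_matrix(hold, used)
            row[hid] = evaluate_auc(_proba(model, Xh.to_numpy()), yh).auc
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["mean_auc"] = table.mean(axis=1)
    return table.sort_values("mean_auc", ascending=False)


# --------------------------------------------------------------------------
# feature importance

def _null_threshold(stat_fn, y, rng, n_perm: int, pooled: bool) -> np.ndarray:
    """95th percentile of the label-permutation null of a per-gene statistic.

    With ``pooled`` the null draws of all genes form one distribution (used
    for expensive multivariate scores so fewer refits still give hundreds
    of draws); otherwise each gene keeps its own per-gene null.
    """
    draws = np.stack([stat_fn(rng.permutation(y)) for _ in range(n_perm)])
    if pooled:
        return np.full(draws.shape[1], np.percentile(draws, 95))
    return np.percentile(draws, 95, axis=0)


def rank_feature_importance(cohort, candidates: GeneSet, method: str,
                            seed: int = 0, n_permutations: int = 200,
                            **kwargs) -> pd.DataFrame:
    """Score and select genes by one of five importance methods.

    Methods: per-gene discrimination (``univariate_auc``), L1-logistic
    stability selection (``l1_selection_frequency``), random-forest
    permutation importance (``permutation_importance``), forward wrapper
    selection by CV AUC (``greedy_forward``), and per-gene Gaussian
    naive-Bayes log-likelihood gain (``nb_loglik``).  Except for the
    wrapper (whose stopping rule is its selection criterion), a gene is
    selected when its score exceeds the 95th percentile of a seeded
    label-permutation null.
    """
    if method not in IMPORTANCE_METHODS:
        raise InputError(f"unknown importance method {method!r}")
    X, y, genes = _feature_matrix(cohort, candidates.genes)
    Xn = X.to_numpy()
    rng = np.random.default_rng(seed)
    constant = Xn.std(axis=0) == 0

    if method == "univariate_auc":
        ranks = rankdata(Xn, axis=0)  # precomputed: AUC needs only ranks

        def stat(yy):
            n_pos = yy.sum()
            n_neg = yy.size - n_pos
            u = ranks[yy == 1].sum(axis=0) - n_pos * (n_pos + 1) / 2.0
            return np.abs(u / (n_pos * n_neg) - 0.5)

        score = stat(y)
        thr = _null_threshold(stat, y, rng, n_permutations, pooled=False)
        selected = score > thr

    elif method == "nb_loglik":
        def stat(yy):
            return _nb_gain(Xn, yy)

        score = stat(y)
        thr = _null_threshold(stat, y, rng, n_permutations, pooled=False)
        selected = score > thr

    elif method == "l1_selection_frequency":
        n_sub = kwargs.get("n_subsamples", 30)
        n_perm = kwargs.get("n_null_runs", 20)

        def stat(yy):
            return _l1_frequency(Xn, yy, rng, n_sub)

        score = stat(y)
        thr = _null_threshold(stat, y, rng, n_perm, pooled=True)
        selected = score > thr

    elif method == "permutation_importance":
        n_perm = kwargs.get("n_null_runs", 10)

        def stat(yy):
            rf = RandomForestClassifier(n_estimators=50, random_state=seed).fit(Xn, yy)
            imp = permutation_importance(rf, Xn, yy, n_repeats=3, random_state=seed)
            return np.clip(imp.importances_mean, 0.0, None)

        score = stat(y)
        thr = _null_threshold(stat, y, rng, n_perm, pooled=True)
        selected = score > thr

    else:  # greedy_forward
        score, selected = _greedy_forward(
            Xn, y, seed,
            max_steps=kwargs.get("max_steps", 15),
            min_gain=kwargs.get("min_gain", 0.01),
        )

    score = np.where(constant, 0.0, score)
    selected = np.where(constant, False, selected)
    return pd.DataFrame({"score": score, "selected": selected, "method": method},
                        index=genes)


def _nb_gain(Xn: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian log-likelihood gain of class-conditional densities.

    Profile log-likelihood of the two-class Gaussian model minus the
    pooled single-Gaussian baseline, per observation; class-mean shifts
    shrink the within-class variances, so the gain captures them.
    """
    n = len(y)
    ll_null = -0.5 * n * np.log(Xn.var(axis=0) + 1e-9)
    ll_split = np.zeros_like(ll_null)
    for cls in (0, 1):
        block = Xn[y == cls]
        ll_split += -0.5 * len(block) * np.log(block.var(axis=0) + 1e-9)
    return np.clip((ll_split - ll_null) / n, 0.0, None)


def _l1_fit_support(Xn: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    lr = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=1000)
    return lr.fit(Xn, y).coef_[0] != 0


def _pick_l1_penalty(Xn: np.ndarray, y: np.ndarray) -> float:
    """Smallest C whose full-data support is minimally non-degenerate.

    Keeps the stability selection sparse enough that frequencies do not
    saturate at 1 for every gene (which would make planted and null genes
    indistinguishable); applied identically inside each permutation run.
    """
    p = Xn.shape[1]
    target = max(2, p // 10)
    for C in (0.02, 0.05, 0.1, 0.2, 0.5):
        if int(_l1_fit_support(Xn, y, C).sum()) >= target:
            return C
    return 0.5


def _l1_frequency(Xn: np.ndarray, y: np.ndarray, rng, n_sub: int) -> np.ndarray:
    C = _pick_l1_penalty(Xn, y)
    freq = np.zeros(Xn.shape[1])
    n = len(y)
    for _ in range(n_sub):
        idx = rng.choice(n, size=int(0.8 * n), replace=False)
        if len(np.unique(y[idx])) < 2:
            continue
        freq += _l1_fit_support(Xn[idx], y[idx], C).astype(float)
    return freq / n_sub


def _greedy_forward(Xn: np.ndarray, y: np.ndarray, seed: int,
                    max_steps: int, min_gain: float):
    """Forward wrapper selection by 3-fold CV AUC of a logistic model."""
    skf = StratifiedKFold(3, shuffle=True, random_state=seed)
    splits = list(skf.split(Xn, y))

    def cv_auc(cols):
        oof = np.full(len(y), np.nan)
        for train, test in splits:
            lr = LogisticRegression(max_iter=1000, solver="liblinear")
            lr.fit(Xn[np.ix_(train, cols)], y[train])
            oof[test] = _proba(lr, Xn[np.ix_(test, cols)])
        return _rank_auc(oof, y)

    p = Xn.shape[1]
    chosen: list[int] = []
    score = np.zeros(p)
    best = 0.5
    for _ in range(min(max_steps, p)):
        gains = np.full(p, -np.inf)
        for j in range(p):
            if j in chosen:
                continue
            gains[j] = cv_auc(chosen + [j]) - best
        j_best = int(np.argmax(gains))
        if gains[j_best] < min_gain:
            break
        chosen.append(j_best)
        score[j_best] = gains[j_best]
        best += gains[j_best]
    selected = np.zeros(p, dtype=bool)
    selected[chosen] = True
    return score, selected


def consensus_hub(tables: list[pd.DataFrame], min_votes: int = 3) -> HubSet:
    """Majority-vote consensus: retain genes selected by >= ``min_votes`` methods."""
    if len(tables) < min_votes:
        raise InputError(f"need >= {min_votes} importance tables, got {len(tables)}")
    index = tables[0].index
    for t in tables[1:]:
        if not t.index.equals(index):
            raise InputError("importance tables cover different candidate genes")
    votes = sum(t["selected"].astype(int) for t in tables)
    return HubSet(votes=votes.rename("votes"), min_votes=min_votes)
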