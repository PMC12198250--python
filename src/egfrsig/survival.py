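"""Survival machinery: penalized Cox signatures, risk scores, stratification.

The prognostic signature is an L1-penalized (or elastic-net) Cox model over
standardized gene expression; the penalty strength is chosen by repeated
k-fold cross-validated partial-likelihood deviance (Verweij–van
Houwelingen).  A patient's risk score is the linear combination
``sum_i beta_i * expression_i`` over signature genes; patients are split
into high/low risk at the median score (or a maximally selected log-rank
cutoff) and compared by Kaplan–Meier curves, the log-rank test and
Harrell's concordance index.

Ties in the partial likelihood are handled with the Breslow approximation
throughout, which keeps the likelihood identical to the brute-force form
used for verification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_concordance
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .errors import FitError, InputError, PipelineError

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalData", "CoxFit", "RiskGroups", "KMCurve", "LogrankResult",
    "breslow_loglik", "fit_l1_cox", "risk_score", "split_by_cutoff",
    "km_estimate", "logrank_test", "cindex", "newton_cox", "stepwise_cox",
    "benchmark_prognostic_models",
]


@dataclass
class SurvivalData:
    """Per-patient follow-up time (days), event indicator and endpoint label."""

    time: pd.Series
    event: pd.Series
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        self.time = pd.Series(self.time, dtype=float)
        self.event = pd.Series(self.event, dtype=int).reindex(self.time.index)
        if (self.time <= 0).any():
            raise InputError("survival times must be positive")
        if not self.event.isin([0, 1]).all():
            raise InputError("event indicator must be 0/1")
        if self.endpoint not in {"DSS", "PFI", "OS"}:
            raise InputError(f"unknown endpoint {self.endpoint!r}")

    @property
    def patients(self) -> pd.Index:
        return self.time.index

    def subset(self, ids) -> "SurvivalData":
        return SurvivalData(self.time.loc[ids], self.event.loc[ids], self.endpoint)

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class CoxFit:
    """Penalized Cox coefficients on standardized expression.

    ``beta`` applies to ``(x - gene_means) / gene_sds``; ``selection_frequency``
    is the fraction of cross-validation fits in which a gene's coefficient
    was nonzero at the chosen penalty.
    """

    beta: pd.Series
    lambda_: float
    alpha: float
    selection_frequency: pd.Series = None
    gene_means: pd.Series = None
    gene_sds: pd.Series = None

    def __post_init__(self) -> None:
        if self.gene_means is None:
            self.gene_means = pd.Series(0.0, index=self.beta.index)
        if self.gene_sds is None:
            self.gene_sds = pd.Series(1.0, index=self.beta.index)

    @property
    def genes(self) -> list[str]:
        return list(self.beta.index)

    @property
    def selected(self) -> list[str]:
        return list(self.beta.index[self.beta != 0])


@dataclass
class RiskGroups:
    labels: pd.Series  # "high" / "low" per patient
    cutoff: float
    method: str


@dataclass
class KMCurve:
    """Product-limit estimate: S(0)=1 and a step down at each event time."""

    times: np.ndarray       # ordered distinct event times
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


class LogrankResult(NamedTuple):
    statistic: float
    p: float


def breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood with Breslow handling of tied event times."""
    eta = np.asarray(eta, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="mergesort")
    t_s, eta_s, e_s = time[order], eta[order], event[order]
    # log-sum-exp over the risk set {j : t_j >= t_i}; ties share a risk set
    rev_lse = np.logaddexp.accumulate(eta_s[::-1])[::-1]
    first_of_tie = np.searchsorted(t_s, t_s, side="left")
    lse_at = rev_lse[first_of_tie]
    mask = e_s == 1
    return float(np.sum(eta_s[mask] - lse_at[mask]))


def _standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (X - mu) / sd, mu, sd


def _surv_y(surv: SurvivalData):
    return Surv.from_arrays(surv.event.to_numpy().astype(bool), surv.time.to_numpy())


def fit_l1_cox(
    expr: pd.DataFrame,
    surv: SurvivalData,
    alpha: float = 1.0,
    cv_folds: int = 10,
    iterations: int = 25,
    seed: int = 0,
    n_lambdas: int = 50,
) -> CoxFit:
    """Cross-validated L1 (or elastic-net) Cox fit.

    Genes are standardized before penalization.  The penalty ``lambda`` is
    chosen to minimize the cross-validated partial-likelihood deviance,
    averaged over ``iterations`` re-randomized fold assignments (the
    full-scale convention is 1000 iterations; 25 keeps routine runs fast
    and is the packaged default).  ``alpha`` is the elastic-net mixing (1.0 = lasso).

    Returns the refit coefficients at the chosen penalty plus per-gene
    selection frequencies across all cross-validation fits.
    """
    if not (0.0 < alpha <= 1.0):
        raise InputError(f"elastic-net mixing alpha must be in (0, 1], got {alpha}")
    X = expr.T.loc[surv.patients].astype(float)
    n, p = X.shape
    if surv.event.sum() < 2:
        raise FitError("need at least 2 events to fit a Cox model")
    if n < cv_folds:
        raise FitError(f"fewer patients ({n}) than folds ({cv_folds})")

    Xs, mu, sd = _standardize(X)
    y = _surv_y(surv)
    time = surv.time.to_numpy()
    event = surv.event.to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path = CoxnetSurvivalAnalysis(
            l1_ratio=alpha, n_alphas=n_lambdas, alpha_min_ratio=0.01,
            fit_baseline_model=False,
        ).fit(Xs.to_numpy(), y)
    lambdas = np.asarray(path.alphas_)

    rng = np.random.default_rng(seed)
    deviance = np.zeros(len(lambdas))
    counts = np.zeros(len(lambdas))
    nonzero = np.zeros((len(lambdas), p))
    n_fits = 0
    for _ in range(iterations):
        perm = rng.permutation(n)
        for fold in np.array_split(perm, cv_folds):
            train = np.setdiff1d(np.arange(n), fold)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = CoxnetSurvivalAnalysis(
                    l1_ratio=alpha, alphas=lambdas, fit_baseline_model=False
                ).fit(Xs.to_numpy()[train], y[train])
            coefs = m.coef_  # (p, n_fitted); the solver may truncate the path
            etas = Xs.to_numpy() @ coefs
            for kf, lam in enumerate(np.asarray(m.alphas_)):
                k = int(np.argmin(np.abs(lambdas - lam)))
                ll_full = breslow_loglik(etas[:, kf], time, event)
                ll_train = breslow_loglik(etas[train, kf], time[train], event[train])
                deviance[k] += -2.0 * (ll_full - ll_train)
                counts[k] += 1
                nonzero[k] += coefs[:, kf] != 0
            n_fits += 1

    # prefer penalties evaluated in every fold
    full = counts == counts.max()
    mean_dev = np.where(full, deviance / np.maximum(counts, 1), np.inf)
    best = int(np.argmin(mean_dev))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = CoxnetSurvivalAnalysis(
            l1_ratio=alpha, alphas=[lambdas[best]], fit_baseline_model=False
        ).fit(Xs.to_numpy(), y)
    beta = pd.Series(final.coef_[:, 0], index=X.columns, name="beta")
    return CoxFit(
        beta=beta,
        lambda_=float(lambdas[best]),
        alpha=alpha,
        selection_frequency=pd.Series(nonzero[best] / max(counts[best], 1),
                                      index=X.columns),
        gene_means=mu,
        gene_sds=sd,
    )


def risk_score(expr: pd.DataFrame, fit: CoxFit) -> pd.Series:
    """Linear risk score ``sum_i beta_i * standardized expression_i``.

    Every fit gene must be present in the matrix; missing genes raise an
    error naming them rather than being silently dropped.
    """
    missing = [g for g in fit.genes if g not in expr.index]
    if missing:
        raise FitError(f"expression matrix lacks fit genes: {missing}")
    X = expr.loc[fit.genes].T.astype(float)
    Xs = (X - fit.gene_means) / fit.gene_sds
    return pd.Series(Xs.to_numpy() @ fit.beta.to_numpy(), index=X.index, name="risk_score")


def split_by_cutoff(scores: pd.Series, surv: SurvivalData, method: str = "median") -> RiskGroups:
    """High/low risk split at the median or at the best log-rank cutoff.

    ``median``: the cutoff is the median score; scores equal to the cutoff
    go to the low-risk group.  ``best``: the cutoff maximizing the two-group
    log-rank statistic, searched over distinct score values between the
    10th and 90th percentiles (the restriction avoids degenerate splits;
    the resulting log-rank p-value is descriptive only, since the cutoff
    was selected to maximize it).
    """
    scores = scores.loc[surv.patients]
    if method == "median":
        cutoff = float(scores.median())
    elif method == "best":
        lo, hi = np.percentile(scores, [10, 90])
        candidates = sorted(set(scores[(scores >= lo) & (scores <= hi)]))
        best_stat, cutoff = -np.inf, None
        for c in candidates:
            high = scores > c
            if high.sum() < 2 or (~high).sum() < 2:
                continue
            stat = _logrank_arrays(surv, high).statistic
            if stat > best_stat:
                best_stat, cutoff = stat, float(c)
        if cutoff is None:
            raise PipelineError("no cutoff yields two groups of >= 2 patients")
    else:
        raise InputError(f"unknown cutoff method {method!r}")

    labels = pd.Series(np.where(scores > cutoff, "high", "low"), index=scores.index)
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise PipelineError(f"degenerate split at cutoff {cutoff}")
    return RiskGroups(labels=labels, cutoff=cutoff, method=method)


def km_estimate(surv: SurvivalData) -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    Patients censored exactly at an event time are counted as still at
    risk at that time (the standard convention).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    survival = np.array([float(sf.loc[t]) for t in times])
    return KMCurve(
        times=times,
        survival=survival,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
    )


def _logrank_arrays(surv: SurvivalData, high: pd.Series) -> LogrankResult:
    res = _ll_logrank(
        surv.time[high], surv.time[~high],
        event_observed_A=surv.event[high], event_observed_B=surv.event[~high],
    )
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def logrank_test(groups: RiskGroups, surv: SurvivalData) -> LogrankResult:
    """Two-group log-rank test (chi-square with 1 df)."""
    high = (groups.labels.loc[surv.patients] == "high")
    if high.sum() == 0 or (~high).sum() == 0:
        raise InputError("both risk groups must be non-empty")
    return _logrank_arrays(surv, high)


def cindex(scores: pd.Series, surv: SurvivalData) -> float:
    """Harrell's concordance index: higher score should mean shorter survival.

    Usable pairs follow Harrell (the shorter time must be an event);
    score ties receive half credit.
    """
    scores = scores.loc[surv.patients]
    try:
        return float(
            _ll_concordance(surv.time, -scores.to_numpy(), surv.event)
        )
    except ZeroDivisionError as exc:
        raise FitError("no usable pairs for concordance") from exc


def newton_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
               max_iter: int = 50, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Unpenalized Cox fit (Breslow ties) by Newton–Raphson.

    Returns ``(beta, partial log-likelihood)``.  Intended for the small
    design matrices of stepwise selection; a tiny ridge stabilizes the
    Hessian against collinear candidates.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    order = np.argsort(time, kind="mergesort")
    Xs, t_s, e_s = X[order], np.asarray(time, float)[order], np.asarray(event, int)[order]
    first_of_tie = np.searchsorted(t_s, t_s, side="left")
    ev = e_s == 1
    beta = np.zeros(p)

    def _ll_grad_hess(b):
        eta = Xs @ b
        w = np.exp(eta - eta.max())
        # reverse-cumulative risk-set sums, evaluated at each tie block start
        s0 = np.cumsum(w[::-1])[::-1][first_of_tie]
        s1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1][first_of_tie]
        xw = w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
        s2 = np.cumsum(xw[::-1], axis=0)[::-1][first_of_tie]
        mean = s1 / s0[:, None]
        ll = float(np.sum(eta[ev] - (np.log(s0[ev]) + eta.max())))
        grad = (Xs[ev] - mean[ev]).sum(axis=0)
        hess = -(s2[ev] / s0[ev, None, None]
                 - mean[ev][:, :, None] * mean[ev][:, None, :]).sum(axis=0)
        return ll, grad, hess

    ll, grad, hess = _ll_grad_hess(beta)
    for _ in range(max_iter):
        step = np.linalg.solve(hess - 1e-9 * np.eye(p), grad)
        new_beta = beta - step
        new_ll, new_grad, new_hess = _ll_grad_hess(new_beta)
        halvings = 0
        while new_ll < ll and halvings < 10:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _ll_grad_hess(new_beta)
            halvings += 1
        converged = abs(new_ll - ll) < tol
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if converged:
            break
    return beta, ll


def stepwise_cox(X: pd.DataFrame, surv: SurvivalData, max_steps: int = 1000) -> pd.Series:
    """Forward stepwise Cox selection by AIC.

    Adds one covariate per step while the partial-likelihood AIC
    (``-2 ll + 2k``) improves, up to ``max_steps`` steps.  Returns
    coefficients over all columns with zeros for unselected covariates.
    """
    Xf = X.loc[surv.patients].astype(float)
    time, event = surv.time.to_numpy(), surv.event.to_numpy()
    selected: list[str] = []
    remaining = list(X.columns)
    best_aic = -2.0 * breslow_loglik(np.zeros(len(Xf)), time, event)
    beta = pd.Series(0.0, index=X.columns)
    best_beta = None
    for _ in range(min(max_steps, len(remaining))):
        trial = (np.inf, None, None)
        for gene in remaining:
            cols = selected + [gene]
            try:
                b, ll = newton_cox(Xf[cols].to_numpy(), time, event)
            except np.linalg.LinAlgError:
                continue
            aic = -2.0 * ll + 2.0 * len(cols)
            if aic < trial[0]:
                trial = (aic, gene, b)
        if trial[1] is None or trial[0] >= best_aic:
            break
        best_aic, gene, best_beta = trial
        selected.append(gene)
        remaining.remove(gene)
    if best_beta is not None:
        beta[:] = 0.0
        beta[selected] = best_beta
    return beta


def _coxnet_cv_lambda(Xs: np.ndarray, y, time, event, alpha: float, folds: int, rng) -> float:
    """Pick a Coxnet penalty by one round of k-fold VVH deviance."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path = CoxnetSurvivalAnalysis(
            l1_ratio=alpha, n_alphas=30, alpha_min_ratio=0.05, fit_baseline_model=False
        ).fit(Xs, y)
    lambdas = np.asarray(path.alphas_)
    dev = np.zeros(len(lambdas))
    counts = np.zeros(len(lambdas))
    n = len(time)
    perm = rng.permutation(n)
    for fold in np.array_split(perm, folds):
        train = np.setdiff1d(np.arange(n), fold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = CoxnetSurvivalAnalysis(
                l1_ratio=alpha, alphas=lambdas, fit_baseline_model=False
            ).fit(Xs[train], y[train])
        etas = Xs @ m.coef_
        for kf, lam in enumerate(np.asarray(m.alphas_)):
            k = int(np.argmin(np.abs(lambdas - lam)))
            dev[k] += -2.0 * (
                breslow_loglik(etas[:, kf], time, event)
                - breslow_loglik(etas[train, kf], time[train], event[train])
            )
            counts[k] += 1
    mean_dev = np.where(counts == counts.max(), dev / np.maximum(counts, 1), np.inf)
    return float(lambdas[int(np.argmin(mean_dev))])


def benchmark_prognostic_models(
    expr: pd.DataFrame,
    surv: SurvivalData,
    alphas: Iterable[float] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1)),
    include_stepwise: bool = True,
    seed: int = 0,
    loo_max_n: int = 300,
) -> pd.DataFrame:
    """Concordance comparison of an elastic-net alpha grid plus stepwise Cox.

    Each model's out-of-fold risk scores are pooled into a single Harrell
    C-index.  Cross-validation is leave-one-out for n <= ``loo_max_n`` and
    10-fold otherwise.  ``alpha = 0`` is fit as a pure ridge Cox model; all
    other alphas go through the elastic-net path with an inner
    cross-validated penalty choice.  Per-model failures are recorded as NaN
    without aborting the grid.
    """
    X = expr.T.loc[surv.patients].astype(float)
    Xs, _, _ = _standardize(X)
    Xn = Xs.to_numpy()
    time, event = surv.time.to_numpy(), surv.event.to_numpy()
    n = len(X)

    if n <= loo_max_n:
        splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        kf = KFold(n_splits=10, shuffle=True, random_state=seed)
        splits = list(kf.split(Xn))

    models: dict[str, float] = {}

    def _run(name, fit_predict):
        oof = np.full(n, np.nan)
        try:
            for train, test in splits:
                oof[test] = fit_predict(train, test)
            models[name] = cindex(
                pd.Series(oof, index=surv.patients), surv
            )
        except Exception as exc:
            logger.warning("model %s failed: %s", name, exc)
            models[name] = float("nan")

    y = _surv_y(surv)
    for a in alphas:
        a = float(a)
        if a == 0.0:
            def _ridge(train, test):
                best_ll, best_eta = -np.inf, None
                for pen in (0.1, 1.0, 10.0):
                    m = CoxPHSurvivalAnalysis(alpha=pen, ties="breslow")
                    m.fit(Xn[train], y[train])
                    ll = breslow_loglik(Xn[train] @ m.coef_, time[train], event[train])
                    if ll > best_ll:
                        best_ll, best_eta = ll, Xn[test] @ m.coef_
                return best_eta
            _run("enet_a0.0", _ridge)
        else:
            def _enet(train, test, a=a):
                rng = np.random.default_rng(seed)
                lam = _coxnet_cv_lambda(Xn[train], y[train], time[train], event[train],
                                        a, folds=5, rng=rng)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = CoxnetSurvivalAnalysis(
                        l1_ratio=a, alphas=[lam], fit_baseline_model=False
                    ).fit(Xn[train], y[train])
                return Xn[test] @ m.coef_[:, 0]
            _run(f"enet_a{a:.1f}", _enet)

    if include_stepwise:
        def _step(train, test):
            beta = stepwise_cox(
                Xs.iloc[train], SurvivalData(surv.time.iloc[train],
                                             surv.event.iloc[train], surv.endpoint)
            )
            return Xn[test] @ beta.to_numpy()
        _run("stepwise_cox", _step)

    out = pd.DataFrame.from_dict(models, orient="index", columns=["cindex"])
    out.attrs["best_model"] = out["cindex"].idxmax()
    return out
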