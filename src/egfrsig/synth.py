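"""Synthetic cohorts with planted ground truth.

Three generators emulate the pipeline's inputs:

* single-cell tumor cohorts (malignant / immune / stromal cells) with a
  per-cell latent EGFR-activity scalar, a planted subset of genes whose
  within-cell-type Spearman correlation with that scalar is controlled
  exactly (Gaussian copula; Pearson rho set to ``2 sin(pi rho_s / 6)`` so
  the configured value is the Spearman coefficient), and a planted subset
  of malignant-up-regulated genes with a configured mean log2 shift;
* bulk immunotherapy (ICI) cohorts in which the log-odds of RECIST
  response and the log-hazard of survival are linear in a planted gene
  subset, with independent exponential censoring tuned to a target rate;
* CRISPR screen sets with planted negative-LFC resistance genes and
  configurable missingness.

Every generator is a deterministic function of ``SimConfig.seed``, and
each output carries a :class:`TruthRecord` of the planted structure so
downstream recovery can be tested without external data.

Correlation is planted against the *within-cell-type residual* of the
activity scalar, so correlation-only genes acquire no incidental
malignant shift; the recovery truth for signature derivation is exactly
the set of genes planted with both correlation and differential
expression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .survival import SurvivalData

__all__ = [
    "SimConfig", "TruthRecord", "ScCohort", "ResponseCohort", "CrisprScreenSet",
    "simulate_sc_cohort", "simulate_ici_cohort", "simulate_crispr_screens",
    "write_sc_cohort", "write_ici_cohort", "write_crispr_screens",
]

_CELL_TYPES = ("malignant", "immune", "stromal")


@dataclass
class SimConfig:
    """All knobs of the synthetic generators; the seed fully determines output."""

    n_genes: int = 1000
    n_cells: int = 2000
    n_samples: int = 600
    cell_type_proportions: dict = field(
        default_factory=lambda: {"malignant": 0.5, "immune": 0.35, "stromal": 0.15}
    )
    # single-cell plantings
    n_corr_genes: int = 12
    corr_strength: float = 0.7
    n_de_genes: int = 12
    de_log2fc: float = 1.0
    malignant_activity_shift: float = 1.5
    # bulk ICI plantings
    n_planted_genes: int = 8
    response_effect: float = 1.0
    hazard_effect: float = 1.0
    response_rate: float = 0.4
    censoring_rate: float = 0.3
    # CRISPR plantings
    n_screens: int = 17
    n_resistance_genes: int = 60
    resistance_effect: float = -2.0
    missing_rate: float = 0.1
    # shared
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells", "n_samples", "n_screens"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        props = self.cell_type_proportions
        if set(props) != set(_CELL_TYPES):
            raise ConfigError(f"cell_type_proportions must cover {_CELL_TYPES}")
        if abs(sum(props.values()) - 1.0) > 1e-9 or any(v < 0 for v in props.values()):
            raise ConfigError("cell_type_proportions must be a simplex")
        for name in ("n_corr_genes", "n_de_genes", "n_planted_genes", "n_resistance_genes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not (0.0 <= self.corr_strength < 1.0):
            raise ConfigError("corr_strength must be in [0, 1)")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ConfigError("censoring_rate must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1) (1 would lose genes)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.n_planted_genes == 0 and (self.response_effect or self.hazard_effect):
            raise ConfigError("nonzero effect requested with an empty planted set")


@dataclass
class TruthRecord:
    """The generator's planted parameters, for recovery tests."""

    corr_genes: dict = field(default_factory=dict)       # gene -> Spearman strength
    de_genes: dict = field(default_factory=dict)         # gene -> log2 shift
    response_genes: dict = field(default_factory=dict)   # gene -> log-odds effect
    hazard_genes: dict = field(default_factory=dict)     # gene -> log-HR
    resistance_genes: dict = field(default_factory=dict) # gene -> LFC effect
    activity: pd.Series | None = None                    # per-cell latent EGFR activity

    @property
    def signature_genes(self) -> list[str]:
        """Genes planted with both correlation and malignant up-regulation."""
        return sorted(set(self.corr_genes) & set(self.de_genes))

    def subset_cells(self, cells) -> "TruthRecord":
        act = None if self.activity is None else self.activity.loc[cells]
        return TruthRecord(self.corr_genes, self.de_genes, self.response_genes,
                           self.hazard_genes, self.resistance_genes, act)

    def to_json(self, path: str | Path) -> None:
        d = {k: v for k, v in asdict(self).items() if k != "activity"}
        if self.activity is not None:
            d["activity"] = {str(k): float(v) for k, v in self.activity.items()}
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


@dataclass
class ScCohort:
    """A single-cell cohort: log-normalized expression plus annotations."""

    expr: pd.DataFrame          # genes x cells, non-negative log scale
    cell_labels: pd.Series      # malignant / immune / stromal
    mito_fraction: pd.Series
    genes_detected: pd.Series
    truth: TruthRecord

    def __post_init__(self) -> None:
        cells = self.expr.columns
        if not (len(self.cell_labels) == len(self.mito_fraction)
                == len(self.genes_detected) == len(cells)):
            raise ConfigError("annotation vectors must match the cell count")
        if ((self.mito_fraction < 0) | (self.mito_fraction > 1)).any():
            raise ConfigError("mito_fraction must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.expr.shape[1]

    def subset(self, cells) -> "ScCohort":
        return ScCohort(
            expr=self.expr[cells],
            cell_labels=self.cell_labels.loc[cells],
            mito_fraction=self.mito_fraction.loc[cells],
            genes_detected=self.genes_detected.loc[cells],
            truth=self.truth.subset_cells(cells),
        )

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.cell_labels,
            "mito_fraction": self.mito_fraction,
            "genes_detected": self.genes_detected,
        })


@dataclass
class ResponseCohort:
    """A bulk ICI cohort: expression, RECIST categories and survival."""

    expr: pd.DataFrame       # genes x patients
    recist: pd.Series        # CR / PR / SD / PD
    response: pd.Series      # "R" iff recist in {CR, PR}
    cohort_id: pd.Series
    survival: SurvivalData
    truth: TruthRecord

    def __post_init__(self) -> None:
        derived = self.recist.isin(["CR", "PR"]).map({True: "R", False: "NR"})
        if not derived.equals(self.response):
            raise ConfigError("response labels inconsistent with RECIST categories")

    @property
    def patients(self) -> pd.Index:
        return self.expr.columns

    def subset(self, patients) -> "ResponseCohort":
        return ResponseCohort(
            expr=self.expr[patients],
            recist=self.recist.loc[patients],
            response=self.response.loc[patients],
            cohort_id=self.cohort_id.loc[patients],
            survival=self.survival.subset(patients),
            truth=self.truth,
        )

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "recist": self.recist,
            "response": self.response,
            "time_days": self.survival.time,
            "event": self.survival.event,
            "cohort_id": self.cohort_id,
        })


@dataclass
class CrisprScreenSet:
    """Gene x screen log-fold changes; NaN marks unmeasured entries."""

    lfc: pd.DataFrame
    truth: TruthRecord

    def __post_init__(self) -> None:
        if (self.lfc.notna().sum(axis=1) == 0).any():
            raise ConfigError("every retained gene needs >= 1 observed value")

    @property
    def screen_ids(self) -> list[str]:
        return list(self.lfc.columns)


def _gene_names(config: SimConfig, gene_names=None) -> list[str]:
    if gene_names is not None:
        names = [str(g).upper() for g in gene_names]
        if len(names) != config.n_genes:
            raise ConfigError(
                f"gene_names has {len(names)} entries, config.n_genes={config.n_genes}"
            )
        if len(set(names)) != len(names):
            raise ConfigError("gene_names must be unique")
        return names
    width = len(str(config.n_genes))
    return [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]


def _background_expr(rng, n_genes: int, n_obs: int) -> np.ndarray:
    """log2(1 + counts) of negative-binomial-like background expression."""
    base_mean = rng.lognormal(mean=np.log(5.0), sigma=0.5, size=n_genes)
    r = 4.0  # NB dispersion (size); moderate overdispersion
    p = r / (r + base_mean)
    counts = rng.negative_binomial(r, p[:, None], size=(n_genes, n_obs))
    return np.log2(1.0 + counts)


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula Pearson coefficient yielding the target Spearman."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def simulate_sc_cohort(config: SimConfig, gene_names=None) -> ScCohort:
    """Simulate one single-cell tumor cohort with planted structure.

    Malignant cells carry an elevated latent EGFR-activity scalar.  The
    first ``n_corr_genes`` genes follow a Gaussian copula with the
    activity residual at the configured Spearman strength; the first
    ``n_de_genes`` genes get a ``de_log2fc`` additive shift in malignant
    cells.  The two planted prefixes overlap, so genes planted with both
    roles form the recoverable signature truth.
    """
    if max(config.n_corr_genes, config.n_de_genes) > config.n_genes:
        raise ConfigError("planted gene counts exceed n_genes")
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config, gene_names)
    cells = [f"C{i + 1:05d}" for i in range(config.n_cells)]

    props = [config.cell_type_proportions[t] for t in _CELL_TYPES]
    labels = rng.choice(_CELL_TYPES, size=config.n_cells, p=props)
    is_mal = labels == "malignant"

    residual = rng.normal(size=config.n_cells)
    activity = config.malignant_activity_shift * is_mal + residual

    expr = _background_expr(rng, config.n_genes, config.n_cells)

    planted = sorted(set(range(config.n_corr_genes)) | set(range(config.n_de_genes)))
    rho_p = _spearman_to_pearson(config.corr_strength)
    for g in planted:
        eps = rng.normal(size=config.n_cells)
        if g < config.n_corr_genes and config.corr_strength > 0:
            latent = rho_p * residual + np.sqrt(1.0 - rho_p ** 2) * eps
        else:
            latent = eps
        x = 3.0 + latent
        if g < config.n_de_genes:
            x = x + config.de_log2fc * is_mal
        expr[g] = np.clip(x, 0.0, None)

    mito = rng.beta(1.5, 20.0, size=config.n_cells)
    detected = rng.negative_binomial(12, 12 / (12 + 1400), size=config.n_cells)

    truth = TruthRecord(
        corr_genes={genes[i]: config.corr_strength for i in range(config.n_corr_genes)},
        de_genes={genes[i]: config.de_log2fc for i in range(config.n_de_genes)},
        activity=pd.Series(activity, index=cells, name="activity"),
    )
    return ScCohort(
        expr=pd.DataFrame(expr, index=genes, columns=cells),
        cell_labels=pd.Series(labels, index=cells, name="label"),
        mito_fraction=pd.Series(mito, index=cells, name="mito_fraction"),
        genes_detected=pd.Series(detected, index=cells, name="genes_detected"),
        truth=truth,
    )


def _solve_censoring_rate(rng, event_rates: np.ndarray, target: float) -> np.ndarray:
    """Exponential censoring times whose expected censored fraction is ``target``."""
    if target == 0.0:
        return np.full(event_rates.size, np.inf)
    lo, hi = 1e-12, 1e6 * event_rates.max()
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        frac = float(np.mean(mid / (mid + event_rates)))
        if frac < target:
            lo = mid
        else:
            hi = mid
    return rng.exponential(scale=1.0 / mid, size=event_rates.size)


def simulate_ici_cohort(config: SimConfig, cohort_id: str = "cohort1",
                        n: int | None = None, gene_names=None) -> ResponseCohort:
    """Simulate one bulk ICI cohort with planted response and hazard effects.

    Response probability is ``logistic(logit(response_rate) +
    sum_g effect * z_g)`` over the standardized planted-gene expression;
    survival times are exponential with hazard proportional to
    ``exp(sum_g hazard * z_g)``, censored by an independent exponential
    tuned to the configured censoring rate.  RECIST categories are drawn
    consistently with the binary label (responders 30% CR / 70% PR,
    nonresponders 50% SD / 50% PD).
    """
    if config.n_planted_genes > config.n_genes:
        raise ConfigError("planted gene count exceeds n_genes")
    rng = np.random.default_rng(config.seed)
    n = config.n_samples if n is None else n
    genes = _gene_names(config, gene_names)
    patients = [f"{cohort_id}_P{i + 1:04d}" for i in range(n)]

    expr = _background_expr(rng, config.n_genes, n)
    k = config.n_planted_genes
    for g in range(k):
        expr[g] = np.clip(3.0 + rng.normal(scale=1.0, size=n)
                          + rng.normal(scale=config.noise_sd, size=n), 0.0, None)

    z = np.zeros(n)
    lp_hazard = np.zeros(n)
    if k:
        block = expr[:k]
        zb = (block - block.mean(axis=1, keepdims=True)) / block.std(axis=1, keepdims=True)
        z = config.response_effect * zb.sum(axis=0)
        lp_hazard = config.hazard_effect * zb.sum(axis=0)

    eta = np.log(config.response_rate / (1.0 - config.response_rate)) + z
    responder = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    recist = np.where(
        responder,
        rng.choice(["CR", "PR"], size=n, p=[0.3, 0.7]),
        rng.choice(["SD", "PD"], size=n, p=[0.5, 0.5]),
    )

    base_rate = 1.0 / 365.0
    rates = base_rate * np.exp(lp_hazard)
    t_event = rng.exponential(scale=1.0 / rates)
    t_cens = _solve_censoring_rate(rng, rates, config.censoring_rate)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time * 1.0, 1e-3)  # keep times strictly positive

    truth = TruthRecord(
        response_genes={genes[i]: config.response_effect for i in range(k)},
        hazard_genes={genes[i]: config.hazard_effect for i in range(k)},
    )
    surv = SurvivalData(
        pd.Series(time, index=patients, name="time_days"),
        pd.Series(event, index=patients, name="event"),
        endpoint="OS",
    )
    recist_s = pd.Series(recist, index=patients, name="recist")
    return ResponseCohort(
        expr=pd.DataFrame(expr, index=genes, columns=patients),
        recist=recist_s,
        response=recist_s.isin(["CR", "PR"]).map({True: "R", False: "NR"}),
        cohort_id=pd.Series(cohort_id, index=patients, name="cohort_id"),
        survival=surv,
        truth=truth,
    )


def simulate_crispr_screens(config: SimConfig, gene_names=None,
                            resistance_genes=None) -> CrisprScreenSet:
    """Simulate a CRISPR screen set with planted resistance genes.

    Planted genes get a ``resistance_effect`` (negative) mean log-fold
    change across screens plus N(0, noise_sd) noise; entries go missing
    independently at ``missing_rate``, except that each gene keeps at
    least one observation.
    """
    if resistance_genes is None and config.n_resistance_genes > config.n_genes:
        raise ConfigError("planted resistance count exceeds n_genes")
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config, gene_names)
    screens = [f"S{j + 1:02d}" for j in range(config.n_screens)]

    if resistance_genes is not None:
        resistance = [str(g).upper() for g in resistance_genes]
        unknown = sorted(set(resistance) - set(genes))
        if unknown:
            raise ConfigError(f"resistance genes not in the gene universe: {unknown}")
    else:
        resistance = genes[: config.n_resistance_genes]
    res_mask = np.isin(genes, resistance)

    lfc = rng.normal(scale=config.noise_sd, size=(config.n_genes, config.n_screens))
    lfc[res_mask] += config.resistance_effect

    missing = rng.random(lfc.shape) < config.missing_rate
    all_gone = missing.all(axis=1)
    if all_gone.any():
        keep_col = rng.integers(0, config.n_screens, size=int(all_gone.sum()))
        missing[np.where(all_gone)[0], keep_col] = False
    lfc = np.where(missing, np.nan, lfc)

    truth = TruthRecord(
        resistance_genes={g: config.resistance_effect for g in resistance}
    )
    return CrisprScreenSet(
        lfc=pd.DataFrame(lfc, index=genes, columns=screens), truth=truth
    )


# --------------------------------------------------------------------------
# writers (thin wrappers for the CLI)

def write_sc_cohort(cohort: ScCohort, outdir: str | Path) -> None:
    from . import io
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_expression(cohort.expr, outdir / "expression.tsv")
    io.write_annotation(cohort.annotation_frame(), outdir / "annotation.tsv")
    cohort.truth.to_json(outdir / "truth.json")


def write_ici_cohort(cohort: ResponseCohort, outdir: str | Path) -> None:
    from . import io
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_expression(cohort.expr, outdir / "expression.tsv")
    io.write_clinical(cohort.clinical_frame(), outdir / "clinical.tsv")
    cohort.truth.to_json(outdir / "truth.json")


def write_crispr_screens(screens: CrisprScreenSet, outdir: str | Path) -> None:
    from . import io
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_crispr(screens.lfc, outdir / "crispr_lfc.tsv")
    screens.truth.to_json(outdir / "truth.json")
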