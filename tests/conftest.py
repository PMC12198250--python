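"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

import egfrsig as es


@pytest.fixture(scope="session")
def sc_cohort():
    """Small single-cell cohort with 6 planted correlated+DE genes."""
    cfg = es.SimConfig(
        n_genes=80, n_cells=600, n_corr_genes=6, n_de_genes=6,
        corr_strength=0.7, de_log2fc=1.0, seed=101,
    )
    return es.simulate_sc_cohort(cfg)


@pytest.fixture(scope="session")
def ici_cohort():
    """Bulk ICI cohort with planted response/hazard effects."""
    cfg = es.SimConfig(
        n_genes=40, n_samples=300, n_planted_genes=5,
        response_effect=0.8, hazard_effect=0.8, seed=202,
    )
    return es.simulate_ici_cohort(cfg, cohort_id="train")


@pytest.fixture(scope="session")
def null_ici_cohort():
    """Bulk ICI cohort with no planted effects (labels independent of genes)."""
    cfg = es.SimConfig(
        n_genes=40, n_samples=300, n_planted_genes=5,
        response_effect=0.0, hazard_effect=0.0, seed=303,
    )
    return es.simulate_ici_cohort(cfg, cohort_id="null")


@pytest.fixture(scope="session")
def crispr_set():
    cfg = es.SimConfig(
        n_genes=500, n_screens=17, n_resistance_genes=25,
        resistance_effect=-2.0, noise_sd=0.5, missing_rate=0.1, seed=404,
    )
    return es.simulate_crispr_screens(cfg)


@pytest.fixture
def tiny_expr():
    """4-gene, 2-sample matrix for hand-checkable scoring."""
    return pd.DataFrame(
        {"s1": [4.0, 3.0, 2.0, 1.0], "s2": [4.0, 3.0, 2.0, 1.0]},
        index=["G1", "G2", "G3", "G4"],
    )


@pytest.fixture
def surv_simple():
    """Three patients, times 1 < 2 < 3, all events."""
    return es.SurvivalData(
        pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"]),
        pd.Series([1, 1, 1], index=["a", "b", "c"]),
    )
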