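"""CRISPR-screen aggregation and immune-resistance ranking.

Genome-wide knockout screens report per-gene log-fold changes of sgRNA
abundance under immune pressure.  To compare across heterogeneous screens,
each screen column is z-normalized over its observed values; genes are
then ranked from low to high by their mean z across the screens where they
were measured.  Low mean z means knockout sensitizes the tumor to immune
killing, so top-ranked genes are "immune resistance" genes; the first 6%
of ranks are flagged, and the flagged proportion within a gene signature
measures how enriched that signature is for such genes.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import InputError
from .score import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["normalize_screens", "rank_genes", "flag_top", "signature_enrichment"]


def normalize_screens(screens) -> pd.DataFrame:
    """Per-screen z-normalization of log-fold changes.

    Each column's observed values are centered to mean 0 and scaled to unit
    sample (n-1) standard deviation; missing entries stay missing.  A
    zero-variance column is set to all zeros with a warning.
    """
    lfc = screens.lfc if hasattr(screens, "lfc") else screens
    z = pd.DataFrame(index=lfc.index, columns=lfc.columns, dtype=float)
    for col in lfc.columns:
        x = lfc[col]
        obs = x.notna()
        if int(obs.sum()) < 2:
            raise InputError(f"screen {col!r} has fewer than 2 observed values")
        sd = float(x[obs].std(ddof=1))
        if sd == 0.0:
            logger.warning("screen %r has zero variance; z set to 0", col)
            z.loc[obs, col] = 0.0
        else:
            z.loc[obs, col] = (x[obs] - float(x[obs].mean())) / sd
    return z


def rank_genes(z: pd.DataFrame) -> pd.DataFrame:
    """Rank genes ascending by mean z over observed screens.

    Genes with no observations are excluded with a warning.  Ties in mean z
    are broken by gene identifier (lexicographically earlier gets the lower
    rank) so the table is fully deterministic.
    """
    n_obs = z.notna().sum(axis=1)
    dropped = z.index[n_obs == 0]
    if len(dropped):
        logger.warning("%d genes with no observed screens excluded", len(dropped))
    kept = z.loc[n_obs > 0]
    table = pd.DataFrame(
        {
            "mean_z": kept.mean(axis=1, skipna=True),
            "n_screens": kept.notna().sum(axis=1).astype(int),
        }
    )
    order = np.lexsort((kept.index.astype(str).to_numpy(), table["mean_z"].to_numpy()))
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    table["top_flag"] = False
    return table


def flag_top(table: pd.DataFrame, fraction: float = 0.06) -> pd.DataFrame:
    """Flag the first ``floor(fraction * N)`` ranks as immune-resistance genes."""
    if not (0.0 < fraction < 1.0):
        raise InputError(f"fraction must be in (0, 1), got {fraction}")
    out = table.copy()
    count = math.floor(fraction * len(out))
    if count == 0:
        logger.warning("flag count is 0 at fraction %.3f with N=%d", fraction, len(out))
    out["top_flag"] = out["rank"] <= count
    return out


def signature_enrichment(table: pd.DataFrame, sigs: list[GeneSet]) -> pd.DataFrame:
    """Per-signature proportion (percent) of flagged genes.

    Signature genes absent from the ranking are excluded from the
    denominator with a warning; a signature entirely absent from the
    ranking is recorded as an error row (NaN proportion).
    """
    by_upper = {str(g).upper(): g for g in table.index}
    rows = {}
    for sig in sigs:
        members = [by_upper[g] for g in sig.genes if g in by_upper]
        n_absent = len(sig) - len(members)
        if not members:
            logger.warning("signature %r fully absent from ranking; skipped", sig.name)
            rows[sig.name] = {"n_top": 0, "n_total": 0, "proportion": float("nan")}
            continue
        if n_absent:
            logger.warning(
                "signature %r: %d genes absent from ranking excluded", sig.name, n_absent
            )
        n_top = int(table.loc[members, "top_flag"].sum())
        rows[sig.name] = {
            "n_top": n_top,
            "n_total": len(members),
            "proportion": 100.0 * n_top / len(members),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
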