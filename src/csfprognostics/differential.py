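"""Protein-wise association tests and rankings.

Differentially abundant proteins (DAPs) are found by ordinary least
squares of log2 abundance on a trait — binary conversion status or a
continuous rate of change — with a two-sided t test on the trait
coefficient and Benjamini-Hochberg FDR across proteins. Additional views:
Pearson-correlation ranking of proteins against outcome slopes (heatmap
selection) and group-level regression of abundance on time-to-event for
converters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import AbundanceMatrix

__all__ = ["dap_linear", "bh_fdr", "pearson_rank", "time_to_event_regression"]

logger = logging.getLogger(__name__)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, aligned to the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ols_trait(y: np.ndarray, X: np.ndarray, coef_idx: int) -> tuple[float, float, float]:
    """OLS of y on X; returns (beta, t, p) for column ``coef_idx``."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k or n <= k:
        return np.nan, np.nan, np.nan
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[coef_idx, coef_idx])
    if se == 0:
        return float(beta[coef_idx]), np.inf, 0.0
    t = beta[coef_idx] / se
    p = 2.0 * stats.t.sf(abs(t), df=n - k)
    return float(beta[coef_idx]), float(t), float(p)


def dap_linear(
    m: AbundanceMatrix,
    trait,
    covariates: pd.DataFrame | None = None,
    min_per_level: int = 3,
) -> pd.DataFrame:
    """Per-protein linear-model association with a trait.

    ``trait`` is one value per sample: binary group membership (coded or
    labelled) or a continuous phenotype such as a rate of change. Returns a
    table with coefficient, t, p, BH q and sign per tested protein.
    Proteins with fewer than 4 observed values are skipped (logged).
    """
    trait = np.asarray(trait)
    if trait.shape[0] != m.n_samples:
        raise ValueError("trait not aligned to samples")
    if trait.dtype.kind in "OUS":  # labels -> 0/1
        levels = np.unique(trait)
        if len(levels) != 2:
            raise ValueError("a categorical trait must have exactly 2 levels")
        trait = (trait == levels[1]).astype(float)
    else:
        trait = trait.astype(float)
    if np.all(trait == trait[0]):
        raise ValueError("trait is constant; no contrast to test")
    uniq = np.unique(trait)
    if len(uniq) == 2:
        counts = [(trait == u).sum() for u in uniq]
        if min(counts) < min_per_level:
            raise ValueError(f"need >= {min_per_level} samples per binary level")

    cols = [np.ones(m.n_samples), trait]
    if covariates is not None:
        dummies = pd.get_dummies(covariates, drop_first=True, dtype=float)
        cols.extend(dummies.to_numpy(dtype=float).T)
    X = np.column_stack(cols)
    k = X.shape[1]
    obs = m.observed()

    rows = []
    for i, pid in enumerate(m.protein_ids):
        keep = ~m.mask[i]
        if keep.sum() < max(4, k + 1):
            logger.info("protein %s skipped: only %d observed values", pid, keep.sum())
            continue
        beta, t, p = _ols_trait(obs[i, keep], X[keep], coef_idx=1)
        if not np.isfinite(p):
            logger.info("protein %s skipped: degenerate design", pid)
            continue
        rows.append((pid, beta, t, p))
    out = pd.DataFrame(rows, columns=["protein_id", "coefficient", "t_stat", "p_value"])
    out["q_value"] = bh_fdr(out["p_value"]) if len(out) else []
    out["direction"] = np.sign(out["coefficient"]).astype(int)
    return out


def pearson_rank(
    m: AbundanceMatrix,
    slopes_by_sample: dict[str, pd.Series] | pd.Series,
    top_k: int = 30,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank proteins by |Pearson r| against per-sample outcome slopes.

    ``slopes_by_sample`` maps outcome name to a Series indexed by sample id
    (a bare Series is treated as a single outcome). Returns the per-outcome
    correlation table (with rank and a top-``top_k`` flag) and the union of
    top proteins across outcomes. Zero-variance proteins and proteins with
    fewer than 3 paired observations are excluded (logged).
    """
    if isinstance(slopes_by_sample, pd.Series):
        slopes_by_sample = {"outcome": slopes_by_sample}
    obs = m.observed()
    sample_pos = {s: j for j, s in enumerate(m.sample_ids)}
    tables = []
    union: list[str] = []
    for outcome, ser in slopes_by_sample.items():
        ser = ser.dropna()
        cols = np.array([sample_pos[s] for s in ser.index if s in sample_pos])
        y = ser[[s for s in ser.index if s in sample_pos]].to_numpy(dtype=float)
        rows = []
        for i, pid in enumerate(m.protein_ids):
            x = obs[i, cols]
            keep = np.isfinite(x)
            if keep.sum() < 3:
                logger.info("%s/%s: <3 paired observations, excluded", outcome, pid)
                continue
            xv, yv = x[keep], y[keep]
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                logger.info("%s/%s: zero variance, excluded", outcome, pid)
                continue
            r, _ = stats.pearsonr(xv, yv)
            rows.append((pid, outcome, r))
        tab = pd.DataFrame(rows, columns=["protein_id", "outcome_name", "r"])
        tab["rank"] = tab["r"].abs().rank(ascending=False, method="first").astype(int)
        tab["top"] = tab["rank"] <= top_k
        tables.append(tab)
        union.extend(tab.loc[tab["top"], "protein_id"])
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["protein_id", "outcome_name", "r", "rank", "top"])
    union_sorted = sorted(set(union))
    return table, union_sorted


def time_to_event_regression(m: AbundanceMatrix, tte_years) -> pd.DataFrame:
    """Group-level regression of abundance on time-to-event (converters).

    ``tte_years`` is one value per sample in years, 0 at the event and
    negative beforehand. Per protein, OLS abundance ~ tte; proteins are
    ranked by p-value and the 10 smallest are flagged for display.
    """
    tte = np.asarray(tte_years, dtype=float)
    if tte.shape[0] != m.n_samples:
        raise ValueError("tte not aligned to samples")
    if m.n_samples < 3:
        raise ValueError("need >= 3 converters")
    if np.ptp(tte[np.isfinite(tte)]) == 0:
        raise ValueError("all time-to-event values equal; no regression possible")
    X = np.column_stack([np.ones(m.n_samples), tte])
    obs = m.observed()
    rows = []
    for i, pid in enumerate(m.protein_ids):
        keep = ~m.mask[i] & np.isfinite(tte)
        if keep.sum() < 3 or np.ptp(tte[keep]) == 0:
            continue
        beta, _, rank, _ = np.linalg.lstsq(X[keep], obs[i, keep], rcond=None)
        _, t, p = _ols_trait(obs[i, keep], X[keep], coef_idx=1)
        rows.append((pid, float(beta[0]), float(beta[1]), p))
    out = pd.DataFrame(rows, columns=["protein_id", "intercept", "slope_per_year", "p_value"])
    out["rank"] = out["p_value"].rank(method="first").astype(int)
    out["top10"] = out["rank"] <= 10
    return out.sort_values("rank").reset_index(drop=True)
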