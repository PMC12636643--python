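"""Intensity scaling, batch harmonization and ML-input preparation.

The harmonization workhorse is TAMPOR (tunable approach for median polish
of ratio): intensities are expressed as ratios to the median of selected
samples within each TMT batch, log2-transformed, and then cleaned by an
iterative two-way median polish until every row and column median is zero
(within tolerance). Per-batch multiplicative effects cancel exactly in the
ratio step; the polish removes residual protein- and sample-wise offsets
while preserving between-group biology.

Residual technical structure is then removed by non-parametric bootstrap
regression: per protein, the covariate coefficient is estimated by OLS on
bootstrap resamples of samples and the covariate times the median
coefficient is subtracted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .matrix import AbundanceMatrix

__all__ = [
    "TamporConfig",
    "scale_sample_loading",
    "zeros_to_missing",
    "filter_quantified",
    "tampor",
    "bootstrap_regress_covariates",
    "filter_completeness",
    "knn_impute",
]

logger = logging.getLogger(__name__)


@dataclass
class TamporConfig:
    """TAMPOR settings.

    denominator_mode selects the per-batch reference for the ratio step:
    ``all_batch_samples`` uses every sample in the batch (appropriate when
    no dedicated reference channels exist), ``designated_samples`` uses an
    explicit per-batch reference set (e.g. global internal standards).
    """

    denominator_mode: str = "all_batch_samples"
    designated: dict = field(default_factory=dict)  # batch_id -> list of sample ids
    tol: float = 1e-8
    max_iter: int = 250

    def __post_init__(self) -> None:
        if self.denominator_mode not in ("all_batch_samples", "designated_samples"):
            raise ValueError(f"unknown denominator_mode {self.denominator_mode!r}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def scale_sample_loading(m: AbundanceMatrix) -> AbundanceMatrix:
    """Equalize total loading: divide each sample by its observed intensity
    sum, then multiply by the maximum pre-scaling sum. Missing cells are
    untouched."""
    if m.scale != "raw":
        raise ValueError("scale_sample_loading expects raw intensities")
    obs = np.where(m.mask, 0.0, m.values)
    colsum = obs.sum(axis=0)
    dead = colsum <= 0
    if dead.any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(dead)]
        raise ValueError(f"all-missing or zero-sum sample(s): {bad}")
    scaled = m.values / colsum[None, :] * colsum.max()
    return replace(m, values=np.where(m.mask, m.values, scaled), mask=m.mask.copy())


def zeros_to_missing(m: AbundanceMatrix) -> AbundanceMatrix:
    """Mark raw zero intensities as missing (the raw-export convention)."""
    if m.scale != "raw":
        raise ValueError("zeros_to_missing expects raw intensities")
    return replace(m, values=m.values.copy(), mask=m.mask | (m.values == 0.0))


def filter_quantified(m: AbundanceMatrix, min_frac: float = 0.5) -> AbundanceMatrix:
    """Keep proteins quantified in at least ``min_frac`` of samples (inclusive)."""
    return m.subset_proteins(m.observed_fraction() >= min_frac)


def filter_completeness(m: AbundanceMatrix, min_frac: float = 0.95) -> AbundanceMatrix:
    """Keep proteins observed in strictly more than ``min_frac`` of samples.

    The strict inequality is deliberate: the ML-input rule retains proteins
    with data in *more than* 95% of participants, so exactly 95% is dropped.
    """
    return m.subset_proteins(m.observed_fraction() > min_frac)


def _batch_denominators(
    m: AbundanceMatrix, batch_of: pd.Series, cfg: TamporConfig
) -> dict[str, np.ndarray]:
    """Per-batch, per-protein denominator medians over the reference set."""
    obs = m.observed()
    denoms: dict[str, np.ndarray] = {}
    for b in batch_of.unique():
        in_batch = (batch_of == b).to_numpy()
        if cfg.denominator_mode == "designated_samples":
            if b not in cfg.designated:
                raise ValueError(f"no designated samples for batch {b}")
            ref = np.isin(m.sample_ids, list(cfg.designated[b])) & in_batch
            if not ref.any():
                raise ValueError(f"designated samples for batch {b} not in batch")
        else:
            ref = in_batch
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            denoms[b] = np.nanmedian(obs[:, ref], axis=1)
    return denoms


def median_polish(log2: np.ndarray, tol: float = 1e-8, max_iter: int = 250) -> tuple[np.ndarray, int, float]:
    """Two-way median polish on a (possibly NaN-holed) log2 matrix.

    Alternately subtracts row (protein) medians and column (sample) medians
    until the largest absolute median is below ``tol``. Returns the polished
    matrix, iterations used and the final delta.
    """
    x = log2.copy()
    delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            rmed = np.nanmedian(x, axis=1)
            rmed = np.where(np.isfinite(rmed), rmed, 0.0)
            x -= rmed[:, None]
            cmed = np.nanmedian(x, axis=0)
            cmed = np.where(np.isfinite(cmed), cmed, 0.0)
            x -= cmed[None, :]
            rchk = np.nanmedian(x, axis=1)
            cchk = np.nanmedian(x, axis=0)
        delta = max(np.nanmax(np.abs(rchk), initial=0.0),
                    np.nanmax(np.abs(cchk), initial=0.0))
        if delta < tol:
            break
    else:
        logger.warning("median polish did not converge: final delta %.3e", delta)
    return x, it, delta


def tampor(
    m: AbundanceMatrix, meta: pd.DataFrame, cfg: TamporConfig | None = None
) -> AbundanceMatrix:
    """Batch harmonization by median polish of per-batch intensity ratios.

    Steps: (1) per protein and batch, divide by the median over the batch's
    denominator samples (observed entries only); (2) log2; (3) iterative
    two-way median polish; the result has row and column medians ~ 0.
    A protein whose denominator median is missing or zero in some batch has
    its values in that batch set missing (logged).
    """
    if m.scale != "raw":
        raise ValueError("tampor expects raw intensities")
    cfg = cfg or TamporConfig()
    batch_of = meta.set_index("sample_id").loc[m.sample_ids, "batch_id"]
    denoms = _batch_denominators(m, batch_of, cfg)

    obs = m.observed()
    ratio = np.full_like(obs, np.nan)
    mask = m.mask.copy()
    for b, d in denoms.items():
        cols = (batch_of == b).to_numpy()
        bad = ~np.isfinite(d) | (d <= 0)
        if bad.any():
            logger.warning("batch %s: %d protein(s) lack a usable denominator; "
                           "values set missing", b, int(bad.sum()))
            mask[np.ix_(bad, cols)] = True
        good = ~bad
        ratio[np.ix_(good, cols)] = obs[np.ix_(good, cols)] / d[good, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(ratio)
    log2[mask] = np.nan

    polished, it, delta = median_polish(log2, tol=cfg.tol, max_iter=cfg.max_iter)
    logger.info("TAMPOR polish converged in %d iteration(s), delta %.3e", it, delta)
    values = np.where(np.isfinite(polished), polished, 0.0)
    return AbundanceMatrix(values=values, mask=~np.isfinite(polished),
                           protein_ids=list(m.protein_ids),
                           sample_ids=list(m.sample_ids), scale="log2")


def _design_matrix(design: pd.DataFrame) -> np.ndarray:
    """Dummy-code categoricals and prepend an intercept column."""
    num = pd.get_dummies(design, drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(num)), num.to_numpy(dtype=float)])
    return X


def bootstrap_regress_covariates(
    m: AbundanceMatrix,
    design: pd.DataFrame,
    n_boot: int = 100,
    seed: int = 0,
) -> AbundanceMatrix:
    """Remove covariate effects by median-of-bootstraps OLS.

    Per protein, OLS coefficients of log2 abundance on the design are
    estimated on ``n_boot`` bootstrap resamples of samples; the corrected
    value subtracts each covariate times the median coefficient across
    bootstraps (the intercept is never subtracted). Missing cells are
    excluded from fits and stay missing. Proteins with fewer observed
    samples than coefficients are left uncorrected (logged).
    """
    if m.scale != "log2":
        raise ValueError("bootstrap_regress_covariates expects a log2 matrix")
    if len(design) != m.n_samples:
        raise ValueError("design rows do not align with samples")
    X = _design_matrix(design)
    n, k = X.shape
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_boot, n))

    obs = m.observed()
    complete = ~m.mask.any(axis=1)
    coefs = np.zeros((m.n_proteins, k))
    corrected = obs.copy()

    if complete.any():
        Y = obs[complete].T  # n x p_complete
        betas = np.empty((n_boot, k, Y.shape[1]))
        for b in range(n_boot):
            idx = boot_idx[b]
            betas[b], *_ = np.linalg.lstsq(X[idx], Y[idx], rcond=None)
        coefs[complete] = np.median(betas, axis=0).T

    for i in np.flatnonzero(~complete):
        row_obs = ~m.mask[i]
        if row_obs.sum() < k:
            logger.warning("protein %s: %d observed < %d coefficients; "
                           "left uncorrected", m.protein_ids[i], row_obs.sum(), k)
            continue
        y = obs[i]
        betas_i = []
        for b in range(n_boot):
            idx = boot_idx[b]
            idx = idx[row_obs[idx]]
            if len(idx) < k:
                continue
            beta, *_ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
            betas_i.append(beta)
        if betas_i:
            coefs[i] = np.median(np.asarray(betas_i), axis=0)

    corrected -= coefs[:, 1:] @ X[:, 1:].T
    values = np.where(m.mask, 0.0, corrected)
    return replace(m, values=values, mask=m.mask.copy())


def knn_impute(m: AbundanceMatrix, k: int = 5, seed: int = 0) -> AbundanceMatrix:
    """Complete the matrix by k-nearest-neighbour imputation.

    Orientation is sample-wise: a sample's missing protein is imputed from
    the mean of its ``k`` most similar samples (nan-Euclidean distance over
    shared observed proteins, donors restricted to samples observed at that
    protein). Observed cells are never altered. ``seed`` is accepted for
    interface uniformity; the procedure is deterministic.
    """
    empty_samples = m.mask.all(axis=0)
    if empty_samples.any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(empty_samples)]
        raise ValueError(f"sample(s) with no observed proteins: {bad}")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(m.observed().T).T
    if filled.shape != m.values.shape:
        raise ValueError("a protein with no observed values cannot be imputed")
    return replace(m, values=filled, mask=np.zeros_like(m.mask))
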