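"""Single-subtype event-based staging of cross-sectional biomarkers.

Disease progression is modeled as a fixed but unknown ordering of
biomarker "events". A subject at stage k has the first k biomarkers of
the ordering in their abnormal state (mean ``z_event``) and the rest
normal (mean 0), all with Gaussian noise; subjects are a uniform mixture
over the N+1 stages. The most likely ordering is found by greedy ascent
from random restarts followed by Metropolis MCMC over pairwise swaps,
which also yields positional uncertainty; subjects are then staged by
their posterior over stages under the chosen ordering.

This is the single-subtype, one-z-threshold-per-biomarker member of the
subtype-and-stage family, which suffices for ordering a small panel of
top-ranked proteins within one progression group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "EventModelConfig",
    "EventSequence",
    "zscore_biomarkers",
    "sequence_likelihood",
    "fit_event_sequence",
    "stage_subjects",
]

logger = logging.getLogger(__name__)


@dataclass
class EventModelConfig:
    """Event-model settings: post-event mean and sd in z units (scalar or
    per-biomarker), restarts for the greedy search, and MCMC length."""

    z_event: float | np.ndarray = 2.0
    sigma: float | np.ndarray = 1.0
    n_restarts: int = 25
    mcmc_iters: int = 10_000
    seed: int = 0

    def validate(self, n_biomarkers: int) -> tuple[np.ndarray, np.ndarray]:
        z = np.broadcast_to(np.asarray(self.z_event, dtype=float), (n_biomarkers,))
        s = np.broadcast_to(np.asarray(self.sigma, dtype=float), (n_biomarkers,))
        if np.any(s <= 0):
            raise ValueError("sigma must be positive")
        if np.any(z == 0):
            raise ValueError("z_event must be nonzero")
        return z.copy(), s.copy()


@dataclass
class EventSequence:
    """Fitted ordering with positional and stage uncertainty."""

    order: list[str]
    log_likelihood: float
    positional_probability: pd.DataFrame   # biomarker x position
    stage_posterior: pd.DataFrame          # subject x stage (0..N)
    map_stages: pd.Series
    acceptance_rate: float


def zscore_biomarkers(
    X: pd.DataFrame, reference: np.ndarray, directions: pd.Series | dict | None = None
) -> pd.DataFrame:
    """Standardize against a reference (stable) group, oriented so every
    event is an increase.

    ``reference`` is a boolean row mask or row indices; ``directions`` maps
    biomarker to +/-1 (e.g. signs of differential-abundance coefficients).
    """
    ref = X.loc[np.asarray(reference)] if np.asarray(reference).dtype == bool \
        else X.iloc[np.asarray(reference)]
    if len(ref) < 3:
        raise ValueError("reference group needs >= 3 rows")
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero reference sd for biomarker(s): {list(zero.index)}")
    z = (X - mu) / sd
    if directions is not None:
        d = pd.Series(directions).reindex(z.columns)
        if d.isna().any() or not d.abs().eq(1).all():
            raise ValueError("directions must give +/-1 for every biomarker")
        z = z * d
    return z


def _stage_loglik(
    Z: np.ndarray, order_idx: np.ndarray, z_event: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """n_subjects x (N+1) log-likelihood of each stage under one ordering."""
    lp_event = norm.logpdf(Z, loc=z_event[None, :], scale=sigma[None, :])
    lp_normal = norm.logpdf(Z, loc=0.0, scale=sigma[None, :])
    E = lp_event[:, order_idx]
    C = lp_normal[:, order_idx]
    n, N = Z.shape
    pre = np.concatenate([np.zeros((n, 1)), np.cumsum(E, axis=1)], axis=1)
    suf = np.concatenate([np.cumsum(C[:, ::-1], axis=1)[:, ::-1],
                          np.zeros((n, 1))], axis=1)
    return pre + suf  # column k: events at positions <= k, rest normal


def _total_loglik(stage_ll: np.ndarray) -> float:
    N1 = stage_ll.shape[1]
    return float(np.sum(logsumexp(stage_ll, axis=1) - np.log(N1)))


def sequence_likelihood(Z: pd.DataFrame, order, cfg: EventModelConfig) -> float:
    """Total log-likelihood of the data under one event ordering.

    Each subject contributes log of the uniform mixture over stages
    P = (1/(N+1)) sum_k prod_i Normal(z_i; mu_i(k), sigma_i) with
    mu_i(k) = z_event_i once biomarker i's position is <= k, else 0.
    """
    biomarkers = list(Z.columns)
    if sorted(order) != sorted(biomarkers):
        raise ValueError("order must be a permutation of the biomarkers")
    z_event, sigma = cfg.validate(len(biomarkers))
    col = {b: i for i, b in enumerate(biomarkers)}
    order_idx = np.array([col[b] for b in order])
    ll = _stage_loglik(Z.to_numpy(dtype=float), order_idx, z_event, sigma)
    return _total_loglik(ll)


def _greedy_ascend(
    Z: np.ndarray, order_idx: np.ndarray, z_event, sigma
) -> tuple[np.ndarray, float]:
    """Best single-element relocation until no gain."""
    cur = order_idx.copy()
    cur_ll = _total_loglik(_stage_loglik(Z, cur, z_event, sigma))
    N = len(cur)
    improved = True
    while improved:
        improved = False
        best_ll, best_order = cur_ll, None
        for i in range(N):
            for j in range(N):
                if i == j:
                    continue
                cand = np.delete(cur, i)
                cand = np.insert(cand, j, cur[i])
                ll = _total_loglik(_stage_loglik(Z, cand, z_event, sigma))
                if ll > best_ll + 1e-12:
                    best_ll, best_order = ll, cand
        if best_order is not None:
            cur, cur_ll = best_order, best_ll
            improved = True
    return cur, cur_ll


def fit_event_sequence(Z: pd.DataFrame, cfg: EventModelConfig) -> EventSequence:
    """Infer the maximum-likelihood event ordering and stage the subjects.

    ``n_restarts`` greedy ascents from random permutations seed a
    Metropolis MCMC over pairwise swaps; the returned order is the best
    ever visited, positional probabilities are MCMC frequencies, and stage
    posteriors are computed under the returned (MAP) order.
    """
    biomarkers = list(Z.columns)
    N = len(biomarkers)
    if N < 2:
        raise ValueError("need >= 2 biomarkers")
    z_event, sigma = cfg.validate(N)
    Zv = Z.to_numpy(dtype=float)
    if np.allclose(Zv.std(axis=0), 0) and np.allclose(np.ptp(Zv, axis=0), 0):
        logger.warning("degenerate data: all subjects identical; "
                       "positional matrix will be uninformative")
    rng = np.random.default_rng(cfg.seed)

    best_order, best_ll = None, -np.inf
    for _ in range(max(1, cfg.n_restarts)):
        start = rng.permutation(N)
        order, ll = _greedy_ascend(Zv, start, z_event, sigma)
        if ll > best_ll:
            best_order, best_ll = order, ll

    # Metropolis over pairwise swaps, started at the greedy optimum
    cur, cur_ll = best_order.copy(), best_ll
    counts = np.zeros((N, N))  # biomarker x position
    accepted = 0
    for _ in range(cfg.mcmc_iters):
        i, j = rng.integers(0, N, size=2)
        if i == j:
            counts[cur, np.arange(N)] += 1
            continue
        cand = cur.copy()
        cand[i], cand[j] = cand[j], cand[i]
        cand_ll = _total_loglik(_stage_loglik(Zv, cand, z_event, sigma))
        if np.log(rng.random()) < cand_ll - cur_ll:
            cur, cur_ll = cand, cand_ll
            accepted += 1
            if cur_ll > best_ll:
                best_order, best_ll = cur.copy(), cur_ll
        counts[cur, np.arange(N)] += 1
    acc_rate = accepted / max(1, cfg.mcmc_iters)
    logger.info("MCMC acceptance rate %.3f", acc_rate)

    pos_prob = counts / counts.sum(axis=1, keepdims=True)
    order_names = [biomarkers[k] for k in best_order]
    posterior, map_stages = stage_subjects(Z, order_names, cfg)
    return EventSequence(
        order=order_names,
        log_likelihood=best_ll,
        positional_probability=pd.DataFrame(
            pos_prob, index=biomarkers,
            columns=[f"pos{i + 1}" for i in range(N)]),
        stage_posterior=posterior,
        map_stages=map_stages,
        acceptance_rate=acc_rate,
    )


def stage_subjects(
    Z: pd.DataFrame, order, cfg: EventModelConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Posterior over stages 0..N per subject under a fixed ordering.

    MAP stage ties break toward the lower stage.
    """
    biomarkers = list(Z.columns)
    z_event, sigma = cfg.validate(len(biomarkers))
    col = {b: i for i, b in enumerate(biomarkers)}
    order_idx = np.array([col[b] for b in order])
    ll = _stage_loglik(Z.to_numpy(dtype=float), order_idx, z_event, sigma)
    post = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
    posterior = pd.DataFrame(post, index=Z.index,
                             columns=[f"stage{k}" for k in range(ll.shape[1])])
    map_stages = pd.Series(np.argmax(post, axis=1), index=Z.index, name="map_stage")
    return posterior, map_stages
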