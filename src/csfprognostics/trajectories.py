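"""Biomarker status, conversion groups and per-subject outcome slopes.

Longitudinal outcomes (e.g. ADAS-Cog11, CDR-SB, imaging SUVRs) are reduced
to one rate-of-change per participant by a linear mixed-effects model with
participant-specific intercepts and slopes; the per-subject slope is the
fixed slope plus the subject's predicted random effect (BLUP). Inclusion
rules, outlier trimming and the fast/slow median split follow the cohort
definitions used for downstream differential testing and classification.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "classify_AT",
    "select_longitudinal",
    "fit_subject_slopes",
    "trim_outlier_slopes",
    "median_split",
    "define_conversion_groups",
    "DEFAULT_INCLUSION",
    "WORSENING_SIGN",
]

logger = logging.getLogger(__name__)

AT_CUTOFF = 39.20  # pre-established CSF Abeta42/pTau181 ratio cutoff

# (min_visits, min_span_months) per outcome; imaging SUVRs use the relaxed rule
DEFAULT_INCLUSION = {
    "ADAS-Cog11": (3, 24.0),
    "CDR-SB": (3, 24.0),
    "hippocampal_volume_norm": (3, 24.0),
    "FDG_SUVR": (2, 12.0),
    "tau_SUVR": (2, 12.0),
}
_DEFAULT_RULE = (3, 24.0)

# +1: an increasing slope means worsening; -1: a decreasing slope does
WORSENING_SIGN = {
    "ADAS-Cog11": +1, "CDR-SB": +1, "tau_SUVR": +1,
    "hippocampal_volume_norm": -1, "FDG_SUVR": -1,
}


def classify_AT(abeta42, ptau181, cutoff: float = AT_CUTOFF,
                positive_above: bool = True):
    """AT status from the CSF Abeta42/pTau181 ratio.

    With ``positive_above`` (default), a ratio above ``cutoff`` is AT+ and a
    ratio at or below it is AT-, following the published assignment rule for
    this cutoff verbatim. Note this direction is the reverse of the usual
    biochemical reading of an Abeta42/pTau ratio; ``positive_above=False``
    flips it. Accepts scalars or arrays.
    """
    abeta42 = np.asarray(abeta42, dtype=float)
    ptau181 = np.asarray(ptau181, dtype=float)
    if np.any(ptau181 <= 0):
        raise ValueError("ptau181 must be positive")
    ratio = abeta42 / ptau181
    above = ratio > cutoff
    plus = above if positive_above else ~above
    out = np.where(plus, "AT_plus", "AT_minus")
    return out.item() if out.ndim == 0 else out


def select_longitudinal(
    series: pd.DataFrame,
    min_visits: int | None = None,
    min_span_months: float | None = None,
) -> pd.DataFrame:
    """Filter a long-format series to subjects with sufficient follow-up.

    Defaults per outcome: clinical/volumetric outcomes require >= 3 visits
    spanning >= 24 months; tau and FDG SUVR require >= 2 visits spanning
    >= 12 months. Explicit arguments override.
    """
    keep_parts = []
    for (outcome, subject), grp in series.groupby(["outcome_name", "subject_id"], sort=False):
        mv, ms = DEFAULT_INCLUSION.get(outcome, _DEFAULT_RULE)
        mv = min_visits if min_visits is not None else mv
        ms = min_span_months if min_span_months is not None else ms
        t = grp["months"].to_numpy(dtype=float)
        if len(t) >= mv and (t.max() - t.min()) >= ms:
            keep_parts.append(grp)
    if not keep_parts:
        return series.iloc[0:0]
    return pd.concat(keep_parts, ignore_index=True)


def _ols_slopes(series: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for subject, grp in series.groupby("subject_id", sort=True):
        t = grp["months"].to_numpy(dtype=float)
        y = grp["value"].to_numpy(dtype=float)
        slope = np.polyfit(t, y, 1)[0] if len(t) >= 2 else np.nan
        rows.append((subject, slope, len(t), t.max() - t.min()))
    return pd.DataFrame(rows, columns=["subject_id", "slope", "n_visits", "span_months"])


def fit_subject_slopes(series: pd.DataFrame, outcome_name: str | None = None) -> pd.DataFrame:
    """Per-subject rates of change from a random-intercept/random-slope model.

    Fits y_ij = (b0 + u0_i) + (b1 + u1_i) t_ij + eps_ij by REML and returns
    a slope table with slope = b1 + BLUP(u1_i). If the mixed fit is singular
    or fails to converge, falls back to per-subject OLS slopes, flagged in
    the ``method`` column.
    """
    if outcome_name is not None:
        series = series[series["outcome_name"] == outcome_name]
    elif "outcome_name" in series.columns and series["outcome_name"].nunique() > 1:
        raise ValueError("multiple outcomes present; pass outcome_name")
    if series["subject_id"].nunique() < 2:
        raise ValueError("need >= 2 subjects to fit slopes")

    ols = _ols_slopes(series)
    method = "lmm"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            t = series["months"].to_numpy(dtype=float)
            y = series["value"].to_numpy(dtype=float)
            exog = sm.add_constant(t)
            model = sm.MixedLM(y, exog, groups=series["subject_id"].to_numpy(),
                               exog_re=exog)
            fit = model.fit(reml=True, method="lbfgs")
        fixed_slope = fit.fe_params[1]
        re = fit.random_effects
        slopes = {s: fixed_slope + re[s].iloc[1] for s in re}
        slope_col = ols["subject_id"].map(slopes)
        if slope_col.isna().any():
            raise RuntimeError("missing random effect for some subject")
    except Exception as exc:  # singular fit, convergence failure
        logger.warning("mixed model fit failed (%s); falling back to per-subject OLS", exc)
        slope_col = ols["slope"]
        method = "ols"

    out = ols.copy()
    out["slope"] = np.asarray(slope_col, dtype=float)
    if outcome_name is None and "outcome_name" in series.columns:
        outcome_name = series["outcome_name"].iloc[0]
    out["outcome_name"] = outcome_name if outcome_name is not None else "outcome"
    out["included"] = out["n_visits"] >= 2
    out["reason"] = np.where(out["included"], "", "fewer than 2 visits")
    out["method"] = method
    out.loc[~out["included"], "slope"] = np.nan
    return out[["subject_id", "outcome_name", "slope", "n_visits",
                "span_months", "included", "reason", "method"]]


def trim_outlier_slopes(slopes: pd.DataFrame, n_sd: float = 4.0) -> pd.DataFrame:
    """Drop slopes more than ``n_sd`` standard deviations from the mean.

    Single pass: the mean and sd are computed once over included slopes and
    not recomputed after removal.
    """
    out = slopes.copy()
    inc = out["included"].to_numpy(dtype=bool)
    vals = out.loc[inc, "slope"].to_numpy(dtype=float)
    if len(vals) < 3:
        raise ValueError("need >= 3 included slopes to trim")
    mu, sd = vals.mean(), vals.std(ddof=1)
    if sd > 0:
        extreme = inc & (np.abs(out["slope"].to_numpy(dtype=float) - mu) > n_sd * sd)
        out.loc[extreme, "included"] = False
        out.loc[extreme, "reason"] = f"slope beyond {n_sd:g} SD"
    return out[out["included"]].reset_index(drop=True)


def median_split(slopes: pd.DataFrame, worsening_sign: int | None = None) -> pd.DataFrame:
    """Label fast vs slow progressors at the median slope.

    Fast means the slope, oriented so that larger = clinically worse, is
    strictly greater than the cohort median; everyone else is slow. If all
    slopes are equal the split is degenerate (everyone slow, logged).
    """
    out = slopes.copy()
    if worsening_sign is None:
        outcome = out["outcome_name"].iloc[0] if "outcome_name" in out.columns else None
        worsening_sign = WORSENING_SIGN.get(outcome, +1)
    if worsening_sign not in (+1, -1):
        raise ValueError("worsening_sign must be +1 or -1")
    oriented = worsening_sign * out["slope"].to_numpy(dtype=float)
    if len(oriented) < 2:
        raise ValueError("need >= 2 slopes for a median split")
    med = np.median(oriented)
    fast = oriented > med
    if not fast.any():
        logger.warning("degenerate median split: no slope strictly above the median")
    out["progressor"] = np.where(fast, "fast", "slow")
    return out


_COHORT_RULES = {
    # cohort: (baseline states, event states, window_months or None)
    "mci": ({"MCI"}, {"Dementia"}, 36.0),
    "amyloid": ({"Abeta-"}, {"Abeta+"}, None),
    "asymptomatic": ({"CN", "Asym"}, {"MCI", "Dementia"}, None),
}


def define_conversion_groups(
    history: pd.DataFrame, cohort: str, window_months: float | None = None
) -> pd.DataFrame:
    """Stable/converter/excluded labels from a diagnosis-history table.

    ``history`` has columns subject_id, months, status. For the MCI cohort
    a converter has a first Dementia diagnosis within the window (<= 36
    months by default); a stable subject stays MCI at every visit and has a
    visit beyond the window; everyone else is excluded. The amyloid and
    asymptomatic cohorts have no window: any qualifying event at follow-up
    makes a converter, otherwise stable.
    """
    if cohort not in _COHORT_RULES:
        raise ValueError(f"unknown cohort {cohort!r}")
    baseline_states, event_states, default_window = _COHORT_RULES[cohort]
    window = window_months if window_months is not None else default_window

    rows = []
    for subject, grp in history.groupby("subject_id", sort=True):
        grp = grp.sort_values("months")
        t = grp["months"].to_numpy(dtype=float)
        status = grp["status"].astype(str).to_numpy()
        if len(grp) == 0 or status[0] not in baseline_states:
            rows.append((subject, cohort, "excluded", np.nan, "missing or invalid baseline status"))
            continue
        event_idx = np.flatnonzero(np.isin(status, list(event_states)))
        t_event = t[event_idx[0]] if len(event_idx) else np.nan
        if window is None:
            if len(event_idx):
                rows.append((subject, cohort, "converter", t_event, ""))
            else:
                rows.append((subject, cohort, "stable", np.nan, ""))
        else:
            if len(event_idx) and t_event <= window:
                rows.append((subject, cohort, "converter", t_event, ""))
            elif len(event_idx) == 0 and np.isin(status, list(baseline_states)).all() \
                    and t.max() > window:
                rows.append((subject, cohort, "stable", np.nan, ""))
            else:
                rows.append((subject, cohort, "excluded", np.nan,
                             "insufficient follow-up or late event"))
    return pd.DataFrame(rows, columns=["subject_id", "cohort", "label",
                                       "time_to_event_months", "reason"])
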