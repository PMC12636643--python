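"""Predictive protein panels: selection, evaluation and comparison.

Panels are chosen by bootstrap-stability LASSO: an L1-penalized logistic
regression is refit on bootstrap resamples (penalty tuned by internal
cross-validation with the 1-SE rule) and proteins selected in at least 90%
of bootstraps form the panel. Panels are evaluated with random-forest
classifiers over repeated stratified train/test splits (grid-searched on
training folds only), summarized as the median test AUC with a 2.5-97.5
percentile interval across runs. Predictor sets are compared with a
synchronized permutation test: both models see identical splits, and the
null re-runs the synced evaluation after jointly permuting the
participant-to-feature-row assignment of both blocks.

Feature attribution is a model-agnostic Shapley estimator: marginal
contributions along feature orderings against a background sample, which
telescopes so that base value + attributions equals the model score
exactly (local accuracy); small feature counts are enumerated exactly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "PanelSelection",
    "EvalResult",
    "AttributionMatrix",
    "stability_select",
    "evaluate_panel",
    "evaluate_nested_panel",
    "roc_auc",
    "youden_threshold",
    "attribute_features",
    "compare_predictor_sets",
    "combine_with_conventional",
    "DEFAULT_RF_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_RF_GRID = {"n_estimators": [100, 300, 500], "max_depth": [3, 5, None]}


# --------------------------------------------------------------------------
# helpers

def _as_frame(X, prefix: str = "f") -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"{prefix}{j}" for j in range(X.shape[1])])


def _binary_labels(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must have exactly 2 classes")
    return (y == classes[1]).astype(int)


def _stratified_boot(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap resample preserving class counts."""
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def _stratified_split(
    y: np.ndarray, test_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split; every class appears in both parts."""
    train, test = [], []
    for cls in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == cls))
        n_test = max(1, int(round(test_frac * len(members))))
        if n_test >= len(members):
            raise ValueError("class too small to split")
        test.append(members[:n_test])
        train.append(members[n_test:])
    return np.concatenate(train), np.concatenate(test)


# --------------------------------------------------------------------------
# ROC / AUC / Youden

def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC (Mann-Whitney probability, ties counted 1/2) and the ROC curve."""
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def youden_threshold(roc: pd.DataFrame) -> tuple[float, float]:
    """Threshold maximizing J = TPR - FPR; ties go to higher sensitivity."""
    if len(roc) == 0:
        raise ValueError("empty ROC")
    j = roc["tpr"].to_numpy() - roc["fpr"].to_numpy()
    best = j.max()
    cand = roc[np.isclose(j, best)]
    cand = cand[cand["tpr"] == cand["tpr"].max()]
    thr = float(cand["threshold"].min())
    return thr, float(best)


# --------------------------------------------------------------------------
# stability selection

@dataclass
class PanelSelection:
    """Bootstrap selection frequencies and the retained panel."""

    frequencies: pd.Series           # feature -> fraction of bootstraps selecting it
    selected: list[str]
    n_boot: int
    threshold: float


def _lasso_one_se(
    X: np.ndarray, y: np.ndarray, Cs: np.ndarray, cv_folds: int,
    rng: np.random.Generator,
) -> LogisticRegression:
    """L1 logistic with C chosen by CV log-loss under the 1-SE rule."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    losses = np.zeros((len(Cs), cv_folds))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        for c, C in enumerate(Cs):
            clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=C,
                                     max_iter=500, random_state=0)
            clf.fit(X[tr], y[tr])
            losses[c, f] = log_loss(y[va], clf.predict_proba(X[va])[:, 1],
                                    labels=[0, 1])
    mean = losses.mean(axis=1)
    se = losses.std(axis=1, ddof=1) / math.sqrt(cv_folds)
    best = int(np.argmin(mean))
    # 1-SE rule: strongest penalty whose loss is within one SE of the best
    ok = np.flatnonzero(mean <= mean[best] + se[best])
    chosen = Cs[ok.min()]  # Cs ascending: smallest C = most regularized
    final = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=chosen,
                               max_iter=500, random_state=0)
    final.fit(X, y)
    return final


def stability_select(
    X,
    y,
    n_boot: int = 100,
    threshold: float = 0.9,
    seed: int = 0,
    cv_folds: int = 5,
    Cs: np.ndarray | None = None,
) -> PanelSelection:
    """Bootstrap-stability LASSO feature selection.

    Each bootstrap resamples samples with replacement (stratified by
    class), standardizes features, fits an L1 logistic regression with the
    penalty tuned by internal CV (1-SE rule) and records which features
    have nonzero coefficients. Features selected in >= ``threshold`` of
    bootstraps form the panel.
    """
    Xf = _as_frame(X)
    if Xf.isna().any().any():
        raise ValueError("X has missing cells; run knn_impute first")
    yb = _binary_labels(y)
    if Cs is None:
        Cs = np.logspace(-2, 1, 8)
    rng = np.random.default_rng(seed)
    counts = np.zeros(Xf.shape[1])
    Xv = Xf.to_numpy(dtype=float)
    for b in range(n_boot):
        for _attempt in range(10):
            idx = _stratified_boot(yb, rng)
            if len(np.unique(yb[idx])) == 2:
                break
            logger.warning("bootstrap %d drew one class; redrawn", b)
        Xb = StandardScaler().fit_transform(Xv[idx])
        clf = _lasso_one_se(Xb, yb[idx], np.asarray(Cs), cv_folds, rng)
        counts += (np.abs(clf.coef_[0]) > 1e-10).astype(float)
    freq = pd.Series(counts / n_boot, index=Xf.columns, name="selection_frequency")
    selected = list(freq.index[freq >= threshold])
    return PanelSelection(frequencies=freq, selected=selected,
                          n_boot=n_boot, threshold=threshold)


# --------------------------------------------------------------------------
# panel evaluation

@dataclass
class EvalResult:
    """Per-run AUCs over permuted splits plus summary statistics."""

    aucs: np.ndarray
    rocs: list = field(repr=False, default_factory=list)
    youden: list = field(default_factory=list)
    splits: list = field(repr=False, default_factory=list)
    n_runs: int = 0
    test_frac: float = 0.2
    seed: int = 0

    @property
    def median_auc(self) -> float:
        return float(np.median(self.aucs))

    @property
    def ci(self) -> tuple[float, float]:
        return (float(np.percentile(self.aucs, 2.5)),
                float(np.percentile(self.aucs, 97.5)))


def _fit_tuned(
    X_tr: np.ndarray, y_tr: np.ndarray, grid: dict, cv_folds: int, run_seed: int,
    estimator_factory=None,
):
    if estimator_factory is not None:
        est = estimator_factory(run_seed)
        est.fit(X_tr, y_tr)
        return est
    combos = math.prod(len(v) for v in grid.values()) if grid else 1
    base = RandomForestClassifier(random_state=run_seed)
    if not grid or combos == 1:
        params = {k: v[0] for k, v in grid.items()} if grid else {}
        base.set_params(**params)
        base.fit(X_tr, y_tr)
        return base
    search = GridSearchCV(
        base, grid, scoring="roc_auc",
        cv=StratifiedKFold(cv_folds, shuffle=True, random_state=run_seed),
        n_jobs=1)
    search.fit(X_tr, y_tr)
    return search.best_estimator_


def _score(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return np.asarray(model.predict(X), dtype=float)


def evaluate_panel(
    X,
    y,
    n_runs: int = 100,
    test_frac: float = 0.2,
    cv_folds: int = 5,
    grid: dict | None = None,
    seed: int = 0,
    estimator_factory=None,
    splits: list | None = None,
) -> EvalResult:
    """Evaluate a fixed panel over repeated stratified train/test splits.

    Each run tunes a random forest by grid search with ``cv_folds``-fold CV
    on the training part only, scores the held-out part, and records the
    ROC, AUC and Youden threshold. ``splits`` overrides split generation
    (used by the synchronized comparison). The summary is the median AUC
    and the 2.5-97.5 percentile interval across runs.
    """
    Xf = _as_frame(X)
    if Xf.isna().any().any():
        raise ValueError("X has missing cells; run knn_impute first")
    yb = _binary_labels(y)
    if grid is None:
        grid = DEFAULT_RF_GRID
    Xv = Xf.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31, size=n_runs)
    if splits is None:
        splits = [_stratified_split(yb, test_frac, np.random.default_rng(int(s)))
                  for s in run_seeds]
    res = EvalResult(aucs=np.empty(n_runs), n_runs=n_runs,
                     test_frac=test_frac, seed=seed)
    for r, ((tr, te), rs) in enumerate(zip(splits, run_seeds)):
        model = _fit_tuned(Xv[tr], yb[tr], grid, cv_folds, int(rs) % (2**31),
                           estimator_factory)
        scores = _score(model, Xv[te])
        auc, roc = roc_auc(scores, yb[te])
        thr, j = youden_threshold(roc)
        res.aucs[r] = auc
        res.rocs.append(roc)
        res.youden.append((thr, j))
        res.splits.append((tr, te))
    return res


def evaluate_nested_panel(
    X,
    y,
    n_runs: int = 100,
    test_frac: float = 0.2,
    cv_folds: int = 5,
    grid: dict | None = None,
    seed: int = 0,
    select_kwargs: dict | None = None,
) -> tuple[EvalResult, list[list[str]]]:
    """Nested mode: re-select the panel inside each training split.

    Counterpart to the fixed-panel mode (select once on all data, evaluate
    across runs); the difference between the two medians estimates the
    selection optimism. Returns the evaluation plus the per-run panels.
    If a run selects nothing, its highest-frequency feature is used
    (logged).
    """
    Xf = _as_frame(X)
    yb = _binary_labels(y)
    if grid is None:
        grid = DEFAULT_RF_GRID
    select_kwargs = dict(select_kwargs or {})
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31, size=n_runs)
    aucs = np.empty(n_runs)
    panels: list[list[str]] = []
    res = EvalResult(aucs=aucs, n_runs=n_runs, test_frac=test_frac, seed=seed)
    for r, rs in enumerate(run_seeds):
        tr, te = _stratified_split(yb, test_frac, np.random.default_rng(int(rs)))
        sel = stability_select(Xf.iloc[tr], yb[tr], seed=int(rs) % (2**31),
                               **select_kwargs)
        panel = sel.selected
        if not panel:
            panel = [sel.frequencies.idxmax()]
            logger.warning("run %d: empty panel; using top-frequency feature %s",
                           r, panel[0])
        panels.append(panel)
        model = _fit_tuned(Xf.iloc[tr][panel].to_numpy(), yb[tr], grid,
                           cv_folds, int(rs) % (2**31), None)
        scores = _score(model, Xf.iloc[te][panel].to_numpy())
        auc, roc = roc_auc(scores, yb[te])
        res.aucs[r] = auc
        res.rocs.append(roc)
        res.youden.append(youden_threshold(roc))
        res.splits.append((tr, te))
    return res, panels


# --------------------------------------------------------------------------
# feature attribution

@dataclass
class AttributionMatrix:
    """Additive per-sample, per-feature contributions to the model score."""

    values: np.ndarray               # n_test x n_features
    base_value: float
    feature_names: list[str]

    def global_ranking(self) -> pd.Series:
        imp = np.abs(self.values).mean(axis=0)
        return pd.Series(imp, index=self.feature_names).sort_values(ascending=False)


def attribute_features(
    model,
    X_test,
    background=None,
    n_permutations: int = 32,
    max_background: int = 32,
    seed: int = 0,
    exact_limit: int = 6,
    tol: float = 1e-6,
) -> AttributionMatrix:
    """Shapley feature attributions by averaged marginal contributions.

    For each test sample, features are switched from a background row's
    values to the sample's values along random orderings; the averaged
    marginal score changes are Shapley attributions. The telescoping sum
    makes local accuracy exact: base value (mean background score) plus the
    attribution row equals the model score. With at most ``exact_limit``
    features all orderings are enumerated (exact Shapley values);
    otherwise ``n_permutations`` sampled orderings are used.
    """
    Xf = _as_frame(X_test)
    M = Xf.shape[1]
    Xv = Xf.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if background is None:
        bg = Xv
    else:
        bg = _as_frame(background).to_numpy(dtype=float)
    if len(bg) > max_background:
        bg = bg[rng.choice(len(bg), size=max_background, replace=False)]

    if M <= exact_limit:
        perms = np.array(list(itertools.permutations(range(M))))
    else:
        perms = np.array([rng.permutation(M) for _ in range(n_permutations)])

    base_scores = _score(model, bg)
    base_value = float(base_scores.mean())

    n_test = len(Xv)
    phi = np.zeros((n_test, M))
    # build every hybrid row, one batched model call per (perm, step)
    for perm in perms:
        for b in range(len(bg)):
            cur = np.tile(bg[b], (n_test, 1))
            prev = np.full(n_test, base_scores[b])
            for j in perm:
                cur[:, j] = Xv[:, j]
                s = _score(model, cur)
                phi[:, j] += s - prev
                prev = s
    phi /= len(perms) * len(bg)

    full = _score(model, Xv)
    err = np.abs(base_value + phi.sum(axis=1) - full).max()
    if err > tol:
        raise RuntimeError(f"local accuracy violated: max error {err:.3e}")
    return AttributionMatrix(values=phi, base_value=base_value,
                             feature_names=list(Xf.columns))


# --------------------------------------------------------------------------
# synchronized comparison and feature blocks

def _synced_medians(
    Xa: np.ndarray, Xb: np.ndarray, y: np.ndarray,
    n_runs: int, test_frac: float, cv_folds: int, grid: dict, base_seed: int,
    estimator_factory,
) -> tuple[float, float]:
    """Median AUC of two predictor blocks on identical splits."""
    rng = np.random.default_rng(base_seed)
    run_seeds = rng.integers(0, 2**31, size=n_runs)
    splits = [_stratified_split(y, test_frac, np.random.default_rng(int(s)))
              for s in run_seeds]
    aucs_a = np.empty(n_runs)
    aucs_b = np.empty(n_runs)
    for r, ((tr, te), rs) in enumerate(zip(splits, run_seeds)):
        for X, out in ((Xa, aucs_a), (Xb, aucs_b)):
            model = _fit_tuned(X[tr], y[tr], grid, cv_folds, int(rs) % (2**31),
                               estimator_factory)
            out[r] = roc_auc_score(y[te], _score(model, X[te]))
    return float(np.median(aucs_a)), float(np.median(aucs_b))


def compare_predictor_sets(
    X_A,
    X_B,
    y,
    n_runs: int = 100,
    B: int = 100,
    test_frac: float = 0.2,
    cv_folds: int = 5,
    grid: dict | None = None,
    seed: int = 0,
    estimator_factory=None,
) -> tuple[float, float]:
    """Synchronized permutation test comparing two predictor blocks.

    Observed statistic: difference of median AUCs over ``n_runs`` splits
    shared by both blocks. Null: the participant-to-feature-row assignment
    of *both* blocks is permuted jointly (labels fixed) and the synced
    evaluation repeated; two-sided p with the (b+1)/(B+1) correction.
    """
    Xa = _as_frame(X_A, "a").to_numpy(dtype=float)
    Xb = _as_frame(X_B, "b").to_numpy(dtype=float)
    yb = _binary_labels(y)
    if len(Xa) != len(Xb) or len(Xa) != len(yb):
        raise ValueError("X_A, X_B and y must be row-aligned")
    if grid is None:
        grid = DEFAULT_RF_GRID
    rng = np.random.default_rng(seed)
    eval_seed = int(rng.integers(2**31))
    med_a, med_b = _synced_medians(Xa, Xb, yb, n_runs, test_frac, cv_folds,
                                   grid, eval_seed, estimator_factory)
    delta_obs = med_a - med_b
    count = 0
    for b in range(B):
        perm = rng.permutation(len(yb))
        pa, pbm = _synced_medians(Xa[perm], Xb[perm], yb, n_runs, test_frac,
                                  cv_folds, grid, int(rng.integers(2**31)),
                                  estimator_factory)
        if abs(pa - pbm) >= abs(delta_obs):
            count += 1
    p = (count + 1) / (B + 1)
    return delta_obs, p


def combine_with_conventional(X_panel: pd.DataFrame, conventional: pd.DataFrame) -> pd.DataFrame:
    """Column-concatenate the protein panel with conventional predictors.

    Panel columns come first; duplicate column names are an error; each
    column's provenance is recorded in ``DataFrame.attrs['provenance']``.
    """
    X_panel = _as_frame(X_panel)
    conventional = _as_frame(conventional, "conv")
    if len(conventional.columns) == 0:
        out = X_panel.copy()
        out.attrs["provenance"] = {c: "panel" for c in X_panel.columns}
        return out
    if len(X_panel) != len(conventional):
        raise ValueError("row counts differ")
    dup = set(X_panel.columns) & set(conventional.columns)
    if dup:
        raise ValueError(f"duplicate column names: {sorted(dup)}")
    out = pd.concat([X_panel.reset_index(drop=True),
                     conventional.reset_index(drop=True)], axis=1)
    out.attrs["provenance"] = {
        **{c: "panel" for c in X_panel.columns},
        **{c: "conventional" for c in conventional.columns},
    }
    return out
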