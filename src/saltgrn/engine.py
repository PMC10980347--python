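"""Tree-ensemble network inference: one stochastic replicate.

Each candidate target gene is regressed on all other panel genes with
stochastic gradient boosting of regression trees (squared-error loss).
At every stage a depth-limited tree is fitted to the current residuals on
a without-replacement row subsample, considering a random fraction of
predictors per split; the fit advances by ``learning_rate`` times the
tree's prediction.  The stage's generalization gain is measured as the
drop in squared-error loss on that stage's held-out (out-of-bag) rows;
boosting stops once the trailing-window mean of these gains is
non-positive.  Importances are computed over the *retained* stages — the
prefix ending at the maximum of cumulative out-of-bag gain, i.e. the best
iteration — as total impurity reduction per predictor, normalized to sum
one.  The normalized importance of predictor j for target t is the weight
of the candidate edge j -> t.

Expression enters the trees untransformed: splits are invariant to any
monotone per-predictor rescaling, so the engine is scale-covariant and no
centering/scaling step is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .simulate import ExpressionMatrix

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("regulator", "target", "importance")


@dataclass(frozen=True)
class InferenceParams:
    """Stochastic-GBM hyperparameters.

    Defaults mirror the published profile of GRN boosting tools:
    learning rate 0.01, up to 5000 stages, 90% row subsampling, 10% of
    predictors per split, depth-3 trees, early-stop window 25.  The 10%
    feature fraction presumes a panel of at least ~100 candidate
    regulators; on very small predictor sets it degenerates to
    single-feature random splits, and raising ``feature_fraction`` toward
    1 restores a meaningful split search.
    """

    learning_rate: float = 0.01
    max_stages: int = 5000
    subsample_fraction: float = 0.9
    feature_fraction: float = 0.1
    max_tree_depth: int = 3
    early_stop_window: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.max_stages <= 0 or self.max_tree_depth <= 0:
            raise ValueError("max_stages and max_tree_depth must be positive")
        for name in ("subsample_fraction", "feature_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 < self.early_stop_window <= self.max_stages:
            raise ValueError("early_stop_window must lie in [1, max_stages]")


def fit_target_model(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame,
    params: InferenceParams,
    diagnostics: dict | None = None,
) -> np.ndarray:
    """Fit one boosted model of a target on its candidate predictors and
    return the normalized per-predictor importance vector.

    With fewer than 4 samples, row subsampling is disabled (no held-out
    rows exist to monitor), early stopping cannot engage and all stages
    are retained.  An all-zero vector is returned when no variance-
    reducing split occurred in any retained stage.  Deterministic given
    ``params.seed``.

    If a dict is passed as ``diagnostics`` it is filled with
    ``stages_trained`` and ``stages_retained``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a samples x predictors matrix with >= 1 predictor")
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and X disagree on sample count")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("expression values must be finite with no missing entries")

    n_samples, n_predictors = X.shape
    importance = np.zeros(n_predictors)
    if np.ptp(y) == 0.0:
        if diagnostics is not None:
            diagnostics.update(stages_trained=0, stages_retained=0)
        return importance

    subsample = params.subsample_fraction
    if n_samples < 4 and subsample < 1.0:
        logger.warning("fewer than 4 samples: disabling row subsampling")
        subsample = 1.0
    n_sub = min(max(1, int(round(subsample * n_samples))), n_samples)
    monitor_oob = n_sub < n_samples
    max_features = max(1, int(params.feature_fraction * n_predictors))

    rng = np.random.default_rng(params.seed)
    pred = np.full(n_samples, y.mean())
    window = params.early_stop_window
    gains: list[float] = []
    tree_importances: list[np.ndarray] = []
    all_idx = np.arange(n_samples)

    for _stage in range(params.max_stages):
        if monitor_oob:
            idx = rng.choice(n_samples, size=n_sub, replace=False)
        else:
            idx = all_idx
        tree_seed = int(rng.integers(2**31))
        residual = y - pred
        tree = DecisionTreeRegressor(
            max_depth=params.max_tree_depth,
            max_features=max_features,
            random_state=tree_seed,
        )
        tree.fit(X[idx], residual[idx])
        delta = params.learning_rate * tree.predict(X)
        if monitor_oob:
            oob = np.setdiff1d(all_idx, idx, assume_unique=True)
            before = float(np.mean(residual[oob] ** 2))
            after = float(np.mean((residual[oob] - delta[oob]) ** 2))
            gains.append(before - after)
        pred = pred + delta
        tree_importances.append(tree.tree_.compute_feature_importances(normalize=False))
        if monitor_oob and len(gains) >= window and sum(gains[-window:]) <= 0.0:
            break

    if monitor_oob:
        cum = np.cumsum(gains)
        retained = int(np.argmax(cum)) + 1 if cum.max() > 0 else 0
    else:
        retained = len(tree_importances)
    if diagnostics is not None:
        diagnostics.update(stages_trained=len(tree_importances), stages_retained=retained)
    for ti in tree_importances[:retained]:
        importance += ti
    total = importance.sum()
    return importance / total if total > 0 else np.zeros(n_predictors)


def _as_values(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    return matrix


def infer_edges(
    matrix,
    candidates: Sequence[str],
    params: InferenceParams,
    targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run one inference replicate over the candidate panel.

    For every target gene the remaining candidates act as predictors; rows
    with positive importance become edges.  The returned edge list is
    sorted by importance descending with lexicographic (regulator, target)
    tie-breaking, so identical inputs yield byte-identical output.
    """
    values = _as_values(matrix)
    candidates = list(candidates)
    missing = set(candidates) - set(values.index)
    if missing:
        raise ValueError(f"candidates absent from matrix: {sorted(missing)}")
    if targets is None:
        targets = candidates
    else:
        targets = list(targets)
        if not set(targets) <= set(candidates):
            raise ValueError("targets must be a subset of candidates")

    rows = []
    for t in targets:
        predictors = [g for g in candidates if g != t]
        if not predictors:
            continue
        imp = fit_target_model(
            values.loc[t].to_numpy(),
            values.loc[predictors].to_numpy().T,
            params,
        )
        for g, w in zip(predictors, imp):
            if w > 0:
                rows.append((g, t, float(w)))
    edges = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    edges = edges.sort_values(
        ["importance", "regulator", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return edges


def extract_target_regulators(
    edges: pd.DataFrame,
    target: str,
    mode: str = "positive",
    k: int | None = None,
) -> list[str]:
    """Predicted direct regulators of ``target`` from one replicate's edges,
    ordered by importance descending; ``top_k`` truncates to the k strongest."""
    if mode not in ("positive", "top_k"):
        raise ValueError(f"unknown extraction mode: {mode!r}")
    if mode == "top_k":
        if k is None or k < 1:
            raise ValueError("top_k extraction requires k >= 1")
    sub = edges[edges["target"] == target]
    sub = sub.sort_values(["importance", "regulator"], ascending=[False, True])
    regulators = list(sub["regulator"])
    return regulators[:k] if mode == "top_k" else regulators
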