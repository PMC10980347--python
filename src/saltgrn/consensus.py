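"""Consensus-frequency ranking over replicate inference runs.

Stability-selection style robustness: the stochastic inference is repeated
``n_runs`` times with seeds ``base_seed + 1 .. base_seed + n_runs`` and,
for the gene of interest, each candidate regulator is scored by how often
it is predicted as a direct regulator.  Condition-specific frequency
thresholds (0.80 for the stress network, 0.40 for the noisier control
network) then define the retained regulator sets.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import InferenceParams, fit_target_model, _as_values

logger = logging.getLogger(__name__)

CONSENSUS_COLUMNS = ("regulator", "count", "frequency", "mean_importance", "rank")


def run_consensus(
    matrix,
    candidates: Sequence[str],
    target: str,
    n_runs: int = 100,
    base_seed: int = 0,
    params: InferenceParams | None = None,
    extraction: str = "positive",
    k: int | None = None,
) -> pd.DataFrame:
    """Replicate target-restricted inference ``n_runs`` times and tabulate
    per-regulator prediction counts.

    Returns a DataFrame with one row per candidate regulator (the target
    itself excluded, zero-count regulators included) holding ``count``,
    ``frequency`` (= count / n_runs), ``mean_importance`` (mean over the
    runs where predicted, 0 if never) and ``rank`` under the ordering
    (frequency desc, mean_importance desc, identifier asc).  Deterministic
    given ``base_seed``.
    """
    if params is None:
        params = InferenceParams()
    candidates = list(candidates)
    if target not in candidates:
        raise ValueError(f"target {target!r} not among candidates")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if extraction not in ("positive", "top_k"):
        raise ValueError(f"unknown extraction mode: {extraction!r}")
    if extraction == "top_k" and (k is None or k < 1):
        raise ValueError("top_k extraction requires k >= 1")

    values = _as_values(matrix)
    missing = set(candidates) - set(values.index)
    if missing:
        raise ValueError(f"candidates absent from matrix: {sorted(missing)}")
    predictors = [g for g in candidates if g != target]
    y = values.loc[target].to_numpy()
    X = values.loc[predictors].to_numpy().T

    counts = np.zeros(len(predictors), dtype=int)
    imp_sums = np.zeros(len(predictors))
    order = np.lexsort((predictors,))  # identifier tie-break, precomputed
    for i in range(1, n_runs + 1):
        imp = fit_target_model(y, X, replace(params, seed=base_seed + i))
        predicted = np.flatnonzero(imp > 0)
        if extraction == "top_k" and predicted.size > k:
            # strongest k by importance, identifier-asc on ties
            key = np.lexsort((order, -imp))
            predicted = np.array([j for j in key if imp[j] > 0][:k])
        counts[predicted] += 1
        imp_sums[predicted] += imp[predicted]

    with np.errstate(invalid="ignore"):
        mean_imp = np.where(counts > 0, imp_sums / np.maximum(counts, 1), 0.0)
    table = pd.DataFrame(
        {
            "regulator": predictors,
            "count": counts,
            "frequency": counts / n_runs,
            "mean_importance": mean_imp,
        }
    )
    table = table.sort_values(
        ["frequency", "mean_importance", "regulator"], ascending=[False, False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    logger.info(
        "consensus for %s: %d runs, %d/%d regulators ever predicted",
        target, n_runs, int((counts > 0).sum()), len(predictors),
    )
    return table


def threshold_consensus(table: pd.DataFrame, min_frequency: float) -> list[str]:
    """Regulators retained at a consensus-frequency threshold (inclusive),
    in rank order.  Never-predicted regulators are excluded at every
    threshold — frequency is defined only over predicted interactions."""
    if not 0.0 <= min_frequency <= 1.0:
        raise ValueError("min_frequency must lie in [0, 1]")
    kept = table[(table["count"] >= 1) & (table["frequency"] >= min_frequency)]
    kept = kept.sort_values("rank")
    return list(kept["regulator"])
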