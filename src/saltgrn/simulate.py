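"""Synthetic condition-dependent time-course expression with a known regulatory ground truth.

The generator emulates the kind of input a consensus network-inference
pipeline sees in a salt-stress lateral-root study: a candidate panel of
~94 transcription factors profiled over a short control time course and a
longer stress time course, on a log-like additive intensity scale.  One or
more planted regulators drive the target gene linearly, optionally in one
condition only; a stress-activated regulator is transcriptionally induced
as a unimodal bump peaking a few hours into the treatment.

Non-regulator genes follow smooth, independent latent trajectories, so the
matrix has realistic between-time-point correlation but carries no signal
about the target beyond the planted edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "stress")


@dataclass(frozen=True)
class RegulatorEffect:
    """Effect of one planted regulator on the target gene.

    Parameters
    ----------
    beta
        Linear effect size on the target, per unit of regulator expression
        (log-scale units).
    condition
        Condition(s) in which the edge is active: ``"stress"``,
        ``"control"`` or ``"both"``.
    activation_time
        Hours into the stress treatment at which the regulator's own
        transcript peaks; ``None`` for regulators that are not
        stress-induced (e.g. control-active ones).
    """

    beta: float
    condition: str = "stress"
    activation_time: float | None = 3.0

    def __post_init__(self) -> None:
        if self.condition not in ("stress", "control", "both"):
            raise ValueError(f"unknown condition label: {self.condition!r}")
        if not np.isfinite(self.beta):
            raise ValueError("effect size beta must be finite")


@dataclass(frozen=True)
class GrnSpec:
    """Full description of one synthetic experiment.

    ``n_genes`` counts the whole candidate panel, target included, so the
    default panel mirrors a 94-transcription-factor input.  Control and
    stress time grids are in hours; every (condition, time point) cell gets
    ``n_replicates`` samples.  ``noise_sd`` is the per-sample Gaussian noise
    on the log-like scale, applied to every gene including the target's
    residual term.
    """

    true_regulators: dict[str, RegulatorEffect]
    n_genes: int = 94
    target_id: str = "TARGET"
    control_timepoints: tuple[float, ...] = (3.0, 24.0)
    stress_timepoints: tuple[float, ...] = (0.5, 1.0, 3.0, 6.0, 12.0, 24.0)
    n_replicates: int = 3
    noise_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    induction_amplitude: float = 1.0
    induction_width: float = 2.0
    trajectory_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < len(self.true_regulators) + 1:
            raise ValueError("n_genes must cover all regulators plus the target")
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("dimensions must be positive")
        if self.target_id in self.true_regulators:
            raise ValueError("target cannot be its own regulator")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not self.control_timepoints or not self.stress_timepoints:
            raise ValueError("each condition needs at least one time point")


@dataclass(frozen=True)
class GroundTruth:
    """Planted edges of a synthetic experiment.

    ``edges`` holds unique ``(regulator, target, beta)`` triples;
    ``condition_labels`` maps each regulator to the condition(s) where its
    edge is active (``"stress"``, ``"control"`` or ``"both"``).
    """

    edges: tuple[tuple[str, str, float], ...]
    condition_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [(r, t) for r, t, _ in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (regulator, target) edge")
        if any(r == t for r, t in pairs):
            raise ValueError("self-edges are not allowed")

    @property
    def regulators(self) -> set[str]:
        return {r for r, _, _ in self.edges}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample metadata.

    ``values`` is a genes-by-samples DataFrame; ``samples`` has one row per
    column of ``values`` with columns ``sample``, ``condition``, ``time_h``
    and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        missing = set(self.samples["sample"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"metadata samples absent from matrix: {sorted(missing)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be numeric and finite")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.loc[self.samples["condition"] == condition, "sample"]
        return list(sel)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        meta = self.samples[self.samples["sample"].isin(samples)].reset_index(drop=True)
        return ExpressionMatrix(self.values[list(samples)], meta)


def _format_time(t: float) -> str:
    return f"{t:g}".replace(".", "p")


def _gene_universe(spec: GrnSpec) -> list[str]:
    """Panel row order: auto-named fillers and named regulators interleaved
    in sorted order, target last."""
    named = set(spec.true_regulators) | {spec.target_id}
    fillers: list[str] = []
    i = 1
    while len(fillers) + len(named) < spec.n_genes:
        g = f"TF{i:03d}"
        if g not in named:
            fillers.append(g)
        i += 1
    non_target = sorted(fillers + list(spec.true_regulators))
    return non_target + [spec.target_id]


def _induction_bump(spec: GrnSpec, times: np.ndarray, activation_time: float) -> np.ndarray:
    w = spec.induction_width
    return 1.0 + spec.induction_amplitude * np.exp(-((times - activation_time) ** 2) / (2.0 * w * w))


def simulate_expression(spec: GrnSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one synthetic experiment from ``spec``.

    Every non-target gene follows a smooth quadratic latent trajectory in
    time (shared across replicates) plus i.i.d. replicate noise; stress-
    induced regulators are additionally multiplied by a unimodal bump
    peaking at their activation time, in stress samples only.  The target
    row is the sum of ``beta * regulator`` over the regulators active in
    each sample's condition, plus Gaussian noise — it has no baseline of
    its own, so at ``noise_sd=0`` it is an exact linear function of its
    regulators.

    Returns the expression matrix (with sample metadata) and the planted
    ground truth.  Identical ``spec`` (including ``seed``) yields an
    identical matrix.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_universe(spec)
    non_target = genes[:-1]

    cells: list[tuple[str, float, int]] = []
    for cond, grid in (("control", spec.control_timepoints), ("stress", spec.stress_timepoints)):
        for t in grid:
            for rep in range(1, spec.n_replicates + 1):
                cells.append((cond, float(t), rep))
    sample_ids = [f"{c}_t{_format_time(t)}_r{r}" for c, t, r in cells]
    times = np.array([t for _, t, _ in cells])
    is_stress = np.array([c == "stress" for c, _, _ in cells])

    all_times = np.array(sorted(set(spec.control_timepoints) | set(spec.stress_timepoints)))
    mid = (all_times.min() + all_times.max()) / 2.0
    half = max((all_times.max() - all_times.min()) / 2.0, 1.0)
    tau = (times - mid) / half

    n_nt = len(non_target)
    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_nt)
    coef = rng.normal(0.0, spec.trajectory_sd, size=(n_nt, 2))
    noise = rng.normal(0.0, spec.noise_sd, size=(n_nt, len(cells)))
    target_noise = rng.normal(0.0, spec.noise_sd, size=len(cells))

    X = np.empty((len(genes), len(cells)))
    row_of = {g: i for i, g in enumerate(genes)}
    for i, g in enumerate(non_target):
        traj = mu[i] + coef[i, 0] * tau + coef[i, 1] * tau**2
        eff = spec.true_regulators.get(g)
        if eff is not None and eff.activation_time is not None:
            bump = _induction_bump(spec, times, eff.activation_time)
            traj = np.where(is_stress, traj * bump, traj)
        X[row_of[g]] = traj + noise[i]

    y = target_noise.copy()
    for g, eff in spec.true_regulators.items():
        if eff.condition == "both":
            active = np.ones(len(cells), dtype=bool)
        elif eff.condition == "stress":
            active = is_stress
        else:
            active = ~is_stress
        y = y + np.where(active, eff.beta * X[row_of[g]], 0.0)
    X[row_of[spec.target_id]] = y

    values = pd.DataFrame(X, index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample": sample_ids,
            "condition": [c for c, _, _ in cells],
            "time_h": times,
            "replicate": [r for _, _, r in cells],
        }
    )
    truth = GroundTruth(
        edges=tuple(
            (g, spec.target_id, eff.beta) for g, eff in sorted(spec.true_regulators.items())
        ),
        condition_labels={g: eff.condition for g, eff in spec.true_regulators.items()},
    )
    logger.info(
        "simulated %d genes x %d samples (%d regulators planted)",
        len(genes), len(cells), len(spec.true_regulators),
    )
    return ExpressionMatrix(values, meta), truth


def corrupt_evidence(
    truth: GroundTruth,
    universe: set[str] | list[str],
    sensitivity: float,
    fp_rate: float,
    seed: int,
) -> list[str]:
    """Noisy evidence list over ``universe`` (e.g. a one-hybrid hit list or
    a promoter-binding list): each true regulator enters with probability
    ``sensitivity``, each non-regulator with probability ``fp_rate``.

    Returns a sorted gene list; deterministic for a fixed seed.
    """
    for name, rate in (("sensitivity", sensitivity), ("fp_rate", fp_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    regs = truth.regulators
    if not regs <= set(universe):
        raise ValueError("universe must contain every true regulator")
    rng = np.random.default_rng(seed)
    out = []
    for g in sorted(universe):
        p = sensitivity if g in regs else fp_rate
        if rng.random() < p:
            out.append(g)
    return out


def study_shaped_spec(seed: int = 0, **overrides) -> GrnSpec:
    """The default study-shaped experiment: a 94-gene panel over 2 control
    and 6 stress time points with 3 replicates each, one stress-specific
    regulator induced at 3 h driving the target strongly, and one
    control-active regulator.
    """
    spec = GrnSpec(
        true_regulators={
            "TF045": RegulatorEffect(beta=2.0, condition="stress", activation_time=3.0),
            "TF017": RegulatorEffect(beta=2.0, condition="control", activation_time=None),
        },
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec
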