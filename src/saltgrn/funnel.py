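"""Candidate funnel: moderated two-group differential expression and the
set logic that assembles the panel entering network inference.

The statistics follow the empirical-Bayes moderated-t methodology standard
in microarray/RNA-seq differential expression: per-gene residual variances
s_g^2 with d_g degrees of freedom are shrunk toward a prior (d0, s0^2)
fitted by moment matching on log variances, giving the posterior variance

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and a moderated t statistic referred to a t distribution with d0 + d_g
degrees of freedom.  d0 = 0 recovers the ordinary pooled two-sample t;
d0 = inf pins every gene's variance at s0^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_PROVENANCE_ORDER = ("target", "known-regulator", "one-hybrid")


@dataclass(frozen=True)
class ShrinkagePrior:
    """Empirical-Bayes prior on gene-wise variances.

    ``d0`` is the prior degrees of freedom (``math.inf`` allowed, meaning
    complete shrinkage; 0 means no shrinkage), ``s0_sq`` the prior variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be nonnegative")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def _trigamma(x):
    return polygamma(1, x)


def _digamma(x):
    return polygamma(0, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (damped Newton on the inverse scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def estimate_prior(s2: np.ndarray, d_g: float) -> ShrinkagePrior:
    """Moment-matching fit of (d0, s0^2) from observed gene variances.

    Matches the first two moments of log s_g^2 under the scaled-F model:
    the excess variance of log variances over the trigamma floor
    trigamma(d_g/2) identifies d0; when the observed spread is at or below
    the floor, d0 = inf (the variances are consistent with a single shared
    value, estimated by their mean).  Zero variances are offset to a small
    fraction of the median before taking logs.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 0.0)
    if s2.size < 2:
        raise ValueError("need at least two gene variances to estimate the prior")
    med = float(np.median(s2))
    if med == 0.0:
        raise ValueError("more than half of the gene variances are zero; prior not estimable")
    s2 = np.maximum(s2, 1e-5 * med)
    z = np.log(s2)
    e = z - float(_digamma(d_g / 2.0)) + math.log(d_g / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    excess = evar - float(_trigamma(d_g / 2.0))
    if excess <= 0:
        return ShrinkagePrior(d0=math.inf, s0_sq=float(np.mean(s2)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(emean + float(_digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return ShrinkagePrior(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    prior: ShrinkagePrior | str = "estimate",
) -> pd.DataFrame:
    """Per-gene moderated t test of group_a vs group_b (log2_fc = mean A - mean B).

    ``matrix`` is genes x samples on a log scale.  Returns a DataFrame
    indexed by gene with columns ``log2_fc``, ``s2_g``, ``d_g``, ``t_mod``,
    ``p`` and BH-adjusted ``p_adj``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    missing = (set(group_a) | set(group_b)) - set(matrix.columns)
    if missing:
        raise ValueError(f"samples absent from matrix: {sorted(missing)}")

    A = matrix[group_a].to_numpy(dtype=float)
    B = matrix[group_b].to_numpy(dtype=float)
    na, nb = len(group_a), len(group_b)
    d_g = na + nb - 2
    lfc = A.mean(axis=1) - B.mean(axis=1)
    s2 = (A.var(axis=1, ddof=1) * (na - 1) + B.var(axis=1, ddof=1) * (nb - 1)) / d_g

    if prior == "estimate":
        prior = estimate_prior(s2, d_g)
    elif not isinstance(prior, ShrinkagePrior):
        raise TypeError("prior must be a ShrinkagePrior or 'estimate'")

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d_g * s2) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g
    # total df cannot exceed the pooled residual df of the whole matrix
    df_total = min(df_total, d_g * len(matrix))

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
        # zero posterior variance (only possible at d0=0 on a constant gene):
        # equal means -> no evidence (t=0, p=1); unequal -> infinitely strong.
        t = np.where(se == 0, np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf), t)
    from scipy import stats

    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.minimum(p, 1.0)

    table = pd.DataFrame(
        {
            "log2_fc": lfc,
            "s2_g": s2,
            "d_g": float(d_g),
            "t_mod": t,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=matrix.index,
    )
    logger.info(
        "moderated t: %d genes, %d vs %d samples, prior d0=%.4g s0_sq=%.4g",
        len(table), na, nb, prior.d0, prior.s0_sq,
    )
    return table


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    table: pd.DataFrame,
    lfc_min: float,
    p_max: float,
    use_adjusted: bool = True,
    direction: str = "both",
) -> set[str]:
    """Genes passing |log2_fc| >= lfc_min (restricted by ``direction``) and
    the chosen p-column <= p_max; both comparisons inclusive."""
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction: {direction!r}")
    if not (np.isfinite(lfc_min) and np.isfinite(p_max)) or lfc_min < 0:
        raise ValueError("thresholds must be finite with lfc_min >= 0")
    if table.empty:
        return set()
    lfc = table["log2_fc"]
    if direction == "up":
        fc_ok = lfc >= lfc_min
    elif direction == "down":
        fc_ok = lfc <= -lfc_min
    else:
        fc_ok = lfc.abs() >= lfc_min
    pcol = table["p_adj"] if use_adjusted else table["p"]
    return set(table.index[fc_ok & (pcol <= p_max)])


class Overlap(NamedTuple):
    intersection: set[str]
    a_only: set[str]
    b_only: set[str]


def overlap_sets(set_a: set[str], set_b: set[str]) -> Overlap:
    """Exact partition of two gene sets into intersection and exclusives."""
    set_a, set_b = set(set_a), set(set_b)
    return Overlap(set_a & set_b, set_a - set_b, set_b - set_a)


@dataclass(frozen=True)
class CandidateList:
    """Ordered, deduplicated panel entering network inference.

    ``entries`` pairs each gene with its provenance class (``target``,
    ``known-regulator`` or ``one-hybrid``); order is provenance class
    first (target, known, one-hybrid), identifier-sorted within class.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene in candidate list")
        if sum(1 for _, prov in self.entries if prov == "target") != 1:
            raise ValueError("candidate list must contain the target exactly once")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.genes)


def build_candidate_list(
    overlap_degs: set[str],
    y1h_hits: set[str],
    known_regulators: set[str],
    target: str,
) -> CandidateList:
    """Assemble the inference panel: (y1h ∩ overlap DEGs) ∪ known ∪ {target}.

    Provenance precedence when a gene qualifies in several classes:
    target > known-regulator > one-hybrid.  Deterministic order: target
    first, then known regulators, then one-hybrid hits, identifier-sorted
    within class.
    """
    if not target or not isinstance(target, str):
        raise ValueError("target must be a nonempty identifier")
    y1h_kept = set(y1h_hits) & set(overlap_degs)
    known = set(known_regulators)
    entries = [(target, "target")]
    entries += [(g, "known-regulator") for g in sorted(known - {target})]
    entries += [(g, "one-hybrid") for g in sorted(y1h_kept - known - {target})]
    logger.info(
        "candidate funnel: |y1h|=%d |overlap|=%d |y1h∩overlap|=%d |known|=%d -> %d candidates",
        len(set(y1h_hits)), len(set(overlap_degs)), len(y1h_kept), len(known), len(entries),
    )
    return CandidateList(tuple(entries))
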