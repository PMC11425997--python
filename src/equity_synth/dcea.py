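"""Aggregate distributional cost-effectiveness analysis.

Given one summary result per screening programme (per-person incremental
QALYs and cost, an opportunity-cost threshold K, and the number of people
screened), the analysis spreads both the health gains and the opportunity
costs over socioeconomic groups and asks whether the programme narrows or
widens the health gap:

1. a baseline health distribution: quality-adjusted life expectancy
   (QALE) per person in each deprivation quintile;
2. an opportunity-cost distribution: the share d_j of forgone health
   borne by each group when resources are diverted;
3. per-group net health benefit
   NHB_j = dQALY * n_j - N * dcost * d_j / K  (QALYs);
4. the post-intervention distribution, adding NHB_j / n_j per person;
5. Atkinson-index social welfare: A(eps) measures inequality and the
   equally distributed equivalent health EDEH = N * (1 - A) * mean(h) is
   the equal distribution with the same welfare;
6. the population equity impact, incremental EDEH minus incremental NHB:
   positive means the programme reduces health inequality.

The Atkinson mean over groups is unweighted (quintiles are population
fifths by construction); a population-share-weighted variant is available
for non-quintile group structures.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .core_types import DceaResult, DceaScenario, Direction, SubgroupDistribution

__all__ = [
    "DEFAULT_EPSILON",
    "allocate_population",
    "group_nhb",
    "total_nhb",
    "atkinson_index",
    "edeh",
    "post_intervention_qale",
    "run_dcea",
]

# inequality aversion measured empirically for the UK population
DEFAULT_EPSILON = 10.95


def allocate_population(n_total: float, distribution: SubgroupDistribution) -> np.ndarray:
    """Per-group patient counts n_j = n_total * pop_share_j (real-valued)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return n_total * np.asarray(distribution.pop_share, dtype=float)


def group_nhb(scenario: DceaScenario) -> np.ndarray:
    """Per-group net health benefit, in QALYs.

    NHB_j = dQALY * n_j - N * dcost * d_j / K: the group's share of the
    health gain minus its share of the health forgone elsewhere when the
    programme's budget displaces other care.  Groups carrying a large
    opportunity-cost share can come out negative.
    """
    if scenario.wtp_threshold <= 0:
        raise ValueError("opportunity-cost threshold K must be positive")
    n_j = allocate_population(scenario.n_total, scenario.distribution)
    d_j = np.asarray(scenario.distribution.opp_share, dtype=float)
    gain = scenario.delta_qaly_pp * n_j
    forgone = scenario.n_total * scenario.delta_cost_pp * d_j / scenario.wtp_threshold
    return gain - forgone


def total_nhb(scenario: DceaScenario) -> float:
    """Population net health benefit dQALY*N - N*dcost/K (QALYs).

    Equals the sum of the per-group values because the population and
    opportunity-cost shares each sum to one.
    """
    return (
        scenario.delta_qaly_pp * scenario.n_total
        - scenario.n_total * scenario.delta_cost_pp / scenario.wtp_threshold
    )


def atkinson_index(
    h: Sequence[float],
    epsilon: float,
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Atkinson inequality index A(eps) of a positive health distribution.

    A(eps) = 1 - ( mean_i (h_i / hbar)^(1-eps) )^(1/(1-eps)), with the
    geometric-mean limit A = 1 - GM(h)/hbar at eps = 1.  A is 0 iff the
    distribution is equal, approaches 1 as aversion and inequality grow.
    ``weights`` (population shares) replace the unweighted mean when
    groups are not equal-sized.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("Atkinson index requires strictly positive health values")
    if epsilon < 0:
        raise ValueError("inequality aversion epsilon must be nonnegative")
    if weights is None:
        w = np.full(h.shape, 1.0 / h.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != h.shape or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must match h and sum to 1")
    hbar = float(w @ h)
    if epsilon == 1.0:
        # limit eps -> 1: equally-distributed equivalent is the geometric mean
        return 1.0 - float(np.exp(w @ np.log(h))) / hbar
    p = 1.0 - epsilon
    ede = float(w @ (h / hbar) ** p) ** (1.0 / p)
    return 1.0 - ede


def edeh(h: Sequence[float], epsilon: float, n_total: float, weights=None) -> float:
    """Total equally distributed equivalent health N * (1 - A(eps)) * mean(h).

    The total health (QALYs over ``n_total`` people) that, shared
    perfectly equally, would yield the same social welfare as the actual
    distribution; never exceeds N * mean(h).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    h = np.asarray(h, dtype=float)
    a = atkinson_index(h, epsilon, weights)
    if weights is None:
        hbar = float(h.mean())
    else:
        hbar = float(np.asarray(weights, dtype=float) @ h)
    return n_total * (1.0 - a) * hbar


def post_intervention_qale(
    qale_pre: Sequence[float], nhb_by_group: Sequence[float], n_j: Sequence[float]
) -> np.ndarray:
    """Fold the per-group net health benefit into the baseline distribution.

    Per-person: qale_post_j = qale_pre_j + NHB_j / n_j.
    """
    qale_pre = np.asarray(qale_pre, dtype=float)
    nhb = np.asarray(nhb_by_group, dtype=float)
    n_j = np.asarray(n_j, dtype=float)
    if not (qale_pre.shape == nhb.shape == n_j.shape):
        raise ValueError("qale_pre, nhb_by_group and n_j must have matching lengths")
    if np.any(n_j <= 0):
        raise ValueError("every group must have a positive population")
    return qale_pre + nhb / n_j


def run_dcea(scenario: DceaScenario, weighted_mean: bool = False) -> DceaResult:
    """Execute the full six-step distributional analysis for one scenario.

    equity_impact = (EDEH_post - EDEH_pre) - total NHB; a positive value
    means health gains are distributed in an inequality-reducing way.
    Aborts if any post-intervention QALE is non-positive (the Atkinson
    welfare function is undefined there).
    """
    dist = scenario.distribution
    n_j = allocate_population(scenario.n_total, dist)
    nhb_j = group_nhb(scenario)
    tot = total_nhb(scenario)

    qale_pre = np.asarray(dist.qale, dtype=float)
    qale_post = post_intervention_qale(qale_pre, nhb_j, n_j)
    if np.any(qale_post <= 0):
        raise ValueError(
            "post-intervention QALE is non-positive in at least one group; "
            "Atkinson welfare is undefined for non-positive health"
        )
    if np.any(qale_post < qale_pre):
        warnings.warn(
            "negative net health benefit in at least one group: post-intervention "
            "QALE falls below baseline there",
            stacklevel=2,
        )

    w = np.asarray(dist.pop_share, dtype=float) if weighted_mean else None
    a_pre = atkinson_index(qale_pre, scenario.epsilon, w)
    a_post = atkinson_index(qale_post, scenario.epsilon, w)
    edeh_pre = edeh(qale_pre, scenario.epsilon, scenario.n_total, w)
    edeh_post = edeh(qale_post, scenario.epsilon, scenario.n_total, w)
    delta_edeh = edeh_post - edeh_pre
    equity = delta_edeh - tot

    tol = 1e-9 * max(1.0, abs(tot))
    if equity > tol:
        direction = Direction.reduces_inequality
    elif equity < -tol:
        direction = Direction.increases_inequality
    else:
        direction = Direction.neutral

    return DceaResult(
        group_nhb=tuple(float(x) for x in nhb_j),
        total_nhb=tot,
        qale_pre=tuple(float(x) for x in qale_pre),
        qale_post=tuple(float(x) for x in qale_post),
        atkinson_pre=a_pre,
        atkinson_post=a_post,
        edeh_pre=edeh_pre,
        edeh_post=edeh_post,
        delta_edeh=delta_edeh,
        equity_impact=equity,
        direction=direction,
    )
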