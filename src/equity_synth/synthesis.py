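"""Within-group evidence synthesis: pooled ICERs, COMER weights, TNHB.

A synthesis group holds studies of one screening strategy measured in one
outcome unit.  Pooling is deterministic: total incremental cost and effect
are straight sums, and the pooled ICER is their ratio.  Each study also
gets a net monetary benefit NHB = lambda * delta_effect - delta_cost at
its own (converted) willingness-to-pay threshold lambda; the comparative-
efficiency (COMER) weights are proportional to NHB^(-2), so studies whose
net benefit is close to zero — the decision margin — dominate the weighted
aggregate, and the total net health benefit TNHB is the weighted sum of
the per-study NHBs.

Two interval modes are provided: "paper" mode brackets any point estimate
with +/-25% (the convention used for every printed interval in the source
tables), and an explicit first-order delta-method interval for the ICER
when standard errors are available.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .core_types import Dominance, Interval, StudyRecord, SynthesisGroup

__all__ = [
    "SynthesisResult",
    "DegenerateWeightsError",
    "combine_cohorts",
    "pool_group",
    "net_monetary_benefit",
    "comer_weights",
    "weighted_totals",
    "paper_interval",
    "delta_icer_ci",
    "se_from_interval",
    "synthesize_group",
]


class DegenerateWeightsError(ValueError):
    """Raised when a zero net benefit makes inverse-square weights undefined."""


class SynthesisResult(BaseModel):
    """Pooled and weighted summaries for one synthesis group."""

    model_config = ConfigDict(frozen=True)

    strategy: str
    outcome: str
    n_studies: int
    total_cost: float
    total_effect: float
    icer: Optional[float]
    icer_interval: Optional[Interval]
    dominance: Dominance
    per_study_nhb: tuple[float, ...]
    weights: tuple[float, ...]
    weighted_cost: float
    weighted_effect: float
    tnhb: float
    tnhb_interval: Interval
    mode: str = Field(default="paper")

    def to_json_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "outcome": self.outcome,
            "n_studies": self.n_studies,
            "total_cost": self.total_cost,
            "total_effect": self.total_effect,
            "icer": self.icer,
            "icer_low": self.icer_interval.low if self.icer_interval else None,
            "icer_high": self.icer_interval.high if self.icer_interval else None,
            "dominance": self.dominance.value,
            "weights": list(self.weights),
            "nhb": list(self.per_study_nhb),
            "weighted_cost": self.weighted_cost,
            "weighted_effect": self.weighted_effect,
            "tnhb": self.tnhb,
            "tnhb_low": self.tnhb_interval.low,
            "tnhb_high": self.tnhb_interval.high,
        }


def combine_cohorts(cohorts: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Average per-cohort (delta_cost, delta_effect) pairs into one record's values."""
    if not cohorts:
        raise ValueError("cannot combine an empty cohort list")
    n = len(cohorts)
    return sum(c for c, _ in cohorts) / n, sum(e for _, e in cohorts) / n


def pool_group(
    group: SynthesisGroup,
) -> tuple[float, float, Optional[float], Dominance]:
    """Sum incremental costs and effects and form the pooled ICER.

    Returns (total_cost, total_effect, icer, dominance).  A dominant
    result (cost saving with health gain) or a dominated one (extra cost
    with health loss) is flagged instead of reporting a negative ratio;
    the totals themselves always include every record, whatever its signs.
    """
    total_cost = sum(r.delta_cost for r in group.records)
    total_effect = sum(r.delta_effect for r in group.records)
    if total_cost < 0 and total_effect > 0:
        return total_cost, total_effect, None, Dominance.dominant
    if total_cost > 0 and total_effect < 0:
        return total_cost, total_effect, None, Dominance.dominated
    if total_effect == 0:
        raise ZeroDivisionError(
            f"pooled incremental effect of group {group.label} is zero; ICER undefined"
        )
    return total_cost, total_effect, total_cost / total_effect, Dominance.none


def net_monetary_benefit(record: StudyRecord) -> float:
    """Per-study net monetary benefit lambda * delta_effect - delta_cost (USD)."""
    return record.wtp * record.delta_effect - record.delta_cost


def comer_weights(nhb_values: Sequence[float]) -> np.ndarray:
    """Comparative-efficiency weights: omega_i proportional to NHB_i^(-2).

    Sign-insensitive (squared) and scale-invariant: multiplying every NHB
    by a common nonzero factor leaves the weights unchanged.  Weights sum
    to one.  A zero NHB is rejected — its inverse-square weight would
    swamp the group; callers should perturb the threshold or supply
    weights explicitly.
    """
    nhb = np.asarray(nhb_values, dtype=float)
    if nhb.size == 0:
        raise DegenerateWeightsError("no net-benefit values to weight")
    if np.any(nhb == 0.0):
        raise DegenerateWeightsError(
            "zero net benefit encountered: inverse-square weights are undefined; "
            "supply explicit weights or adjust the threshold"
        )
    # normalize by the smallest magnitude first so the squares stay finite
    scaled = np.abs(nhb) / np.min(np.abs(nhb))
    inv2 = scaled**-2.0
    return inv2 / inv2.sum()


def weighted_totals(
    records: Sequence[StudyRecord], weights: Sequence[float]
) -> tuple[float, float, float]:
    """Weighted incremental cost, effect, and total net health benefit.

    Returns (sum w*c, sum w*e, sum w*NHB); weights must match the records
    and sum to one.
    """
    if len(records) != len(weights):
        raise ValueError(f"{len(records)} records but {len(weights)} weights")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    c = np.array([r.delta_cost for r in records])
    e = np.array([r.delta_effect for r in records])
    nhb = np.array([net_monetary_benefit(r) for r in records])
    return float(w @ c), float(w @ e), float(w @ nhb)


def paper_interval(point: float) -> Interval:
    """The +/-25% reporting interval used around every printed point estimate."""
    a, b = 0.75 * point, 1.25 * point
    return Interval(low=min(a, b), high=max(a, b))


def delta_icer_ci(
    total_cost: float,
    total_effect: float,
    se_cost: float,
    se_effect: float,
    correlation: float = 0.0,
    level: float = 0.95,
) -> Interval:
    """First-order delta-method confidence interval for a cost/effect ratio.

    var(R) ~= R^2 * (se_c^2/c^2 + se_e^2/e^2 - 2 rho se_c se_e / (c e)),
    with a symmetric normal interval at the requested level.  Accurate
    when the coefficient of variation of the denominator is small.
    """
    if total_effect == 0:
        raise ZeroDivisionError("ratio undefined for zero total effect")
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    for name, v in (("se_cost", se_cost), ("se_effect", se_effect), ("correlation", correlation)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite {name}: {v}")
    r = total_cost / total_effect
    var = r * r * (
        (se_cost / total_cost) ** 2 if total_cost != 0 else 0.0
    ) + r * r * (se_effect / total_effect) ** 2
    if total_cost != 0:
        var -= 2 * r * r * correlation * se_cost * se_effect / (total_cost * total_effect)
    var = max(var, 0.0)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return Interval(low=r - half, high=r + half)


def se_from_interval(interval: Interval, level: float = 0.95) -> float:
    """Standard error implied by reading an interval as a normal CI at ``level``."""
    z = stats.norm.ppf(0.5 + level / 2)
    return interval.width / (2 * z)


def _group_se(records: Sequence[StudyRecord], which: str) -> float:
    """SE of a summed quantity from per-study intervals, assuming independence."""
    var = 0.0
    for r in records:
        iv = r.cost_interval if which == "cost" else r.effect_interval
        if iv is None:
            from .standardize import default_interval

            iv = default_interval(r.delta_cost if which == "cost" else r.delta_effect)
        var += se_from_interval(iv) ** 2
    return math.sqrt(var)


def synthesize_group(
    group: SynthesisGroup,
    mode: str = "paper",
    weights: Optional[Sequence[float]] = None,
    level: float = 0.95,
) -> SynthesisResult:
    """Full synthesis of one group: pooling, weighting, and intervals.

    ``mode="paper"`` brackets the pooled ICER and the TNHB with the
    +/-25% reporting convention; ``mode="delta"`` instead derives the ICER
    interval by the delta method from per-study intervals (reported CIs
    when present, +/-50% defaults otherwise, read as normal 95% CIs).
    User-supplied ``weights`` override the inverse-square-NHB rule.
    """
    if mode not in ("paper", "delta"):
        raise ValueError(f"unknown interval mode {mode!r}")
    total_cost, total_effect, icer, dominance = pool_group(group)
    nhb = [net_monetary_benefit(r) for r in group.records]
    w = np.asarray(weights, dtype=float) if weights is not None else comer_weights(nhb)
    weighted_cost, weighted_effect, tnhb = weighted_totals(group.records, w)

    icer_interval: Optional[Interval] = None
    if icer is not None:
        if mode == "paper":
            icer_interval = paper_interval(icer)
        else:
            icer_interval = delta_icer_ci(
                total_cost,
                total_effect,
                se_cost=_group_se(group.records, "cost"),
                se_effect=_group_se(group.records, "effect"),
                level=level,
            )
    tnhb_interval = paper_interval(tnhb)

    return SynthesisResult(
        strategy=group.strategy_type.value,
        outcome=group.outcome_measure.value,
        n_studies=len(group.records),
        total_cost=total_cost,
        total_effect=total_effect,
        icer=icer,
        icer_interval=icer_interval,
        dominance=dominance,
        per_study_nhb=tuple(nhb),
        weights=tuple(float(x) for x in w),
        weighted_cost=weighted_cost,
        weighted_effect=weighted_effect,
        tnhb=tnhb,
        tnhb_interval=tnhb_interval,
        mode=mode,
    )
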