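"""Synthetic evidence bases with known ground truth, plus published fixtures.

``generate_studies`` draws a study set around a known true ICER so the
pooling and weighting machinery can be validated by parameter recovery:
per-study effects are lognormal (screening programmes differ hugely in
scale), costs are ``true_icer * effect`` with multiplicative Gaussian
noise, a configurable fraction of studies is cost-saving (negative cost),
and thresholds are uniform over a plausible range.

``generate_distribution`` builds socioeconomic gradients by linear
interpolation between deprivation-quintile endpoints, emulating the UK
baseline QALE gradient (63.21 -> 75.00 years) and opportunity-cost
gradient (26% -> 14%).

``table3_fixture`` / ``table4_fixture`` return the hand-encoded published
evidence (see ``_tables``), ready for the synthesis and distributional
pipelines.
"""
from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import _tables
from .core_types import (
    DceaScenario,
    OutcomeMeasure,
    StrategyType,
    StudyRecord,
    SubgroupDistribution,
    SynthesisGroup,
)
from .standardize import default_interval

__all__ = [
    "StudySetConfig",
    "generate_studies",
    "generate_distribution",
    "default_uk_distribution",
    "table3_fixture",
    "table3_printed_summary",
    "table4_fixture",
]


class StudySetConfig(BaseModel):
    """Parameters of a synthetic study set with a known true ICER."""

    model_config = ConfigDict(frozen=True)

    n_studies: int = Field(default=5, ge=1)
    true_icer: float = 50_000.0
    effect_scale: float = 1.0  # lognormal median of per-study effects
    effect_sigma: float = Field(default=0.5, ge=0)  # log-scale spread of effects
    cost_noise_cv: float = Field(default=0.2, ge=0)
    wtp_range: tuple[float, float] = (20_000.0, 150_000.0)
    dominance_prob: float = Field(default=0.1, ge=0, le=1)
    seed: int = 0
    strategy_type: StrategyType = StrategyType.cascade
    outcome_measure: OutcomeMeasure = OutcomeMeasure.QALY


def generate_studies(config: StudySetConfig) -> list[StudyRecord]:
    """Draw a reproducible synthetic study set.

    effect_i ~ Lognormal(ln(effect_scale), effect_sigma);
    cost_i = true_icer * effect_i * (1 + eta_i), eta_i ~ N(0, cv), with
    the cost sign flipped (cost-saving study) with ``dominance_prob``;
    wtp_i ~ Uniform(wtp_range).  The +/-50% default intervals are
    attached to every cost and effect.
    """
    rng = np.random.default_rng(config.seed)
    effects = rng.lognormal(mean=np.log(config.effect_scale), sigma=config.effect_sigma,
                            size=config.n_studies)
    noise = rng.normal(0.0, config.cost_noise_cv, size=config.n_studies)
    costs = config.true_icer * effects * (1.0 + noise)
    flip = rng.random(config.n_studies) < config.dominance_prob
    costs = np.where(flip, -np.abs(costs), costs)
    wtps = rng.uniform(*config.wtp_range, size=config.n_studies)

    records = []
    for i in range(config.n_studies):
        records.append(
            StudyRecord(
                study_id=f"synthetic-{i:03d}",
                strategy_type=config.strategy_type,
                outcome_measure=config.outcome_measure,
                delta_cost=float(costs[i]),
                delta_effect=float(effects[i]),
                wtp=float(wtps[i]),
                cost_interval=default_interval(float(costs[i])),
                effect_interval=default_interval(float(effects[i])),
                perspective="synthetic",
                meta={"provenance": "synthetic", "true_icer": config.true_icer},
            )
        )
    return records


def generate_distribution(
    gradient: tuple[float, float],
    opp_gradient: tuple[float, float],
    n_groups: int = 5,
) -> SubgroupDistribution:
    """Linearly interpolated socioeconomic gradients over ``n_groups`` quintile-like groups.

    ``gradient`` gives baseline QALE for the most- and least-deprived
    groups; ``opp_gradient`` the opportunity-cost shares at the two ends,
    normalized to sum to one while preserving their ratio structure.
    Population shares are equal.
    """
    if n_groups < 1:
        raise ValueError("need at least one group")
    qale = np.linspace(gradient[0], gradient[1], n_groups)
    if np.any(qale <= 0):
        raise ValueError(f"infeasible QALE gradient {gradient}: non-positive values")
    opp = np.linspace(opp_gradient[0], opp_gradient[1], n_groups)
    if np.any(opp < 0) or opp.sum() <= 0:
        raise ValueError(f"infeasible opportunity-cost gradient {opp_gradient}")
    opp = opp / opp.sum()
    pop = np.full(n_groups, 1.0 / n_groups)
    # renormalize in compensated arithmetic so shares sum to 1 within 1e-9
    pop[-1] = 1.0 - pop[:-1].sum()
    opp[-1] = 1.0 - opp[:-1].sum()
    return SubgroupDistribution(
        labels=tuple(f"IMD{i + 1}" for i in range(n_groups)),
        qale=tuple(float(x) for x in qale),
        opp_share=tuple(float(x) for x in opp),
        pop_share=tuple(float(x) for x in pop),
    )


def default_uk_distribution(n_groups: int = 5) -> SubgroupDistribution:
    """The default UK deprivation-quintile structure used throughout."""
    return generate_distribution(
        _tables.QALE_ENDPOINTS, _tables.OPP_SHARE_ENDPOINTS, n_groups
    )


def table3_fixture() -> list[SynthesisGroup]:
    """The seven published synthesis groups, thresholds back-solved per row.

    Each record's ``meta`` carries the printed NHB and COMER weight plus
    provenance flags (``printed`` values vs ``back_solved`` lambda).
    """
    groups = []
    for (strategy, outcome), rows in _tables.SYNTHESIS_ROWS.items():
        records = []
        for study_id, cost, effect, nhb, weight in rows:
            cohorts = _tables.COHORTS.get((study_id, outcome))
            records.append(
                StudyRecord(
                    study_id=study_id,
                    strategy_type=StrategyType(strategy),
                    outcome_measure=OutcomeMeasure(outcome),
                    delta_cost=cost,
                    delta_effect=effect,
                    wtp=_tables.back_solved_wtp(cost, effect, nhb),
                    cost_interval=default_interval(cost),
                    effect_interval=default_interval(effect),
                    cohorts=tuple(cohorts) if cohorts else None,
                    meta={
                        "printed_nhb": nhb,
                        "printed_weight": weight,
                        "wtp_provenance": "back_solved",
                        "cost_provenance": "printed",
                    },
                )
            )
        groups.append(
            SynthesisGroup(
                strategy_type=StrategyType(strategy),
                outcome_measure=OutcomeMeasure(outcome),
                records=tuple(records),
            )
        )
    return groups


def table3_printed_summary() -> dict[tuple[str, str], dict]:
    """Printed group-level summaries (pooled ICER, weighted totals, TNHB)."""
    return {k: dict(v) for k, v in _tables.SYNTHESIS_SUMMARY.items()}


def table4_fixture(epsilon: float = 10.95) -> list[DceaScenario]:
    """The six published distributional-analysis scenarios.

    All use the default UK quintile distribution; ``meta`` carries the
    printed incremental NHB/EDEH and a provenance flag (the Crosland row's
    inputs are reconstructed from a garbled source table).
    """
    dist = default_uk_distribution()
    scenarios = []
    for study_id, row in _tables.DCEA_ROWS.items():
        scenarios.append(
            DceaScenario(
                study_id=study_id,
                delta_qaly_pp=row["delta_qaly_pp"],
                delta_cost_pp=row["delta_cost_pp"],
                wtp_threshold=row["wtp"],
                n_total=row["n_total"],
                distribution=dist,
                epsilon=epsilon,
                meta={
                    "printed_dnhb": row["printed_dnhb"],
                    "printed_dedeh": row["printed_dedeh"],
                    "printed_diff": row["printed_diff"],
                    "provenance": row["provenance"],
                },
            )
        )
    return scenarios
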