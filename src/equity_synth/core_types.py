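"""Domain types and file IO for the screening-economics evidence base.

The central objects are :class:`StudyRecord` (one extracted economic
evaluation: incremental cost and effect against a comparator, with the
study's willingness-to-pay threshold already converted to the reference
currency-year, 2023 USD), :class:`SynthesisGroup` (records pooled because
they evaluate the same screening strategy with the same outcome measure),
and :class:`SubgroupDistribution` (the socioeconomic quintile structure a
distributional analysis runs over: baseline quality-adjusted life
expectancy, health-opportunity-cost shares and population shares).

Study tables are read and written as CSV (one row per (study, outcome)
membership — a single publication can contribute to several synthesis
groups with different effect values) or as JSON mirroring the same field
names.  Floats are serialized with ``repr`` so a write/load round trip is
bit-exact.
"""
from __future__ import annotations

import csv
import json
import math
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "StrategyType",
    "OutcomeMeasure",
    "Dominance",
    "Direction",
    "Interval",
    "StudyRecord",
    "SynthesisGroup",
    "ConversionTable",
    "SubgroupDistribution",
    "DceaScenario",
    "DceaResult",
    "SchemaError",
    "RowParseError",
    "load_studies",
    "write_studies",
    "load_distribution",
    "write_distribution",
    "make_groups",
    "STUDY_CSV_COLUMNS",
]


class StrategyType(str, Enum):
    """Screening strategy family."""

    cascade = "cascade"
    universal = "universal"
    opportunistic = "opportunistic"
    combination = "combination"


class OutcomeMeasure(str, Enum):
    """Health outcome the incremental effect is denominated in."""

    QALY = "QALY"
    LYG = "LYG"
    adverse_events_averted = "adverse_events_averted"
    deaths_averted = "deaths_averted"


class Dominance(str, Enum):
    none = "none"
    dominant = "dominant"  # saves money and gains health: no finite ICER
    dominated = "dominated"  # costs money and loses health


class Direction(str, Enum):
    reduces_inequality = "reduces_inequality"
    increases_inequality = "increases_inequality"
    neutral = "neutral"


class SchemaError(ValueError):
    """A study table is missing a mandatory column."""


class RowParseError(ValueError):
    """A study-table cell could not be parsed; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class Interval(BaseModel):
    """Closed interval with ``low <= high``, in the units of the quantity it bounds."""

    model_config = ConfigDict(frozen=True)

    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "Interval":
        if not self.low <= self.high:
            raise ValueError(f"interval endpoints out of order: ({self.low}, {self.high})")
        return self

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


class StudyRecord(BaseModel):
    """One extracted economic evaluation, standardized to 2023 USD.

    ``wtp`` is the study's willingness-to-pay threshold per outcome unit
    after currency conversion; ``cohorts`` optionally holds per-cohort
    (delta_cost, delta_effect) pairs whose means must equal the record's
    headline values (multi-cohort studies are averaged before pooling).
    """

    model_config = ConfigDict(frozen=True)

    study_id: str
    strategy_type: StrategyType
    outcome_measure: OutcomeMeasure
    delta_cost: float
    delta_effect: float
    wtp: float = Field(gt=0)
    cost_interval: Optional[Interval] = None
    effect_interval: Optional[Interval] = None
    perspective: str = ""
    cohorts: Optional[tuple[tuple[float, float], ...]] = None
    # free-form provenance flags, e.g. {"wtp": "back_solved", "nhb": "printed"}
    meta: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _cohorts_average(self) -> "StudyRecord":
        if self.cohorts:
            mc = sum(c for c, _ in self.cohorts) / len(self.cohorts)
            me = sum(e for _, e in self.cohorts) / len(self.cohorts)
            if not (
                math.isclose(mc, self.delta_cost, rel_tol=1e-9, abs_tol=1e-6)
                and math.isclose(me, self.delta_effect, rel_tol=1e-9, abs_tol=1e-9)
            ):
                raise ValueError(
                    f"study {self.study_id}: cohort means ({mc}, {me}) do not match "
                    f"record values ({self.delta_cost}, {self.delta_effect})"
                )
        return self


class SynthesisGroup(BaseModel):
    """Records sharing one (strategy, outcome) cell, eligible for pooling."""

    model_config = ConfigDict(frozen=True)

    strategy_type: StrategyType
    outcome_measure: OutcomeMeasure
    records: tuple[StudyRecord, ...] = Field(min_length=1)

    @model_validator(mode="after")
    def _homogeneous(self) -> "SynthesisGroup":
        for r in self.records:
            if r.strategy_type != self.strategy_type or r.outcome_measure != self.outcome_measure:
                raise ValueError(
                    f"record {r.study_id} ({r.strategy_type.value}, {r.outcome_measure.value}) "
                    f"does not belong in group ({self.strategy_type.value}, "
                    f"{self.outcome_measure.value})"
                )
        return self

    @property
    def label(self) -> str:
        tag = {"cascade": "CS", "universal": "US", "opportunistic": "OS", "combination": "MIX"}
        return f"{tag[self.strategy_type.value]}({self.outcome_measure.value})"


class ConversionTable:
    """(currency code, price year) -> multiplier to the reference currency-year (2023 USD)."""

    def __init__(self, entries: dict[tuple[str, int], float]):
        for (cur, year), mult in entries.items():
            if not mult > 0:
                raise ValueError(f"non-positive multiplier {mult} for ({cur}, {year})")
        self.entries = {(cur.upper(), int(year)): float(m) for (cur, year), m in entries.items()}

    def multiplier(self, currency: str, price_year: int) -> float:
        key = (currency.upper(), int(price_year))
        if key not in self.entries:
            raise KeyError(f"no conversion entry for currency={key[0]}, price_year={key[1]}")
        return self.entries[key]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConversionTable":
        entries: dict[tuple[str, int], float] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"currency", "price_year", "multiplier_to_usd2023"}
            missing = required - set(reader.fieldnames or [])
            if missing:
                raise SchemaError(f"conversion table missing column(s): {sorted(missing)}")
            for row in reader:
                entries[(row["currency"], int(row["price_year"]))] = float(
                    row["multiplier_to_usd2023"]
                )
        return cls(entries)


class SubgroupDistribution(BaseModel):
    """Socioeconomic group structure for distributional analysis.

    Groups are ordered most- to least-deprived (IMD1..IMD5 by default).
    ``qale`` is baseline quality-adjusted life expectancy per person
    (years), ``opp_share`` the share of health opportunity costs borne by
    each group, ``pop_share`` the fraction of screened patients in each.
    """

    model_config = ConfigDict(frozen=True)

    labels: tuple[str, ...]
    qale: tuple[float, ...]
    opp_share: tuple[float, ...]
    pop_share: tuple[float, ...]

    @model_validator(mode="after")
    def _valid(self) -> "SubgroupDistribution":
        n = len(self.labels)
        if not (len(self.qale) == len(self.opp_share) == len(self.pop_share) == n):
            raise ValueError("labels, qale, opp_share and pop_share must have equal length")
        if n == 0:
            raise ValueError("distribution must have at least one group")
        if any(h <= 0 for h in self.qale):
            raise ValueError("all baseline QALE values must be positive")
        for name, vec in (("opp_share", self.opp_share), ("pop_share", self.pop_share)):
            if any(s < 0 for s in vec):
                raise ValueError(f"{name} entries must be nonnegative")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(vec)!r})")
        return self

    @property
    def n_groups(self) -> int:
        return len(self.labels)


class DceaScenario(BaseModel):
    """Inputs to one aggregate distributional cost-effectiveness run.

    Per-person incremental QALYs and costs, the opportunity-cost threshold
    K (USD per QALY), the number of patients screened, the subgroup
    structure and the inequality-aversion parameter epsilon.
    """

    model_config = ConfigDict(frozen=True)

    study_id: str = ""
    delta_qaly_pp: float
    delta_cost_pp: float
    wtp_threshold: float = Field(gt=0)
    n_total: float = Field(gt=0)
    distribution: SubgroupDistribution
    epsilon: float = Field(default=10.95, ge=0)
    meta: dict = Field(default_factory=dict)


class DceaResult(BaseModel):
    """Full output of the six-step distributional analysis."""

    model_config = ConfigDict(frozen=True)

    group_nhb: tuple[float, ...]
    total_nhb: float
    qale_pre: tuple[float, ...]
    qale_post: tuple[float, ...]
    atkinson_pre: float
    atkinson_post: float
    edeh_pre: float
    edeh_post: float
    delta_edeh: float
    equity_impact: float
    direction: Direction

    @model_validator(mode="after")
    def _conserved(self) -> "DceaResult":
        s = sum(self.group_nhb)
        if abs(s - self.total_nhb) > 1e-6 * max(1.0, abs(self.total_nhb)):
            raise ValueError(f"group NHB sum {s} != total NHB {self.total_nhb}")
        return self


# ---------------------------------------------------------------------------
# File IO

STUDY_CSV_COLUMNS = [
    "study_id",
    "strategy_type",
    "outcome_measure",
    "delta_cost_usd2023",
    "delta_effect",
    "cost_low",
    "cost_high",
    "effect_low",
    "effect_high",
    "wtp_usd2023",
    "perspective",
]
_MANDATORY = [
    "study_id",
    "strategy_type",
    "outcome_measure",
    "delta_cost_usd2023",
    "delta_effect",
    "wtp_usd2023",
]


def _record_from_mapping(row: dict, rownum: int) -> StudyRecord:
    def num(col: str, required: bool = True) -> Optional[float]:
        raw = row.get(col)
        if raw is None or raw == "":
            if required:
                raise RowParseError(rownum, f"missing value for '{col}'")
            return None
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise RowParseError(rownum, f"non-numeric value {raw!r} in column '{col}'") from None

    try:
        outcome = OutcomeMeasure(row["outcome_measure"])
    except ValueError:
        raise ValueError(
            f"row {rownum}: unknown outcome_measure {row['outcome_measure']!r} "
            f"(expected one of {[m.value for m in OutcomeMeasure]})"
        ) from None
    strategy = StrategyType(row["strategy_type"])

    cost_low, cost_high = num("cost_low", False), num("cost_high", False)
    eff_low, eff_high = num("effect_low", False), num("effect_high", False)
    return StudyRecord(
        study_id=str(row["study_id"]),
        strategy_type=strategy,
        outcome_measure=outcome,
        delta_cost=num("delta_cost_usd2023"),
        delta_effect=num("delta_effect"),
        wtp=num("wtp_usd2023"),
        cost_interval=Interval(low=cost_low, high=cost_high) if cost_low is not None else None,
        effect_interval=Interval(low=eff_low, high=eff_high) if eff_low is not None else None,
        perspective=row.get("perspective") or "",
    )


def load_studies(path: str | Path, format: Optional[str] = None) -> list[StudyRecord]:
    """Read study records from CSV or JSON, validating every row.

    ``format`` defaults to the file extension.  Row order is preserved.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        payload = json.loads(path.read_text())
        return [_record_from_mapping(row, i + 1) for i, row in enumerate(payload)]
    if fmt != "csv":
        raise ValueError(f"unsupported study-table format {fmt!r}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _MANDATORY if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"study table {path} missing mandatory column(s): {missing}")
        return [_record_from_mapping(row, i + 2) for i, row in enumerate(reader)]


def write_studies(records: Sequence[StudyRecord], path: str | Path) -> None:
    """Write records as CSV with round-trip-exact float serialization."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(STUDY_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.study_id,
                    r.strategy_type.value,
                    r.outcome_measure.value,
                    repr(r.delta_cost),
                    repr(r.delta_effect),
                    repr(r.cost_interval.low) if r.cost_interval else "",
                    repr(r.cost_interval.high) if r.cost_interval else "",
                    repr(r.effect_interval.low) if r.effect_interval else "",
                    repr(r.effect_interval.high) if r.effect_interval else "",
                    repr(r.wtp),
                    r.perspective,
                ]
            )


def load_distribution(path: str | Path) -> SubgroupDistribution:
    """Read a subgroup-distribution CSV: columns group, qale, opp_share, pop_share."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"group", "qale", "opp_share", "pop_share"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"distribution table missing column(s): {sorted(missing)}")
        labels, qale, opp, pop = [], [], [], []
        for row in reader:
            labels.append(row["group"])
            qale.append(float(row["qale"]))
            opp.append(float(row["opp_share"]))
            pop.append(float(row["pop_share"]))
    return SubgroupDistribution(
        labels=tuple(labels), qale=tuple(qale), opp_share=tuple(opp), pop_share=tuple(pop)
    )


def write_distribution(dist: SubgroupDistribution, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "qale", "opp_share", "pop_share"])
        for lab, h, d, p in zip(dist.labels, dist.qale, dist.opp_share, dist.pop_share):
            writer.writerow([lab, repr(h), repr(d), repr(p)])


def make_groups(records: Sequence[StudyRecord]) -> list[SynthesisGroup]:
    """Partition records into synthesis groups by (strategy, outcome).

    Group order is deterministic: strategies in enumeration order (cascade
    before universal), then outcome measures in enumeration order.  Within
    a group, input order is preserved.
    """
    buckets: dict[tuple[StrategyType, OutcomeMeasure], list[StudyRecord]] = {}
    for r in records:
        buckets.setdefault((r.strategy_type, r.outcome_measure), []).append(r)
    strat_order = {s: i for i, s in enumerate(StrategyType)}
    out_order = {m: i for i, m in enumerate(OutcomeMeasure)}
    keys = sorted(buckets, key=lambda k: (strat_order[k[0]], out_order[k[1]]))
    return [
        SynthesisGroup(strategy_type=s, outcome_measure=m, records=tuple(buckets[(s, m)]))
        for s, m in keys
    ]
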