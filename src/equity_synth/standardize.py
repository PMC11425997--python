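"""Cost standardization to the reference currency-year and default intervals.

Costs and thresholds extracted from source studies arrive in mixed
currencies and price years; everything downstream works in 2023 US
dollars.  Conversion multipliers (purchasing-power-parity based) are user
inputs, never fetched: the table maps (currency, price year) to a single
multiplicative factor.

Source studies that report no uncertainty around a cost or effect are
assigned a default interval of +/-50% of the reported value; a reported
confidence interval, when present, takes precedence.
"""
from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .core_types import ConversionTable, Interval

__all__ = ["MonetaryAmount", "convert_to_reference", "default_interval", "REFERENCE_LABEL"]

REFERENCE_LABEL = "2023 USD"


class MonetaryAmount(BaseModel):
    """A money value tagged with its currency and price year."""

    model_config = ConfigDict(frozen=True)

    value: float
    currency: str
    price_year: int = Field(ge=1990, le=2030)


def convert_to_reference(amount: MonetaryAmount, table: ConversionTable) -> float:
    """Convert ``amount`` to 2023 USD using the supplied multiplier table.

    Linear and sign-preserving: cost savings stay negative.  Raises
    ``KeyError`` naming the (currency, year) pair when no entry exists.
    """
    return amount.value * table.multiplier(amount.currency, amount.price_year)


def default_interval(value: float) -> Interval:
    """The +/-50% default uncertainty interval around a reported value.

    Endpoints are 0.5x and 1.5x the value, ordered so low <= high (a
    negative input swaps them); zero maps to the degenerate (0, 0).
    """
    a, b = 0.5 * value, 1.5 * value
    return Interval(low=min(a, b), high=max(a, b))
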