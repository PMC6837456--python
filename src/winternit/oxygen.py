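"""Oxygen demand of nitrification.

Oxidizing one mole of ammonium to nitrate consumes two moles of O2, a
mass ratio of 64 g O2 per 14 g N ≈ 4.57:1. Scaling a volumetric
nitrification rate by this ratio and an accumulation period estimates the
oxygen drawdown attributable to nitrification — e.g. over a 30-day month
or a ~150-day ice-cover season.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import DAYS_PER_MONTH, O2_TO_N_MASS_RATIO

__all__ = ["O2DemandResult", "o2_demand"]


@dataclass(frozen=True)
class O2DemandResult:
    """Oxygen demand (µg O2 L⁻¹) accumulated over ``period`` days."""

    demand: float
    period: float
    mass_ratio: float
    negative_rate: bool


def o2_demand(
    rate: float,
    period: float = DAYS_PER_MONTH,
    mass_ratio: float = O2_TO_N_MASS_RATIO,
) -> O2DemandResult:
    """Oxygen demand of a nitrification rate over an accumulation period.

    ``rate`` in µg N L⁻¹ d⁻¹, ``period`` in days. Negative rates yield
    negative demand, reported and flagged rather than clamped.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    if mass_ratio <= 0:
        raise ValueError("mass_ratio must be > 0")
    return O2DemandResult(
        demand=rate * mass_ratio * period,
        period=period,
        mass_ratio=mass_ratio,
        negative_rate=rate < 0,
    )
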