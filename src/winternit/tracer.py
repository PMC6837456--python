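"""15N-ammonium tracer rate estimation with detection-limit machinery.

A nitrification incubation amends lake water with ammonium chloride highly
enriched in 15N (by design ~10 % of the ambient pool at 98 atom %), so the
ammonium pool carries a known atom % 15N well above natural abundance.
Nitrifiers oxidize that pool to nitrate; after the incubation the nitrate
is reduced and trapped on a diffusion disk, together with an unlabeled
carrier nitrate spike (added when ambient nitrate is scarce) and a small
blank from the Devarda's-alloy reductant. The measured atom % 15N of the
trapped N, corrected for natural abundance and diluted carrier/blank mass,
gives the mass of newly nitrified N and hence a volumetric rate.

Detection limits propagate from the analytical replication of the atom %
measurement: the atom % MDL is the replicate SD times a one-sided
Student-t quantile, and the sample-specific rate LOQ converts that atom %
through the sample's trapped N mass, bottle volume and incubation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _sstats

from .config import (
    GLOBAL_RATE_LOQ,
    MDL_CONFIDENCE,
    NATURAL_ABUNDANCE_15N,
)

__all__ = [
    "TracerIncubation",
    "RecoveredPool",
    "RateEstimate",
    "label_atom_fraction",
    "excess_atom_percent",
    "nitrified_nitrogen_mass",
    "nitrification_rate",
    "atom_percent_mdl",
    "rate_loq",
    "censor_rate",
    "substitute_below_detection",
]


@dataclass(frozen=True)
class TracerIncubation:
    """Amended ammonium pool and incubation conditions for one bottle.

    Concentrations are µg N L⁻¹, enrichments atom % 15N, duration days,
    volume litres.
    """

    ambient_ammonium: float
    spike_ammonium: float
    spike_enrichment: float
    ambient_nitrate: float
    duration: float
    volume: float
    natural_abundance: float = NATURAL_ABUNDANCE_15N

    def __post_init__(self) -> None:
        for name in ("ambient_ammonium", "spike_ammonium", "ambient_nitrate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.natural_abundance < self.spike_enrichment <= 100:
            raise ValueError(
                "require 0 < natural_abundance < spike_enrichment <= 100"
            )
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")

    @property
    def label_atom_percent(self) -> float:
        """Atom % 15N of the amended ammonium pool."""
        return label_atom_fraction(
            self.ambient_ammonium,
            self.spike_ammonium,
            self.spike_enrichment,
            self.natural_abundance,
        )

    @property
    def label_excess(self) -> float:
        """Atom % excess of the amended pool over natural abundance."""
        return self.label_atom_percent - self.natural_abundance


@dataclass(frozen=True)
class RecoveredPool:
    """Post-recovery nitrate-derived N pool trapped on the diffusion disk.

    ``total_nitrogen_mass`` is everything on the disk (µg N): ambient +
    nitrified nitrate, the unlabeled carrier spike, and the Devarda's-alloy
    blank. Carrier and blank are at natural abundance, so all 15N excess is
    attributed to incubation-derived nitrate.
    """

    measured_atom_percent: float
    total_nitrogen_mass: float
    carrier_nitrate_mass: float = 0.0
    blank_nitrogen_mass: float = 0.0
    sd_atom_percent: float = 0.0
    replicate_count: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.measured_atom_percent <= 100:
            raise ValueError("measured_atom_percent must be in [0, 100]")
        if self.carrier_nitrate_mass < 0 or self.blank_nitrogen_mass < 0:
            raise ValueError("carrier and blank masses must be >= 0")
        if self.total_nitrogen_mass < self.carrier_nitrate_mass + self.blank_nitrogen_mass:
            raise ValueError(
                "total_nitrogen_mass must cover carrier + blank masses"
            )
        if self.sd_atom_percent < 0:
            raise ValueError("sd_atom_percent must be >= 0")


@dataclass(frozen=True)
class RateEstimate:
    """A nitrification rate with its sample-specific LOQ and censoring.

    ``rate`` may be negative (analytical noise below baseline is reported,
    never clamped). ``below_loq`` flags rate < sample LOQ; ``censored_rate``
    substitutes the global quantitation threshold when the rate falls under
    it.
    """

    rate: float
    loq: float
    censored_rate: float
    below_loq: bool
    censored: bool


def label_atom_fraction(
    ambient: float,
    spike: float,
    spike_enrichment: float,
    natural_abundance: float = NATURAL_ABUNDANCE_15N,
) -> float:
    """Atom % 15N of the amended ammonium pool by two-component mixing.

    Parameters are the ambient and spike concentrations (any common unit),
    the spike enrichment and the natural-abundance reference, both in
    atom %.
    """
    total = ambient + spike
    if total <= 0:
        raise ValueError("ambient + spike must be > 0")
    return (spike * spike_enrichment + ambient * natural_abundance) / total


def excess_atom_percent(measured: float, reference: float) -> float:
    """Atom % excess of a measurement over a reference.

    Negative excess is possible (measurement noise below baseline) and is
    returned as-is; downstream censoring, not clamping, handles it.
    """
    for value in (measured, reference):
        if not 0 <= value <= 100:
            raise ValueError("atom % values must be in [0, 100]")
    return measured - reference


def nitrified_nitrogen_mass(
    pool: RecoveredPool,
    reference: float,
    label_excess: float,
) -> float:
    """Mass of newly nitrified N (µg) on the disk.

    The 15N excess mass on the disk, (measured − reference)/100 × total
    mass, divided by the label excess fraction of the source ammonium pool.
    Carrier and blank are at natural abundance, so they dilute the measured
    atom % but contribute no excess mass — the correction cancels exactly.
    """
    if label_excess <= 0:
        raise ValueError("label_excess must be > 0 for a tracer incubation")
    excess_mass = excess_atom_percent(pool.measured_atom_percent, reference) / 100.0
    excess_mass *= pool.total_nitrogen_mass
    return excess_mass / (label_excess / 100.0)


def atom_percent_mdl(
    sd_atom_percent: float,
    replicate_count: int,
    confidence: float = MDL_CONFIDENCE,
) -> float:
    """Method detection limit in atom %: SD × one-sided Student-t quantile.

    Degrees of freedom are replicate_count − 1; the conventional MDL uses
    the one-sided 99 % quantile.
    """
    if replicate_count < 2:
        raise ValueError("replicate_count must be >= 2 (needs >= 1 df)")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if sd_atom_percent < 0:
        raise ValueError("sd_atom_percent must be >= 0")
    return sd_atom_percent * _sstats.t.ppf(confidence, replicate_count - 1)


def rate_loq(
    mdl: float,
    pool: RecoveredPool,
    incubation: TracerIncubation,
    mode: str = "literal",
) -> float:
    """Sample-specific minimum quantifiable rate (µg N L⁻¹ d⁻¹).

    ``literal`` converts the atom % MDL to a 15N mass on this sample's disk
    (mdl/100 × total N mass) and normalizes by bottle volume and incubation
    time. ``label_normalized`` additionally divides by the label excess
    fraction, making the LOQ dimensionally identical to the rate itself;
    it is always >= the literal value.
    """
    if mdl < 0:
        raise ValueError("mdl must be >= 0")
    mass = mdl / 100.0 * pool.total_nitrogen_mass
    if mode == "label_normalized":
        mass /= incubation.label_excess / 100.0
    elif mode != "literal":
        raise ValueError(f"unknown LOQ mode: {mode!r}")
    return mass / (incubation.volume * incubation.duration)


def censor_rate(
    rate: float, global_loq: float = GLOBAL_RATE_LOQ
) -> tuple[float, bool]:
    """Replace a rate below the global quantitation threshold by it.

    Returns ``(value, flagged)``; idempotent and order-preserving above the
    threshold.
    """
    if rate < global_loq:
        return global_loq, True
    return rate, False


def nitrification_rate(
    incubation: TracerIncubation,
    pool: RecoveredPool,
    loq_mode: str = "literal",
    confidence: float = MDL_CONFIDENCE,
    global_loq: float = GLOBAL_RATE_LOQ,
) -> RateEstimate:
    """Full rate estimate for one bottle, with LOQ and censoring flags.

    The rate is the nitrified N mass divided by bottle volume and
    incubation duration. The sample LOQ propagates the atom % MDL (from
    the pool's replicate SD) through the same mass/volume/time conversion.
    """
    mass = nitrified_nitrogen_mass(
        pool, incubation.natural_abundance, incubation.label_excess
    )
    rate = mass / (incubation.volume * incubation.duration)
    if pool.sd_atom_percent > 0:
        mdl = atom_percent_mdl(pool.sd_atom_percent, pool.replicate_count, confidence)
        loq = rate_loq(mdl, pool, incubation, mode=loq_mode)
    else:
        loq = 0.0
    censored, flagged = censor_rate(rate, global_loq)
    return RateEstimate(
        rate=rate,
        loq=loq,
        censored_rate=censored,
        below_loq=rate < loq,
        censored=flagged,
    )


def substitute_below_detection(
    value: float,
    flagged: bool,
    mdl: float,
    policy: str = "substitute_mdl",
) -> float | None:
    """Apply a below-detection policy to one concentration record.

    ``substitute_mdl`` returns the MDL for flagged values, ``exclude``
    drops them (returns None), ``keep`` passes the raw value through.
    Unflagged values are returned unchanged under every policy.
    """
    if mdl <= 0:
        raise ValueError("mdl must be > 0")
    if not flagged:
        return value
    if policy == "substitute_mdl":
        return mdl
    if policy == "exclude":
        return None
    if policy == "keep":
        return value
    raise ValueError(f"unknown below-detection policy: {policy!r}")
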