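"""Dissolved N2O and CH4 from headspace equilibration.

A bottle is overfilled with sample water, a known headspace of gas is
introduced, and the two phases are shaken to equilibrium. The dry mole
fraction of the analyte measured in the equilibrated headspace, together
with a temperature- and salinity-dependent solubility function, closes a
mole balance on the bottle and yields the concentration originally
dissolved in the water. Percent saturation compares an observed dissolved
concentration with the concentration in equilibrium with the atmosphere
at in-situ temperature and salinity.

Solubility follows the standard oceanographic ln-polynomial

    ln F = A1 + A2·(100/T) + A3·ln(T/100) + S·[B1 + B2·(T/100) + B3·(T/100)²]

with T in kelvin, S in g kg⁻¹ and F in mol L⁻¹ atm⁻¹. The N2O
coefficients are the moist-air solubility function of Weiss & Price
(1980); the CH4 coefficients are the Bunsen-coefficient fit of Wiesenburg
& Guinasso (1979) with the molar volume of an ideal gas at STP
(22.4136 L mol⁻¹) folded into A1 so both functions share units. For the
semi-saline prairie systems, salinity is the summed mass of the dominant
major ions per kg of solution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .config import R_L_ATM_PER_MOL_K

__all__ = [
    "SolubilityFunction",
    "N2O_SOLUBILITY",
    "CH4_SOLUBILITY",
    "SOLUBILITY_FUNCTIONS",
    "IonSuite",
    "GasEquilibration",
    "solubility",
    "ionic_salinity",
    "dissolved_from_headspace",
    "percent_saturation",
    "ExtrapolationWarning",
]


class ExtrapolationWarning(UserWarning):
    """Solubility evaluated outside its validated T/S range."""


@dataclass(frozen=True)
class SolubilityFunction:
    """Coefficients of the ln-polynomial solubility form (F mol L⁻¹ atm⁻¹)."""

    gas_id: str
    a1: float
    a2: float
    a3: float
    b1: float
    b2: float
    b3: float
    temperature_range: tuple[float, float] = (0.0, 30.0)  # °C, validated
    salinity_range: tuple[float, float] = (0.0, 40.0)  # g kg⁻¹, validated


# Weiss & Price (1980), F in mol l⁻¹ atm⁻¹, moist-air form.
N2O_SOLUBILITY = SolubilityFunction(
    gas_id="N2O",
    a1=-62.7062,
    a2=97.3066,
    a3=24.1406,
    b1=-0.058420,
    b2=0.033193,
    b3=-0.0051313,
)

# Wiesenburg & Guinasso (1979) Bunsen coefficient; A1 carries the
# -ln(22.4136) conversion from (L gas STP) L⁻¹ atm⁻¹ to mol L⁻¹ atm⁻¹.
_STP_MOLAR_VOLUME_L = 22.4136
CH4_SOLUBILITY = SolubilityFunction(
    gas_id="CH4",
    a1=-68.8862 - math.log(_STP_MOLAR_VOLUME_L),
    a2=101.4956,
    a3=28.7314,
    b1=-0.076146,
    b2=0.043970,
    b3=-0.0068672,
)

SOLUBILITY_FUNCTIONS: dict[str, SolubilityFunction] = {
    "N2O": N2O_SOLUBILITY,
    "CH4": CH4_SOLUBILITY,
}


@dataclass(frozen=True)
class IonSuite:
    """Major-ion concentrations (mg L⁻¹) for ionic-salinity estimation."""

    sulfate: float = 0.0
    calcium: float = 0.0
    magnesium: float = 0.0
    sodium: float = 0.0
    potassium: float = 0.0
    chloride: float = 0.0
    bicarbonate: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GasEquilibration:
    """One headspace-equilibration measurement.

    Mixing ratios are dry ppm: ``headspace_mixing_ratio`` after
    equilibration, ``initial_headspace_mixing_ratio`` of the gas used to
    create the headspace (0 for a gas-free headspace),
    ``atmospheric_mixing_ratio`` for the saturation reference.
    """

    gas_id: str
    headspace_mixing_ratio: float
    initial_headspace_mixing_ratio: float
    equilibration_temperature: float
    in_situ_temperature: float
    water_volume: float
    headspace_volume: float
    pressure: float = 1.0
    salinity: float = 0.0
    atmospheric_mixing_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.water_volume <= 0 or self.headspace_volume < 0:
            raise ValueError("volumes must be positive (headspace may be 0)")
        if self.pressure <= 0:
            raise ValueError("pressure must be > 0")
        for name in ("equilibration_temperature", "in_situ_temperature"):
            if getattr(self, name) <= -5:
                raise ValueError(f"{name} must exceed -5 °C")
        for name in (
            "headspace_mixing_ratio",
            "initial_headspace_mixing_ratio",
            "atmospheric_mixing_ratio",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def solubility(
    fn: SolubilityFunction, temperature: float, salinity: float = 0.0
) -> float:
    """Evaluate F(T, S) in mol L⁻¹ atm⁻¹.

    Warns (``ExtrapolationWarning``) when evaluated outside the validated
    temperature/salinity window but still returns the extrapolated value.
    """
    t_lo, t_hi = fn.temperature_range
    s_lo, s_hi = fn.salinity_range
    if not (t_lo <= temperature <= t_hi and s_lo <= salinity <= s_hi):
        warnings.warn(
            f"{fn.gas_id} solubility extrapolated at T={temperature} °C, "
            f"S={salinity} g/kg (validated T {t_lo}–{t_hi}, S {s_lo}–{s_hi})",
            ExtrapolationWarning,
            stacklevel=2,
        )
    t_k = temperature + 273.15
    ln_f = (
        fn.a1
        + fn.a2 * (100.0 / t_k)
        + fn.a3 * math.log(t_k / 100.0)
        + salinity * (fn.b1 + fn.b2 * (t_k / 100.0) + fn.b3 * (t_k / 100.0) ** 2)
    )
    return math.exp(ln_f)


def ionic_salinity(ions: IonSuite, density: float = 1.0) -> float:
    """Ionic salinity (g kg⁻¹) as summed major-ion mass per kg of solution.

    ``density`` is the solution density in kg L⁻¹ (dilute waters ≈ 1).
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    total_mg_per_l = (
        ions.sulfate
        + ions.calcium
        + ions.magnesium
        + ions.sodium
        + ions.potassium
        + ions.chloride
        + ions.bicarbonate
    )
    return total_mg_per_l / 1000.0 / density


def dissolved_from_headspace(
    eq: GasEquilibration, fn: SolubilityFunction | None = None
) -> float:
    """Original dissolved concentration (µmol L⁻¹) by closed-system balance.

    Moles originally in the water equal moles dissolved at equilibrium
    plus the net transfer into the headspace:

        n_orig = x·P·F·V_w + (x − x0)·P·V_h / (R·T)

    with x, x0 the equilibrated and initial headspace dry mole fractions.
    With x in ppm and F in mol L⁻¹ atm⁻¹ the dissolved term is directly
    µmol; the gas term scales the same way. A negative balance (more gas
    removed than the water could hold) signals inconsistent inputs and is
    returned with a warning.
    """
    if fn is None:
        fn = SOLUBILITY_FUNCTIONS[eq.gas_id]
    f = solubility(fn, eq.equilibration_temperature, eq.salinity)
    t_k = eq.equilibration_temperature + 273.15
    x = eq.headspace_mixing_ratio
    x0 = eq.initial_headspace_mixing_ratio
    dissolved_umol = x * eq.pressure * f * eq.water_volume
    headspace_umol = (x - x0) * eq.pressure * eq.headspace_volume / (
        R_L_ATM_PER_MOL_K * t_k
    )
    concentration = (dissolved_umol + headspace_umol) / eq.water_volume
    if concentration < 0:
        warnings.warn(
            f"negative dissolved {eq.gas_id} balance ({concentration:.3g} "
            "µmol/L): inputs are inconsistent",
            UserWarning,
            stacklevel=2,
        )
    return concentration


def percent_saturation(
    observed: float,
    temperature: float,
    salinity: float,
    atmospheric_mixing_ratio: float,
    pressure: float = 1.0,
    fn: SolubilityFunction | None = None,
    gas_id: str | None = None,
) -> float:
    """Observed dissolved concentration as % of atmospheric equilibrium.

    ``observed`` in µmol L⁻¹; the equilibrium concentration is
    x_atm·P·F(T, S) in the same units (x_atm in ppm).
    """
    if fn is None:
        if gas_id is None:
            raise ValueError("provide a SolubilityFunction or gas_id")
        fn = SOLUBILITY_FUNCTIONS[gas_id]
    equilibrium = atmospheric_mixing_ratio * pressure * solubility(
        fn, temperature, salinity
    )
    if equilibrium <= 0:
        raise ValueError("equilibrium concentration is zero; cannot normalize")
    return 100.0 * observed / equilibrium
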