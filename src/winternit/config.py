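"""Shared constants and YAML-backed configuration.

All nitrogen masses are carried in µg N, atom fractions as atom percent
(0–100, not 0–1), concentrations in µg N L⁻¹, rates in µg N L⁻¹ d⁻¹,
gas concentrations in µmol L⁻¹ and mixing ratios in ppm (µmol mol⁻¹ dry
air). Unit conversions live next to the quantities they convert; nothing
downstream re-scales silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Atom % 15N of atmospheric N2, the natural-abundance reference.
NATURAL_ABUNDANCE_15N: float = 0.3663

#: Highest sample-specific rate LOQ across the survey; rates below this are
#: replaced by it before cross-lake statistics (µg N L⁻¹ d⁻¹).
GLOBAL_RATE_LOQ: float = 0.11

#: Method detection limits for ambient nutrient concentrations (µg N L⁻¹).
AMMONIUM_MDL: float = 86.0
NITRATE_MDL: float = 57.0

#: One-sided confidence level of the Student-t multiplier in the atom % MDL.
MDL_CONFIDENCE: float = 0.99

#: Mass of O2 consumed per mass of N nitrified (g O2 / g N); 2 mol O2 per
#: mol N gives 64/14.007 = 4.57.
O2_TO_N_MASS_RATIO: float = 4.57

#: Period conventions for oxygen-demand scaling (days).
DAYS_PER_MONTH: float = 30.0
ICE_SEASON_DAYS: float = 150.0

#: Default dry-air mixing ratios used as the saturation reference (ppm),
#: representative of the mid-2010s northern-hemisphere atmosphere.
N2O_ATMOSPHERIC_PPM: float = 0.330
CH4_ATMOSPHERIC_PPM: float = 1.9

#: Gas constant, L atm mol⁻¹ K⁻¹.
R_L_ATM_PER_MOL_K: float = 0.082057366

#: Default spike design of the tracer incubations.
SPIKE_FRACTION: float = 0.10
SPIKE_ENRICHMENT: float = 98.0
INCUBATION_DURATION_D: float = 2.5  # 60 h

#: Permutation count for permutation regressions.
DEFAULT_N_PERM: int = 5000


@dataclass
class Settings:
    """Runtime configuration, overridable from a YAML file.

    Every field defaults to the module-level constant of the same meaning,
    so a partial YAML file only overrides what it names.
    """

    natural_abundance: float = NATURAL_ABUNDANCE_15N
    global_rate_loq: float = GLOBAL_RATE_LOQ
    ammonium_mdl: float = AMMONIUM_MDL
    nitrate_mdl: float = NITRATE_MDL
    mdl_confidence: float = MDL_CONFIDENCE
    o2_mass_ratio: float = O2_TO_N_MASS_RATIO
    n2o_atmospheric_ppm: float = N2O_ATMOSPHERIC_PPM
    ch4_atmospheric_ppm: float = CH4_ATMOSPHERIC_PPM
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def load_settings(path: str | Path | None = None) -> Settings:
    """Load :class:`Settings` from YAML, keeping defaults for absent keys.

    Unknown keys are preserved under ``extras`` rather than rejected, so a
    single config file can also carry scenario parameters for the
    simulators.
    """
    settings = Settings()
    if path is None:
        return settings
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = set(settings.__dataclass_fields__) - {"extras"}
    for key, value in raw.items():
        if key in known:
            setattr(settings, key, value)
        else:
            settings.extras[key] = value
    return settings
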