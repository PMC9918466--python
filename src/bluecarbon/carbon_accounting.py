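"""Carbon-pool arithmetic: biomass partitioning, carbon conversion, sediment
stock integration to 1 m, ecosystem totals, rates, and CO2-eq conversion.

Unit bookkeeping for the sediment stock: a layer of thickness ``t`` cm with
organic carbon content SOC (%) and bulk density BD (g cm^-3) holds
``SOC/100 * BD`` g C per cm^3, i.e. ``SOC/100 * BD * t`` g C per cm^2 of
surface. One hectare is 1e8 cm^2 and one Mg is 1e6 g, so per hectare the layer
holds ``SOC/100 * BD * t * 1e8 / 1e6 = SOC/100 * BD * t * 100`` Mg C ha^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_io import SedimentProfile

#: molar-mass ratio CO2 : C, exact by definition
CO2_PER_C = 44.0 / 12.0

#: sediment stocks are integrated over the top metre
SEDIMENT_DEPTH_CM = 100.0
#: profiles measuring only surface sediment (< 20 cm) are excluded
MIN_PROFILE_DEPTH_CM = 20.0


class ShallowProfileError(ValueError):
    """Profile only covers surface sediment (< 20 cm) and is excluded."""


@dataclass(frozen=True)
class ConversionFactors:
    """Biomass-to-carbon fractions and the CO2:C molar ratio.

    Defaults are the community-standard conversion fractions for mangrove
    aboveground (0.47) and belowground (0.39) biomass; study-specific carbon
    contents override them where reported.
    """

    above_c_frac: float = 0.47
    below_c_frac: float = 0.39
    co2_per_c: float = CO2_PER_C

    def __post_init__(self):
        for name in ("above_c_frac", "below_c_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


DEFAULT_FACTORS = ConversionFactors()


def partition_total_biomass(total_biomass: float, shoot_root_ratio: float) -> tuple[float, float]:
    """Split total biomass (Mg ha^-1) into above/belowground by shoot:root ratio.

    above = total * r/(r+1), below = total * 1/(r+1); the two parts sum back
    to the total exactly.
    """
    if total_biomass < 0:
        raise ValueError(f"total biomass must be >= 0, got {total_biomass}")
    if shoot_root_ratio <= 0:
        raise ValueError(f"shoot/root ratio must be > 0, got {shoot_root_ratio}")
    above = total_biomass * shoot_root_ratio / (shoot_root_ratio + 1.0)
    return above, total_biomass - above


def biomass_to_carbon(
    biomass: float,
    pool: str,
    factors: ConversionFactors = DEFAULT_FACTORS,
    *,
    fraction: float | None = None,
) -> float:
    """Convert biomass (Mg ha^-1) to carbon density (Mg C ha^-1).

    ``pool`` is "above" or "below"; an explicit study-specific ``fraction``
    overrides the default conversion.
    """
    if biomass < 0:
        raise ValueError(f"biomass must be >= 0, got {biomass}")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError(f"carbon fraction must be in (0, 1], got {fraction}")
        return biomass * fraction
    if pool == "above":
        return biomass * factors.above_c_frac
    if pool == "below":
        return biomass * factors.below_c_frac
    raise ValueError(f"pool must be 'above' or 'below', got {pool!r}")


def sediment_stock_top_meter(profile: SedimentProfile) -> float:
    """Integrate a sediment profile to 1 m depth, in Mg C ha^-1.

    Layers below 100 cm are truncated (the straddling layer pro-rata). If the
    deepest measured layer ends above 100 cm, its volumetric carbon density is
    extended down to 100 cm — the organic layer is assumed to continue at the
    deepest measured density. Profiles shallower than 20 cm are rejected as
    surface-only measurements.
    """
    bottom = profile.bottom_cm
    if bottom < MIN_PROFILE_DEPTH_CM:
        raise ShallowProfileError(
            f"profile reaches only {bottom} cm; surface-only profiles (< "
            f"{MIN_PROFILE_DEPTH_CM:.0f} cm) are excluded"
        )
    stock = 0.0
    for layer in profile.layers:
        top = layer.top_cm
        bot = min(layer.bottom_cm, SEDIMENT_DEPTH_CM)
        if bot <= top:
            break
        stock += layer.soc_pct / 100.0 * layer.bd_g_cm3 * (bot - top) * 100.0
    if bottom < SEDIMENT_DEPTH_CM:
        deepest = profile.layers[-1]
        stock += (
            deepest.soc_pct / 100.0 * deepest.bd_g_cm3
            * (SEDIMENT_DEPTH_CM - bottom) * 100.0
        )
    return stock


def total_ecosystem_carbon(agc: float, bgc: float, scs: float) -> float:
    """TECS = AGC + BGC + SCS (Mg C ha^-1); no imputation of missing pools."""
    pools = {"agc": agc, "bgc": bgc, "scs": scs}
    for name, v in pools.items():
        if v is None:
            raise ValueError(f"{name} missing; all three pools are required")
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return agc + bgc + scs


def annual_rate(density_increment: float, age: float) -> float:
    """Mean annual accumulation rate: increment (Mg C ha^-1) / age (yr)."""
    if age <= 0:
        raise ValueError(f"age must be > 0, got {age}")
    return density_increment / age


def c_to_co2e(mass_c: float, *, allow_negative: bool = False) -> float:
    """Convert carbon mass to CO2 equivalents: mass * 44/12.

    Negative masses (losses) must be explicitly allowed.
    """
    if mass_c < 0 and not allow_negative:
        raise ValueError(f"carbon mass must be >= 0 (got {mass_c}); pass allow_negative=True for losses")
    return mass_c * CO2_PER_C
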