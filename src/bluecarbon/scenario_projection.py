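"""Country-resolved 40-year CO2-eq sequestration projection.

The feasible (restorable) area of a country is its 1996-2016 mangrove loss
minus the parts lost to coastal erosion and settlement, where restoration is
biophysically impossible. The feasible area is restored in equal annual
cohorts over a rollout of 1, 5, 10, or country-varying (5/10/20) years within
a fixed 40-year horizon; a cohort planted in rollout-year k accumulates
carbon for 40 - k + 1 years. Its sequestration is the summed per-pool carbon
density increments since the year-0 baseline, evaluated at the cohort's
fixation time, converted to CO2 equivalents with the molar ratio 44/12 and
scaled by area. Results are reported in Tg CO2-eq (1 Tg = 1e6 Mg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Optional, Protocol, Sequence
import warnings

import numpy as np

from .carbon_accounting import CO2_PER_C
from .data_io import CountryAreaRecord
from .growth_models import PredictionBand

HORIZON_YEARS = 40

#: loss drivers with no restoration possibility
INFEASIBLE_DRIVERS = ("erosion", "settlement")

MG_PER_TG = 1e6

SEQ_POOLS = ("agc", "bgc", "scs")


class CarbonCurve(Protocol):
    """Anything exposing a density increment since age 0 (Mg C ha^-1)."""

    def increment(self, age: float) -> float: ...


class Scenario(str, Enum):
    one_year = "one_year"
    five_year_averaged = "five_year_averaged"
    ten_year_averaged = "ten_year_averaged"
    varying_rates = "varying_rates"


_FIXED_ROLLOUT = {
    Scenario.one_year: 1,
    Scenario.five_year_averaged: 5,
    Scenario.ten_year_averaged: 10,
}

VARYING_ALLOWED_YEARS = (5, 10, 20)


@dataclass(frozen=True)
class ScenarioSpec:
    """A restoration rollout schedule over the fixed 40-year horizon."""

    name: Scenario
    horizon_years: int = HORIZON_YEARS
    country_duration: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.horizon_years != HORIZON_YEARS:
            raise ValueError(f"horizon is fixed at {HORIZON_YEARS} years")
        if self.name is Scenario.varying_rates:
            bad = {c: d for c, d in self.country_duration.items()
                   if d not in VARYING_ALLOWED_YEARS}
            if bad:
                raise ValueError(
                    f"varying-rates rollout years must be in {VARYING_ALLOWED_YEARS}: {bad}"
                )


def feasible_area(record: CountryAreaRecord) -> float:
    """Restorable area (ha): total loss minus erosion and settlement losses."""
    excluded = sum(record.loss_ha_by_driver.get(d, 0.0) for d in INFEASIBLE_DRIVERS)
    return record.total_loss_ha - excluded


def fill_unknown_drivers(
    records: Sequence[CountryAreaRecord],
    zone_means: Mapping[str, Mapping[str, float]],
) -> list[CountryAreaRecord]:
    """Redistribute each record's unknown-driver mass by its zone's shares.

    ``zone_means`` maps geographic zone -> driver share (summing to 1 over the
    known drivers). Totals are conserved exactly.
    """
    for zone, shares in zone_means.items():
        s = sum(shares.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"zone {zone!r} driver shares sum to {s}, expected 1")
    out = []
    for rec in records:
        unknown = rec.loss_ha_by_driver.get("unknown", 0.0)
        if unknown == 0.0:
            out.append(rec)
            continue
        if rec.zone not in zone_means:
            raise KeyError(f"no driver shares for zone {rec.zone!r} (country {rec.country})")
        new_loss = {d: v for d, v in rec.loss_ha_by_driver.items() if d != "unknown"}
        for d, share in zone_means[rec.zone].items():
            new_loss[d] = new_loss.get(d, 0.0) + unknown * share
        new_loss["unknown"] = 0.0
        out.append(rec.model_copy(update={"loss_ha_by_driver": new_loss}))
    return out


def cohort_schedule(
    scenario: ScenarioSpec, country: Optional[str] = None
) -> list[tuple[int, float]]:
    """(fixation_years, area_fraction) per annual cohort of the rollout.

    An R-year rollout plants 1/R of the area per year; the cohort of
    rollout-year k fixes carbon for 40 - k + 1 years, so fixation years run
    from 40 - R + 1 up to 40.
    """
    if scenario.name is Scenario.varying_rates:
        if country is None or country not in scenario.country_duration:
            raise KeyError(
                f"varying-rates scenario needs a rollout duration for country {country!r}"
            )
        rollout = scenario.country_duration[country]
    else:
        rollout = _FIXED_ROLLOUT[scenario.name]
    frac = 1.0 / rollout
    start = scenario.horizon_years - rollout + 1
    return [(i, frac) for i in range(start, scenario.horizon_years + 1)]


@dataclass
class SequestrationResult:
    """CO2-eq sequestration potential for one scope x scenario x pathway."""

    scope: str  # "country" or "global"
    country: str
    scenario: str
    pathway: str
    area_ha: float
    per_pool: dict[str, float]  # Tg CO2-eq
    total_tg: float
    ci_lo_tg: Optional[float] = None
    ci_hi_tg: Optional[float] = None


def _increment_fn(band: PredictionBand, which: str) -> Callable[[float], float]:
    curve = band.curve(which)
    at0 = curve(0.0)
    return lambda age: float(curve(age) - at0)


def sequestration_potential(
    fits: Mapping[str, CarbonCurve],
    areas: Sequence[CountryAreaRecord],
    scenario: ScenarioSpec,
    pathway: str,
    *,
    bands: Optional[Mapping[str, PredictionBand]] = None,
    floor_negative: bool = False,
) -> list[SequestrationResult]:
    """Per-country and global 40-year sequestration potential, Tg CO2-eq.

    ``fits`` maps each pool in (agc, bgc, scs) to its fitted accumulation
    curve for the pathway. For each country,
    Seq = sum over cohorts of fraction x feasible_area x sum over pools of
    increment(i) x 44/12. Optional ``bands`` propagate uncertainty by
    evaluating the same sum on each pool's 2.5th / 97.5th percentile curves
    and summing across pools. Negative point increments warn, and are floored
    at 0 only when ``floor_negative`` is set (confidence bounds keep them).
    """
    missing = [p for p in SEQ_POOLS if p not in fits]
    if missing:
        raise ValueError(f"missing pool fits: {missing}")

    results: list[SequestrationResult] = []
    tot_area = 0.0
    tot_pool = dict.fromkeys(SEQ_POOLS, 0.0)
    tot_lo = 0.0 if bands else None
    tot_hi = 0.0 if bands else None

    for rec in areas:
        area = feasible_area(rec)
        schedule = cohort_schedule(scenario, country=rec.country)
        per_pool: dict[str, float] = {}
        for pool in SEQ_POOLS:
            inc_total = 0.0
            for years, frac in schedule:
                inc = fits[pool].increment(years)
                if inc < 0:
                    warnings.warn(
                        f"negative {pool} increment {inc:.2f} Mg C ha^-1 at "
                        f"{years} yr for {rec.country}",
                        stacklevel=2,
                    )
                    if floor_negative:
                        inc = 0.0
                inc_total += frac * inc
            per_pool[pool] = area * inc_total * CO2_PER_C / MG_PER_TG
        lo = hi = None
        if bands is not None:
            lo = hi = 0.0
            for pool in SEQ_POOLS:
                lo_f = _increment_fn(bands[pool], "lo2p5")
                hi_f = _increment_fn(bands[pool], "hi97p5")
                lo += area * sum(f * lo_f(i) for i, f in schedule) * CO2_PER_C / MG_PER_TG
                hi += area * sum(f * hi_f(i) for i, f in schedule) * CO2_PER_C / MG_PER_TG
        total = sum(per_pool.values())
        results.append(SequestrationResult(
            scope="country", country=rec.country, scenario=scenario.name.value,
            pathway=pathway, area_ha=area, per_pool=per_pool, total_tg=total,
            ci_lo_tg=lo, ci_hi_tg=hi,
        ))
        tot_area += area
        for pool in SEQ_POOLS:
            tot_pool[pool] += per_pool[pool]
        if bands is not None:
            tot_lo += lo
            tot_hi += hi

    results.append(SequestrationResult(
        scope="global", country="", scenario=scenario.name.value, pathway=pathway,
        area_ha=tot_area, per_pool=tot_pool, total_tg=sum(tot_pool.values()),
        ci_lo_tg=tot_lo, ci_hi_tg=tot_hi,
    ))
    return results


def global_result(results: Sequence[SequestrationResult]) -> SequestrationResult:
    for r in results:
        if r.scope == "global":
            return r
    raise ValueError("no global-scope result present")


def pathway_gap(
    results_reforestation: Sequence[SequestrationResult],
    results_afforestation: Sequence[SequestrationResult],
) -> float:
    """Global reforestation minus afforestation total, Tg CO2-eq.

    Both runs must share the scenario and area table.
    """
    refo = global_result(results_reforestation)
    affo = global_result(results_afforestation)
    if refo.scenario != affo.scenario:
        raise ValueError(f"scenario mismatch: {refo.scenario} vs {affo.scenario}")
    if abs(refo.area_ha - affo.area_ha) > 1e-6:
        raise ValueError("pathway runs use different feasible areas")
    return refo.total_tg - affo.total_tg
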