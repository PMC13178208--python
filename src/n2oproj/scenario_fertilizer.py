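"""Scenario fertilizer construction.

Seven policy x climate combinations (INMS1-7).  Each country follows an
NUE trajectory set by the policy ambition; fertilizer totals are crop N
demand divided by NUE; gridded rates are the 2010 baseline scaled by the
country total so the spatial pattern is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FertilizerBaseline, GridDomain
from .errors import InvalidArgumentError, UndefinedScalingError
from .regions import REGION_DEMAND_GROWTH, REGION_NUE, is_oecd

AMBITIONS = ("BAU", "low", "moderate", "high")

#: scenario id -> (ambition, climate pathway, crop-N demand multiplier at 2050)
INMS_TABLE: dict[str, tuple[str, str, float]] = {
    "INMS1": ("BAU", "SSP5-8.5", 1.00),
    "INMS2": ("low", "SSP2-4.5", 1.00),
    "INMS3": ("moderate", "SSP2-4.5", 1.00),
    "INMS4": ("high", "SSP2-4.5", 1.00),
    "INMS5": ("high", "SSP2-4.5", 0.90),   # best-case: dietary shift
    "INMS6": ("high", "SSP2-4.5", 0.80),   # best-case plus: + food-waste cuts
    "INMS7": ("high", "SSP1-2.6", 0.85),   # bioenergy
}

SCENARIO_IDS = tuple(INMS_TABLE)

BASE_YEAR = 2010

#: Fraction of the 2010->target NUE gap closed by 2050 under low ambition.
LOW_AMBITION_GAP_CLOSURE = 0.5


@dataclass(frozen=True)
class CountryPolicy:
    """Per-country NUE trajectory parameters."""

    nue_2010: float
    nue_target: float
    target_year: int | None = None      # None: target never scheduled
    demand_growth_rate: float = 0.01    # yr^-1

    def __post_init__(self) -> None:
        for v in (self.nue_2010, self.nue_target):
            if not (0.0 < v <= 1.0):
                raise InvalidArgumentError("NUE values must lie in (0, 1]")
        if self.target_year is not None and self.target_year < BASE_YEAR:
            raise InvalidArgumentError("target_year before 2010")


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    ambition: str
    climate_pathway: str
    countries: dict[str, CountryPolicy] = field(default_factory=dict)
    demand_multiplier_2050: float = 1.0

    def __post_init__(self) -> None:
        if self.id in INMS_TABLE:
            amb, path, _ = INMS_TABLE[self.id]
            if (amb, path) != (self.ambition, self.climate_pathway):
                raise InvalidArgumentError(
                    f"{self.id} must pair ambition {amb!r} with pathway {path!r}")
        if self.ambition not in AMBITIONS:
            raise InvalidArgumentError(f"unknown ambition {self.ambition!r}")


def default_scenario(scenario_id: str, domain: GridDomain) -> ScenarioSpec:
    """ScenarioSpec with region-derived default country policies.

    High ambition reaches the NUE target by 2030 in OECD regions and 2040
    elsewhere; moderate ambition by 2050 everywhere; low/BAU never.
    """
    if scenario_id not in INMS_TABLE:
        raise InvalidArgumentError(f"unknown scenario {scenario_id!r}")
    ambition, pathway, dmult = INMS_TABLE[scenario_id]
    region_of = domain.region_of_country()
    countries = {}
    for c in domain.countries:
        region = region_of[str(c)]
        nue0, nuet = REGION_NUE[region]
        if ambition == "high":
            target_year = 2030 if is_oecd(region) else 2040
        elif ambition == "moderate":
            target_year = 2050
        else:
            target_year = None
        countries[str(c)] = CountryPolicy(
            nue_2010=nue0, nue_target=nuet, target_year=target_year,
            demand_growth_rate=REGION_DEMAND_GROWTH[region])
    return ScenarioSpec(id=scenario_id, ambition=ambition,
                        climate_pathway=pathway, countries=countries,
                        demand_multiplier_2050=dmult)


# ---------------------------------------------------------------------------
# trajectories

def build_nue_trajectory(country_spec: CountryPolicy, policy: str,
                         years) -> np.ndarray:
    """Yearly NUE path under a policy ambition.

    BAU holds NUE at the 2010 value.  Low ambition drifts linearly toward
    the target but closes only half the gap by 2050.  Moderate/high reach
    the target linearly at ``target_year`` and stay flat afterwards.
    """
    years = np.asarray(years, dtype=int)
    if years.size == 0 or years[0] < BASE_YEAR:
        raise InvalidArgumentError("years must start at or after 2010")
    if policy not in AMBITIONS:
        raise InvalidArgumentError(f"unknown policy {policy!r}")
    n0, nt = country_spec.nue_2010, country_spec.nue_target
    if policy == "BAU" or n0 == nt:
        return np.full(years.size, n0)
    if policy == "low":
        slope = LOW_AMBITION_GAP_CLOSURE * (nt - n0) / (2050 - BASE_YEAR)
        path = n0 + slope * (years - BASE_YEAR)
        # drift never overshoots the target
        path = np.clip(path, min(n0, nt), max(n0, nt))
    else:
        ty = country_spec.target_year
        if ty is None:
            raise InvalidArgumentError(f"policy {policy!r} requires a target_year")
        if ty < BASE_YEAR:
            raise InvalidArgumentError("target_year before 2010")
        if ty == BASE_YEAR:
            path = np.full(years.size, nt)
        else:
            frac = np.clip((years - BASE_YEAR) / (ty - BASE_YEAR), 0.0, 1.0)
            path = n0 + (nt - n0) * frac
    return np.clip(path, 1e-9, 1.0)


def demand_path(demand_2010: float, growth_rate: float, years,
                multiplier_2050: float = 1.0) -> np.ndarray:
    """Exogenous crop-N demand: compound growth times a linear multiplier
    ramp reaching ``multiplier_2050`` at 2050."""
    years = np.asarray(years, dtype=int)
    ramp = 1.0 + (multiplier_2050 - 1.0) * np.clip(
        (years - BASE_YEAR) / (2050 - BASE_YEAR), 0.0, 1.0)
    return demand_2010 * (1.0 + growth_rate) ** (years - BASE_YEAR) * ramp


def fertilizer_from_nue(demand_path: np.ndarray, nue_path: np.ndarray) -> np.ndarray:
    """Country fertilizer totals F(t) = demand(t) / NUE(t)."""
    demand_path = np.asarray(demand_path, dtype=float)
    nue_path = np.asarray(nue_path, dtype=float)
    if demand_path.shape != nue_path.shape:
        raise InvalidArgumentError("demand and NUE paths differ in length")
    if np.any(nue_path <= 0):
        raise InvalidArgumentError("NUE must be positive")
    return demand_path / nue_path


# ---------------------------------------------------------------------------
# gridded scaling

@dataclass(frozen=True)
class FertilizerScenarioField:
    """Gridded scenario fertilizer: rates (n_years, n_cells) plus the
    country trajectory table it conserves."""

    scenario_id: str
    years: np.ndarray
    rates: np.ndarray                   # kg N ha^-1 yr^-1
    country_totals: pd.DataFrame        # columns: country, year, fertilizer_tg, nue

    def rates_at(self, year: int) -> np.ndarray:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise InvalidArgumentError(f"year {year} not in scenario field")
        return self.rates[int(idx[0])]


def baseline_country_totals(baseline: FertilizerBaseline,
                            domain: GridDomain) -> pd.Series:
    """Baseline fertilizer N per country, Tg N yr^-1."""
    mass_tg = baseline.n_rate_2010 * domain.fertilized_area_ha * 1e-9
    return pd.Series(mass_tg).groupby(domain.country_id).sum()


def scale_gridded_fertilizer(baseline: FertilizerBaseline, domain: GridDomain,
                             country_totals: pd.DataFrame,
                             scenario_id: str = "custom") -> FertilizerScenarioField:
    """Scale baseline rates so each country's total follows its trajectory.

    rate_cell(t) = rate_cell(2010) * F_country(t) / F_country(2010); cells
    with zero baseline stay zero, and the baseline spatial pattern within a
    country is preserved for every year.
    """
    required = {"country", "year", "fertilizer_tg"}
    if not required.issubset(country_totals.columns):
        raise InvalidArgumentError(f"country_totals needs columns {sorted(required)}")
    base_totals = baseline_country_totals(baseline, domain)
    years = np.sort(country_totals["year"].unique()).astype(int)
    piv = country_totals.pivot_table(index="year", columns="country",
                                     values="fertilizer_tg", aggfunc="first")
    rates = np.zeros((years.size, domain.n_cells))
    for country, traj in piv.items():
        mask = domain.country_id == country
        base = float(base_totals.get(country, 0.0))
        if base <= 0:
            if np.any(traj.to_numpy() > 0):
                raise UndefinedScalingError(
                    f"country {country!r} has a trajectory but no baseline fertilizer")
            continue
        factors = traj.reindex(years).to_numpy() / base
        rates[:, mask] = factors[:, None] * baseline.n_rate_2010[mask][None, :]
    if np.any(rates < 0):
        raise InvalidArgumentError("negative scenario fertilizer rate")
    return FertilizerScenarioField(scenario_id=scenario_id, years=years,
                                   rates=rates, country_totals=country_totals)


def build_scenario_field(scenario: ScenarioSpec, domain: GridDomain,
                         baseline: FertilizerBaseline, years
                         ) -> FertilizerScenarioField:
    """End-to-end scenario fertilizer: NUE paths -> country totals -> grid.

    Country 2010 demand is implied by the baseline total and 2010 NUE, so
    F(2010) equals the baseline total exactly and scaling is anchored.
    """
    years = np.asarray(years, dtype=int)
    base_totals = baseline_country_totals(baseline, domain)
    rows = []
    for country, policy in scenario.countries.items():
        f0 = float(base_totals.get(country, 0.0))
        nue = build_nue_trajectory(policy, scenario.ambition, years)
        d0 = f0 * policy.nue_2010
        demand = demand_path(d0, policy.demand_growth_rate, years,
                             scenario.demand_multiplier_2050)
        totals = fertilizer_from_nue(demand, nue)
        rows.append(pd.DataFrame({
            "scenario": scenario.id, "country": country, "year": years,
            "fertilizer_tg": totals, "nue": nue,
        }))
    table = pd.concat(rows, ignore_index=True)
    return scale_gridded_fertilizer(baseline, domain, table, scenario.id)
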