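"""Scenario projection, ensemble statistics and reduction-goal timelines.

Runs a scenario's member ensemble through the EF emulator, summarizes the
member spread (median and 25th-75th percentile band), and derives the
headline quantities: relative change vs 2010, first goal-attainment years
on annual and cumulative bases, regional aggregates, mitigation potential
in N and CO2-equivalent terms, and the static-vs-dynamic gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate_ensemble import feature_table
from .datatypes import GridDomain, SoilProperties
from .ef_engine import EFEmulator, compute_emissions, predict_ef, static_emissions
from .errors import (
    ConfigError,
    DomainMismatchError,
    InvalidArgumentError,
    UndefinedBaselineError,
)
from .scenario_fertilizer import FertilizerScenarioField, ScenarioSpec

BASE_YEAR = 2010
HORIZON_YEAR = 2050


@dataclass(frozen=True)
class ReductionGoal:
    """Fractional reduction goal relative to 2010, on an annual or
    cumulative basis."""

    goal_fraction: float
    basis: str = "annual"            # "annual" | "cumulative"
    baseline_year: int = BASE_YEAR

    def __post_init__(self) -> None:
        if not (0.0 < self.goal_fraction < 1.0):
            raise InvalidArgumentError("goal_fraction must lie in (0, 1)")
        if self.basis not in ("annual", "cumulative"):
            raise InvalidArgumentError(f"unknown basis {self.basis!r}")


@dataclass(frozen=True)
class ConversionConstants:
    """Unit-conversion constants for CO2-equivalent reporting.

    ``gwp100`` is per unit N2O mass (default 265; 256 is available for
    comparison with sources that use it); ``n_to_n2o`` = 44/28 converts
    N2O-N mass to N2O mass.
    """

    gwp100: float = 265.0
    n_to_n2o: float = 44.0 / 28.0
    cropland_area_ha: float = 1.35e9

    def __post_init__(self) -> None:
        if min(self.gwp100, self.n_to_n2o, self.cropland_area_ha) <= 0:
            raise InvalidArgumentError("conversion constants must be positive")

    def tg_n_to_pg_co2e(self, tg_n: float) -> float:
        """Tg N2O-N -> Pg CO2e (1 Pg = 1000 Tg)."""
        return tg_n * self.n_to_n2o * self.gwp100 / 1000.0


@dataclass(frozen=True)
class ScenarioProjection:
    """Per-member dynamic emissions plus the parallel static series."""

    scenario_id: str
    years: np.ndarray
    member_ids: tuple[str, ...]
    member_global_tg: np.ndarray        # (n_members, n_years)
    static_global_tg: np.ndarray        # (n_years,)
    member_cell_tg: np.ndarray | None   # (n_members, n_years, n_cells)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    def median_global(self) -> np.ndarray:
        return np.percentile(self.member_global_tg, 50, axis=0)

    def median_cell_field(self, year: int) -> np.ndarray:
        """Cellwise member-median emission (Tg N) at one year."""
        if self.member_cell_tg is None:
            raise InvalidArgumentError("projection did not keep cell fields")
        idx = int(np.flatnonzero(self.years == year)[0])
        return np.percentile(self.member_cell_tg[:, idx, :], 50, axis=0)

    def median_cell_series(self) -> np.ndarray:
        """(n_years, n_cells) member-median emission fields."""
        if self.member_cell_tg is None:
            raise InvalidArgumentError("projection did not keep cell fields")
        return np.percentile(self.member_cell_tg, 50, axis=0)


def project_scenario(scenario: ScenarioSpec, emulator: EFEmulator,
                     climate_members, fertilizer: FertilizerScenarioField,
                     domain: GridDomain, soil: SoilProperties, *,
                     keep_cells: bool = True) -> ScenarioProjection:
    """Project one scenario over its climate-member ensemble.

    For each member: annual climate features + soil + scenario N rates
    -> predicted EF -> emissions.  A parallel static (EF = 1%) series is
    computed from the same fertilizer field; it does not depend on climate.
    """
    members = list(climate_members)
    if not members:
        raise InvalidArgumentError("need at least one climate member")
    for m in members:
        if m.pathway != scenario.climate_pathway:
            raise ConfigError(
                f"member {m.member_id} pathway {m.pathway!r} does not match "
                f"scenario pathway {scenario.climate_pathway!r}")
        if m.n_cells != domain.n_cells:
            raise DomainMismatchError("climate member on a different domain")
    years = fertilizer.years
    n_years, n_cells = years.size, domain.n_cells

    member_global = np.empty((len(members), n_years))
    member_cells = np.empty((len(members), n_years, n_cells)) if keep_cells else None
    for i, m in enumerate(members):
        feats = feature_table(m, soil, fertilizer.rates, years=years)
        ef = predict_ef(emulator, feats)
        ef_grid = np.zeros((n_years, n_cells))
        yr_idx = np.searchsorted(years, feats["year"].to_numpy())
        ef_grid[yr_idx, feats["cell_id"].to_numpy()] = ef
        em = compute_emissions(ef_grid, fertilizer.rates, domain,
                               method="dynamic", scenario_id=scenario.id,
                               member_id=m.member_id)
        member_global[i] = em.cell_tg.sum(axis=-1)
        if keep_cells:
            member_cells[i] = em.cell_tg

    static = static_emissions(fertilizer.rates, domain, scenario_id=scenario.id)
    return ScenarioProjection(
        scenario_id=scenario.id, years=years,
        member_ids=tuple(m.member_id for m in members),
        member_global_tg=member_global,
        static_global_tg=static.cell_tg.sum(axis=-1),
        member_cell_tg=member_cells)


# ---------------------------------------------------------------------------
# ensemble statistics

def ensemble_summary(member_series: np.ndarray, years) -> pd.DataFrame:
    """Median/p25/p75 per year over members (linear-interpolation percentiles)."""
    member_series = np.atleast_2d(np.asarray(member_series, dtype=float))
    if member_series.size == 0:
        raise InvalidArgumentError("empty member series")
    years = np.asarray(years, dtype=int)
    p25, med, p75 = np.percentile(member_series, [25, 50, 75], axis=0)
    return pd.DataFrame({"year": years, "median": med, "p25": p25, "p75": p75})


def relative_change(series: pd.Series, baseline_year: int = BASE_YEAR) -> pd.Series:
    """100 x (x_t - x_base) / x_base, indexed like ``series`` (year index)."""
    if baseline_year not in series.index:
        raise InvalidArgumentError(f"baseline year {baseline_year} not in series")
    base = float(series.loc[baseline_year])
    if base == 0:
        raise UndefinedBaselineError("baseline value is zero")
    return 100.0 * (series - base) / base


def cumulative_target_year(series: pd.Series, goal: ReductionGoal) -> int | None:
    """First year the goal is met, or None if never within the series.

    Annual basis: first t with x_t <= (1-g) x_base.  Cumulative basis:
    first t with sum(x, base+1..t) <= (1-g)(t - base) x_base.
    """
    base_year = goal.baseline_year
    if base_year not in series.index:
        raise InvalidArgumentError(f"baseline year {base_year} not in series")
    x_base = float(series.loc[base_year])
    threshold = (1.0 - goal.goal_fraction) * x_base
    years = np.asarray(series.index, dtype=int)
    after = years > base_year
    if goal.basis == "annual":
        ok = series.to_numpy(dtype=float) <= threshold
        hit = np.flatnonzero(ok & after)
    else:
        cum = np.cumsum(np.where(after, series.to_numpy(dtype=float), 0.0))
        allowed = threshold * (years - base_year)
        hit = np.flatnonzero((cum <= allowed) & after)
    return int(years[hit[0]]) if hit.size else None


def regional_totals(cell_values: np.ndarray, domain: GridDomain) -> pd.DataFrame:
    """Aggregate a cellwise field (last axis = cells) by region.

    Returns one row per region with the summed value and its global share;
    for multi-year inputs the value is summed over leading axes too and the
    per-region yearly series are kept in a ``series`` column of arrays.
    """
    cell_values = np.asarray(cell_values, dtype=float)
    if cell_values.shape[-1] != domain.n_cells:
        raise DomainMismatchError("cell_values misaligned with domain")
    rows = []
    flat = cell_values.reshape(-1, domain.n_cells)
    for region in np.unique(domain.region_id):
        mask = domain.region_id == region
        series = flat[:, mask].sum(axis=-1)
        rows.append({"region": region, "value": float(series.sum()),
                     "series": series})
    out = pd.DataFrame(rows)
    total = out["value"].sum()
    out["share"] = out["value"] / total if total > 0 else 0.0
    return out.sort_values("value", ascending=False, ignore_index=True)


def mitigation_potential(bau_series: pd.Series, ambitious_series: pd.Series,
                         year: int = HORIZON_YEAR,
                         constants: ConversionConstants = ConversionConstants(),
                         ) -> dict[str, float]:
    """Emission cut from a BAU -> ambitious policy shift at one year.

    Returns the cut in Tg N, as percent of the BAU level, in Pg CO2e and
    per hectare of cropland (Mg CO2e ha^-1).
    """
    if year not in bau_series.index or year not in ambitious_series.index:
        raise InvalidArgumentError(f"year {year} missing from a series")
    bau = float(bau_series.loc[year])
    amb = float(ambitious_series.loc[year])
    delta = bau - amb
    pct = 100.0 * delta / bau if bau != 0 else 0.0
    pg = constants.tg_n_to_pg_co2e(delta)
    per_ha = pg * 1e9 / constants.cropland_area_ha   # Mg CO2e per ha
    return {"delta_tg_n": delta, "percent_of_bau": pct,
            "pg_co2e": pg, "mg_co2e_per_ha": per_ha}


def static_dynamic_gap(dynamic_series: pd.Series, static_series: pd.Series
                       ) -> pd.DataFrame:
    """Per-year dynamic-minus-static gap in Tg N and percent of dynamic."""
    if not dynamic_series.index.equals(static_series.index):
        raise InvalidArgumentError("series cover different years")
    gap = dynamic_series - static_series
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(dynamic_series.to_numpy() != 0,
                       100.0 * gap.to_numpy() / dynamic_series.to_numpy(), 0.0)
    return pd.DataFrame({"year": dynamic_series.index.to_numpy(),
                         "gap_tg_n": gap.to_numpy(), "gap_percent": pct})
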