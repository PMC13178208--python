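"""Hotspot ranking and nitrification-inhibitor (NI) mitigation analysis.

Cells are ranked by emission rate per unit fertilized area (descending,
ties broken by ascending cell id).  NI adoption expands along that ranking
as a fraction of total agricultural area, with the boundary cell counted
pro-rata; adopted emissions are cut by the NI efficiency (default 34%)
without changing fertilizer input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GridDomain
from .errors import InvalidArgumentError

NI_EFFICIENCY = 0.34


@dataclass(frozen=True)
class HotspotRanking:
    """Descending emission-rate ordering with cumulative area/emission curves."""

    order: np.ndarray            # cell indices, rate-descending
    rates: np.ndarray            # g N m^-2 yr^-1 along the order
    areas: np.ndarray            # fertilized area (ha) along the order
    emissions: np.ndarray        # Tg N along the order
    cum_area_frac: np.ndarray    # ends at 1
    cum_emission_share: np.ndarray

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def total_emission(self) -> float:
        return float(self.emissions.sum())


def rank_hotspots(cell_emissions_tg: np.ndarray, domain: GridDomain) -> HotspotRanking:
    """Rank cells by emission rate per unit fertilized area.

    Cells with zero fertilized area have rate 0 and sort last.
    """
    em = np.asarray(cell_emissions_tg, dtype=float)
    if em.shape != (domain.n_cells,):
        raise InvalidArgumentError("cell_emissions misaligned with domain")
    area = domain.fertilized_area_ha
    with np.errstate(divide="ignore", invalid="ignore"):
        # Tg / ha -> g/m2: 1 Tg = 1e12 g, 1 ha = 1e4 m2
        rate = np.where(area > 0, em * 1e12 / (area * 1e4), 0.0)
    order = np.lexsort((domain.cell_id, -rate))
    areas = area[order]
    ems = em[order]
    tot_area = areas.sum()
    tot_em = ems.sum()
    cum_area = np.cumsum(areas) / tot_area if tot_area > 0 else np.cumsum(areas)
    cum_em = np.cumsum(ems) / tot_em if tot_em > 0 else np.cumsum(ems)
    return HotspotRanking(order=order, rates=rate[order], areas=areas,
                          emissions=ems, cum_area_frac=cum_area,
                          cum_emission_share=cum_em)


def _prefix_coverage(ranking: HotspotRanking, fraction: float) -> np.ndarray:
    """Per-ranked-cell adoption coverage in [0, 1] for an area fraction.

    Full coverage for cells wholly inside the prefix; the boundary cell is
    covered pro-rata.
    """
    if not (0.0 <= fraction <= 1.0):
        raise InvalidArgumentError("fraction must lie in [0, 1]")
    target = fraction * ranking.total_area
    cum = np.cumsum(ranking.areas)
    cov = np.clip((target - (cum - ranking.areas)) /
                  np.where(ranking.areas > 0, ranking.areas, 1.0), 0.0, 1.0)
    cov[ranking.areas == 0] = 0.0
    return cov


def top_fraction_share(ranking: HotspotRanking, fraction: float) -> float:
    """Emission share of the smallest ranking prefix reaching the area
    fraction, boundary cell pro-rata."""
    if ranking.total_emission <= 0:
        return 0.0
    cov = _prefix_coverage(ranking, fraction)
    return float((cov * ranking.emissions).sum() / ranking.total_emission)


def apply_ni(cell_emissions_tg: np.ndarray, ranking: HotspotRanking,
             adoption_fraction: float, efficiency: float = NI_EFFICIENCY
             ) -> np.ndarray:
    """Emission field after NI adoption on the top ``adoption_fraction``.

    Total removed = efficiency x emissions of the adopted prefix, exactly.
    """
    if not (0.0 <= efficiency < 1.0):
        raise InvalidArgumentError("efficiency must lie in [0, 1)")
    em = np.asarray(cell_emissions_tg, dtype=float).copy()
    cov = _prefix_coverage(ranking, adoption_fraction)
    em[ranking.order] = em[ranking.order] * (1.0 - efficiency * cov)
    return em


def ni_reduction_curve(cell_emissions_tg: np.ndarray, ranking: HotspotRanking,
                       baseline_2010_total: float,
                       efficiency: float = NI_EFFICIENCY,
                       fractions=None) -> pd.DataFrame:
    """Reduction vs 2010 baseline as NI adoption expands along the ranking.

    reduction%(f) = 100 x (E_2010 - E_NI(f)) / E_2010.  Monotone
    non-decreasing in f; concave whenever the ranking is strictly ordered.
    """
    if baseline_2010_total <= 0:
        raise InvalidArgumentError("baseline total must be positive")
    if fractions is None:
        fractions = np.linspace(0.0, 1.0, 101)
    fractions = np.asarray(fractions, dtype=float)
    rows = []
    for f in fractions:
        total = apply_ni(cell_emissions_tg, ranking, f, efficiency).sum()
        rows.append({"fraction": f,
                     "reduction_pct": 100.0 * (baseline_2010_total - total)
                     / baseline_2010_total})
    return pd.DataFrame(rows)


def minimal_adoption_fraction(cell_emissions_tg: np.ndarray,
                              ranking: HotspotRanking, goal: float,
                              baseline_2010_total: float,
                              efficiency: float = NI_EFFICIENCY) -> float | None:
    """Smallest adoption area fraction meeting a reduction goal vs 2010.

    The reduction is piecewise-linear and non-decreasing in the adopted
    area, so the curve is inverted exactly by walking the ranking prefix
    (the continuous-knapsack optimum: highest-rate cells remove the most
    emission per unit area).  Returns None if unattainable at f = 1.
    """
    if not (0.0 < goal < 1.0):
        raise InvalidArgumentError("goal must lie in (0, 1)")
    if baseline_2010_total <= 0:
        raise InvalidArgumentError("baseline total must be positive")
    current = float(np.asarray(cell_emissions_tg, dtype=float).sum())
    needed = current - (1.0 - goal) * baseline_2010_total
    if needed <= 0:
        return 0.0
    removable = efficiency * ranking.emissions          # per ranked cell
    cum_removed = np.cumsum(removable)
    if cum_removed[-1] < needed - 1e-12:
        return None
    k = int(np.searchsorted(cum_removed, needed))
    removed_before = cum_removed[k - 1] if k > 0 else 0.0
    lam = ((needed - removed_before) / removable[k]) if removable[k] > 0 else 1.0
    area_before = ranking.areas[:k].sum()
    frac = (area_before + lam * ranking.areas[k]) / ranking.total_area
    return float(min(frac, 1.0))


def expedited_timeline(cell_emissions_by_year: np.ndarray, years,
                       ranking: HotspotRanking, goal: float,
                       baseline_2010_total: float,
                       efficiency: float = NI_EFFICIENCY,
                       fractions=None, start_year: int = 2020) -> pd.DataFrame:
    """Goal-attainment year as a function of NI adoption fraction.

    NI is applied (along the fixed ranking) to every year >= start_year;
    the goal year is the first year with emissions <= (1-goal) x baseline.
    Goal year is non-increasing in the adoption fraction.
    """
    em = np.asarray(cell_emissions_by_year, dtype=float)
    years = np.asarray(years, dtype=int)
    if em.shape[0] != years.size:
        raise InvalidArgumentError("emission series misaligned with years")
    if fractions is None:
        fractions = np.linspace(0.0, 1.0, 21)
    threshold = (1.0 - goal) * baseline_2010_total
    rows = []
    for f in np.asarray(fractions, dtype=float):
        cov = _prefix_coverage(ranking, f)
        keep = np.ones(em.shape[1])
        keep[ranking.order] = 1.0 - efficiency * cov
        totals = np.where(years[:, None] >= start_year,
                          em * keep[None, :], em).sum(axis=1)
        hit = np.flatnonzero((totals <= threshold) & (years > 2010))
        rows.append({"fraction": float(f),
                     "goal_year": int(years[hit[0]]) if hit.size else None})
    return pd.DataFrame(rows)
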