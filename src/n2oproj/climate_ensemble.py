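"""Climate harmonization: delta bias correction, aridity index, annual features.

The delta correction subtracts, per cell and calendar month, the model-minus
-observation offset over a reference period from the projected series:

    corrected = projected - (mean(model, ref) - mean(obs, ref))

Temperature is unbounded; precipitation is floored at zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ClimateSeries, N_MONTHS
from .errors import DomainMismatchError, IncompleteYearError, InvalidArgumentError

DEFAULT_REFERENCE_PERIOD: tuple[int, int] = (1995, 2014)

#: Cap substituted for the aridity index where PET is zero but P > 0.
ARIDITY_CAP = 30.0


def _reference_mean(series: ClimateSeries, reference_period: tuple[int, int]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-calendar-month (12, n_cells) climatological means over the period."""
    y0, y1 = reference_period
    mask = (series.years >= y0) & (series.years <= y1)
    if not mask.any():
        raise InvalidArgumentError(
            f"reference period {reference_period} outside series coverage")
    return (series.temperature[mask].mean(axis=0),
            series.precipitation[mask].mean(axis=0))


def delta_bias_correct(projected: ClimateSeries, historical_model: ClimateSeries,
                       observed: ClimateSeries,
                       reference_period: tuple[int, int] = DEFAULT_REFERENCE_PERIOD,
                       ) -> ClimateSeries:
    """Delta-method bias correction of one projected member.

    Raises
    ------
    DomainMismatchError
        If the three series do not share the same cell count.
    InvalidArgumentError
        If the reference period lies outside the historical coverage.
    """
    if not (projected.n_cells == historical_model.n_cells == observed.n_cells):
        raise DomainMismatchError("series are on different domains")
    t_mod, p_mod = _reference_mean(historical_model, reference_period)
    t_obs, p_obs = _reference_mean(observed, reference_period)
    temp = projected.temperature - (t_mod - t_obs)[None, :, :]
    prec = np.clip(projected.precipitation - (p_mod - p_obs)[None, :, :], 0.0, None)
    return projected.with_data(temperature=temp, precipitation=prec)


def correct_ensemble(members, historical_members, observed,
                     reference_period=DEFAULT_REFERENCE_PERIOD):
    """Delta-correct each member against its own historical counterpart."""
    hist_by_id = {m.member_id: m for m in historical_members}
    out = []
    for m in members:
        try:
            hist = hist_by_id[m.member_id]
        except KeyError:
            raise DomainMismatchError(f"no historical series for {m.member_id}")
        out.append(delta_bias_correct(m, hist, observed, reference_period))
    return out


# ---------------------------------------------------------------------------
# Thornthwaite-style PET and aridity

def thornthwaite_pet(monthly_temp: np.ndarray) -> np.ndarray:
    """Monthly potential evapotranspiration (mm), temperature-only.

    Standard Thornthwaite with the day-length factor fixed at 12 h
    (30-day months).  Months at or below 0 deg C contribute nothing.
    ``monthly_temp`` has shape (..., 12); PET has the same shape.
    """
    t = np.asarray(monthly_temp, dtype=float)
    if t.shape[-1] != N_MONTHS:
        raise InvalidArgumentError("expected 12 monthly temperatures")
    tpos = np.clip(t, 0.0, None)
    heat = ((tpos / 5.0) ** 1.514).sum(axis=-1)
    a = (6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239)
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (10.0 * tpos / heat[..., None]) ** a[..., None]
    pet = np.where((tpos > 0) & (heat[..., None] > 0), pet, 0.0)
    return pet


def aridity_index(annual_precip: np.ndarray, monthly_temp: np.ndarray,
                  cap: float = ARIDITY_CAP) -> np.ndarray:
    """AI = annual precipitation / annual PET, capped where PET = 0.

    Zero precipitation gives AI = 0 regardless of PET.
    """
    p = np.asarray(annual_precip, dtype=float)
    if np.any(p < 0):
        raise InvalidArgumentError("precipitation must be >= 0")
    pet = thornthwaite_pet(monthly_temp).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(pet > 0, p / pet, np.where(p > 0, cap, 0.0))
    return ai


# ---------------------------------------------------------------------------
# annual feature extraction

def annual_features(series: ClimateSeries) -> pd.DataFrame:
    """Per cell-year climate features: columns cell, year, tas, precip, aridity.

    ``tas`` is the annual mean temperature (deg C), ``precip`` the annual
    total (mm).  Schema matches the climate block of the training table.
    """
    if series.temperature.shape[1] != N_MONTHS:
        raise IncompleteYearError("incomplete monthly coverage")
    ny, _, nc = series.temperature.shape
    tas = series.temperature.mean(axis=1)                  # (ny, nc)
    precip = series.precipitation.sum(axis=1)              # (ny, nc)
    # aridity wants months on the last axis
    ai = aridity_index(precip, np.moveaxis(series.temperature, 1, -1))
    years = np.repeat(series.years, nc)
    cells = np.tile(np.arange(nc), ny)
    return pd.DataFrame({
        "cell": cells, "year": years,
        "tas": tas.ravel(), "precip": precip.ravel(), "aridity": ai.ravel(),
    })


def feature_table(series: ClimateSeries, soil, n_rate_by_year: np.ndarray,
                  years=None) -> pd.DataFrame:
    """Full emulator feature table for one member.

    ``n_rate_by_year`` is (n_years, n_cells) aligned with ``series.years``
    (or with ``years`` when given).  Output columns follow the shared
    feature schema plus bookkeeping ``cell_id``/``year``.
    """
    if years is None:
        years = series.years
    years = np.asarray(years, dtype=int)
    n_rate_by_year = np.asarray(n_rate_by_year, dtype=float)
    if n_rate_by_year.shape != (years.size, series.n_cells):
        raise DomainMismatchError("n_rate_by_year misaligned with climate series")
    feats = annual_features(series)
    feats = feats[np.isin(feats["year"].to_numpy(), years)].reset_index(drop=True)
    cells = feats["cell"].to_numpy()
    yr_idx = np.searchsorted(years, feats["year"].to_numpy())
    return pd.DataFrame({
        "cell_id": cells,
        "year": feats["year"].to_numpy(),
        "n_rate": n_rate_by_year[yr_idx, cells],
        "tas": feats["tas"].to_numpy(),
        "precip": feats["precip"].to_numpy(),
        "aridity": feats["aridity"].to_numpy(),
        "soc": soil.soc[cells],
        "ph": soil.ph[cells],
        "bulk_density": soil.bulk_density[cells],
        "sand_frac": soil.sand_frac[cells],
        "clay_frac": soil.clay_frac[cells],
    })
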