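"""NetCDF/CSV writers for generated fields and summary tables.

NetCDF files use CF-style dimensions (time, cell) or (member, time, cell)
and the scipy backend (classic NetCDF3), which needs no extra libraries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .datatypes import ClimateSeries, GridDomain


def _cell_coords(domain: GridDomain) -> dict:
    return {
        "cell": domain.cell_id,
        "lat": ("cell", domain.lat),
        "lon": ("cell", domain.lon),
    }


def domain_to_frame(domain: GridDomain) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": domain.cell_id, "lat": domain.lat, "lon": domain.lon,
        "area_ha": domain.area_ha, "country_id": domain.country_id,
        "region_id": domain.region_id, "cropland_frac": domain.cropland_frac,
        "pasture_frac": domain.pasture_frac,
    })


def write_climate_netcdf(series: ClimateSeries, domain: GridDomain, path) -> None:
    """Write one climate series with a flat monthly time axis."""
    ny, nm, nc = series.temperature.shape
    time = series.years.repeat(nm) + (np.tile(np.arange(nm), ny) + 0.5) / 12.0
    ds = xr.Dataset(
        {
            "tas": (("time", "cell"), series.temperature.reshape(ny * nm, nc),
                    {"units": "degC", "long_name": "near-surface air temperature"}),
            "pr": (("time", "cell"), series.precipitation.reshape(ny * nm, nc),
                   {"units": "mm month-1", "long_name": "precipitation"}),
        },
        coords={"time": time, **_cell_coords(domain)},
        attrs={"member_id": series.member_id, "pathway": series.pathway},
    )
    ds.to_netcdf(path, engine="scipy")


def write_emission_netcdf(cell_tg: np.ndarray, years, domain: GridDomain, path,
                          *, ef: np.ndarray | None = None,
                          n_rate: np.ndarray | None = None,
                          attrs: dict | None = None) -> None:
    """Write (n_years, n_cells) emissions (optionally EF and N rate) to NetCDF."""
    data = {"n2o_emission": (("time", "cell"), np.asarray(cell_tg, dtype=float),
                             {"units": "Tg N yr-1"})}
    if ef is not None:
        data["ef"] = (("time", "cell"), np.asarray(ef, dtype=float),
                      {"units": "percent"})
    if n_rate is not None:
        data["n_rate"] = (("time", "cell"), np.asarray(n_rate, dtype=float),
                          {"units": "kg N ha-1 yr-1"})
    ds = xr.Dataset(data,
                    coords={"time": np.asarray(years, dtype=int),
                            **_cell_coords(domain)},
                    attrs=attrs or {})
    ds.to_netcdf(path, engine="scipy")


def write_summary_csv(summaries: dict[str, pd.DataFrame], path) -> None:
    """Stack per-scenario ensemble summaries into one long CSV."""
    frames = []
    for sid, df in summaries.items():
        out = df.copy()
        out.insert(0, "scenario", sid)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
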