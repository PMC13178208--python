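"""Core array-backed data containers shared across modules.

All containers hold plain numpy arrays aligned on a common cell index; they
validate their invariants at construction time and are cheap to copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError
from .regions import REGIONS

PATHWAYS: tuple[str, ...] = ("HIST", "SSP1-2.6", "SSP2-4.5", "SSP5-8.5")
N_MONTHS = 12


@dataclass(frozen=True)
class GridDomain:
    """Abstract list of grid cells with area and political membership.

    Attributes
    ----------
    cell_id : (n,) int array — unique, sorted ascending.
    lat, lon : (n,) degrees.
    area_ha : (n,) cell area in hectares, > 0.
    country_id : (n,) str array; every country belongs to one region.
    region_id : (n,) str array drawn from :data:`n2oproj.regions.REGIONS`.
    cropland_frac, pasture_frac : (n,) fractions with sum in [0, 1].
    """

    cell_id: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    area_ha: np.ndarray
    country_id: np.ndarray
    region_id: np.ndarray
    cropland_frac: np.ndarray
    pasture_frac: np.ndarray

    def __post_init__(self) -> None:
        n = self.cell_id.size
        for name in ("lat", "lon", "area_ha", "country_id", "region_id",
                     "cropland_frac", "pasture_frac"):
            if getattr(self, name).shape != (n,):
                raise InvalidArgumentError(f"field {name!r} misaligned with cell_id")
        if np.any(self.area_ha <= 0):
            raise InvalidArgumentError("cell areas must be positive")
        agg = self.cropland_frac + self.pasture_frac
        if np.any(self.cropland_frac < 0) or np.any(self.pasture_frac < 0) or np.any(agg > 1 + 1e-12):
            raise InvalidArgumentError("cropland_frac + pasture_frac must lie in [0, 1]")
        bad = set(np.unique(self.region_id)) - set(REGIONS)
        if bad:
            raise InvalidArgumentError(f"unknown region labels: {sorted(bad)}")
        # each country maps to exactly one region
        pairs = {}
        for c, r in zip(self.country_id, self.region_id):
            if pairs.setdefault(c, r) != r:
                raise InvalidArgumentError(f"country {c!r} spans multiple regions")

    @property
    def n_cells(self) -> int:
        return int(self.cell_id.size)

    @property
    def agricultural_frac(self) -> np.ndarray:
        return self.cropland_frac + self.pasture_frac

    @property
    def fertilized_area_ha(self) -> np.ndarray:
        """Agricultural (cropland + pasture) area per cell, hectares."""
        return self.area_ha * self.agricultural_frac

    @property
    def countries(self) -> np.ndarray:
        return np.unique(self.country_id)

    def region_of_country(self) -> dict[str, str]:
        return {str(c): str(r) for c, r in zip(self.country_id, self.region_id)}


@dataclass(frozen=True)
class SoilProperties:
    """Time-invariant per-cell soil fields."""

    ph: np.ndarray            # unitless, in [3, 10]
    soc: np.ndarray           # g C kg^-1, > 0
    bulk_density: np.ndarray  # g cm^-3
    sand_frac: np.ndarray
    clay_frac: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.ph < 3) or np.any(self.ph > 10):
            raise InvalidArgumentError("pH outside [3, 10]")
        if np.any(self.soc <= 0):
            raise InvalidArgumentError("soc must be positive")
        if np.any(self.sand_frac + self.clay_frac > 1 + 1e-12):
            raise InvalidArgumentError("sand_frac + clay_frac must be <= 1")

    @property
    def n_cells(self) -> int:
        return int(self.ph.size)


@dataclass(frozen=True)
class ClimateSeries:
    """Monthly temperature/precipitation for one member (or observations).

    ``temperature`` and ``precipitation`` have shape (n_years, 12, n_cells);
    ``member_id`` is ``"OBS"`` for the observational series.
    """

    years: np.ndarray
    temperature: np.ndarray    # deg C
    precipitation: np.ndarray  # mm month^-1
    member_id: str
    pathway: str

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise InvalidArgumentError(f"unknown pathway {self.pathway!r}")
        ny = self.years.size
        if self.temperature.shape[:2] != (ny, N_MONTHS):
            raise InvalidArgumentError("temperature must be (n_years, 12, n_cells)")
        if self.precipitation.shape != self.temperature.shape:
            raise InvalidArgumentError("temperature/precipitation shapes differ")
        if np.any(self.precipitation < 0):
            raise InvalidArgumentError("precipitation must be >= 0")
        if self.member_id == "OBS" and self.pathway != "HIST":
            raise InvalidArgumentError("OBS exists only for HIST years")

    @property
    def n_cells(self) -> int:
        return int(self.temperature.shape[2])

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise InvalidArgumentError(f"year {year} not in series")
        return int(idx[0])

    def with_data(self, temperature: np.ndarray, precipitation: np.ndarray,
                  **kw) -> "ClimateSeries":
        return replace(self, temperature=temperature, precipitation=precipitation, **kw)


@dataclass(frozen=True)
class ClimateEnsemble:
    """Observations (HIST only) plus biased pseudo-GCM members."""

    pathway: str
    obs: ClimateSeries | None
    members: tuple[ClimateSeries, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.obs is not None and self.obs.pathway != "HIST":
            raise InvalidArgumentError("obs must carry the HIST pathway")
        for m in self.members:
            if m.pathway != self.pathway:
                raise InvalidArgumentError("member pathway mismatch")

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class FertilizerBaseline:
    """Baseline (2010) fertilizer N rate on the fertilized fraction of a cell."""

    n_rate_2010: np.ndarray  # kg N ha^-1 yr^-1

    def __post_init__(self) -> None:
        if np.any(self.n_rate_2010 < 0):
            raise InvalidArgumentError("n_rate_2010 must be >= 0")

    @property
    def n_cells(self) -> int:
        return int(self.n_rate_2010.size)
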