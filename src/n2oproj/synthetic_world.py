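"""Synthetic-world generators.

Everything downstream (emulator training, scenario projection, hotspot
analysis) runs on worlds produced here: a cell grid with soil, climate,
a skewed baseline fertilizer map, and a closed-form "true" emission-factor
response surface whose value is known at every point — which is what makes
the learned emulator falsifiable.

All generators are pure functions of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import (
    N_MONTHS,
    PATHWAYS,
    ClimateEnsemble,
    ClimateSeries,
    FertilizerBaseline,
    GridDomain,
    SoilProperties,
)
from .errors import CalibrationError, EmptyTableError, InvalidArgumentError
from .regions import REGIONS

#: Ordered feature schema shared by the training table, the annual feature
#: extractor and the emulator.
FEATURE_COLUMNS: tuple[str, ...] = (
    "n_rate", "tas", "precip", "aridity",
    "soc", "ph", "bulk_density", "sand_frac", "clay_frac",
)

#: Default end-of-century-style warming trend per pathway, deg C per decade.
DEFAULT_WARMING_RATE: dict[str, float] = {
    "HIST": 0.0, "SSP1-2.6": 0.10, "SSP2-4.5": 0.25, "SSP5-8.5": 0.45,
}

TREND_REF_YEAR = 2005  # warming trend is zero at this year

# internal rng stream ids (kept stable so OBS/geography agree across calls)
_STREAM_GEO = 101
_STREAM_OBS_NOISE = 201
_STREAM_MEMBER_BIAS = 301
_STREAM_MEMBER_NOISE = 401


# ---------------------------------------------------------------------------
# domain

def generate_domain(n_cells: int, n_countries: int = 18, seed: int = 0) -> GridDomain:
    """Random cell grid partitioned into countries, one region per country.

    Cells carry cos-latitude-weighted areas of a nominal 0.5-degree grid.
    Countries are longitude-contiguous blocks of random size (each >= 1 cell).
    """
    if n_countries < 1 or n_cells < n_countries:
        raise InvalidArgumentError("need n_cells >= n_countries >= 1")
    rng = np.random.default_rng([seed, 1])
    lat = rng.uniform(-55.0, 65.0, n_cells)
    lon = rng.uniform(-180.0, 180.0, n_cells)
    # 0.5 deg x 0.5 deg cell: ~3098 km^2 at the equator
    area_ha = 3098.0 * np.cos(np.deg2rad(lat)) * 100.0

    # longitude-contiguous country blocks with random sizes
    order = np.argsort(lon, kind="stable")
    sizes = rng.multinomial(n_cells - n_countries, np.full(n_countries, 1.0 / n_countries)) + 1
    country = np.empty(n_cells, dtype=object)
    start = 0
    for i, sz in enumerate(sizes):
        country[order[start:start + sz]] = f"C{i:02d}"
        start += sz
    country = country.astype(str)

    # one region per country; distinct while they last, then cycled
    perm = rng.permutation(len(REGIONS))
    region_of = {f"C{i:02d}": REGIONS[perm[i % len(REGIONS)]] for i in range(n_countries)}
    region = np.array([region_of[c] for c in country])

    crop = rng.beta(2.0, 4.0, n_cells) * 0.7
    past = rng.beta(2.0, 6.0, n_cells) * (1.0 - crop)
    nonag = rng.random(n_cells) < 0.15
    crop[nonag] = 0.0
    past[nonag] = 0.0

    return GridDomain(
        cell_id=np.arange(n_cells),
        lat=lat, lon=lon, area_ha=area_ha,
        country_id=country, region_id=region,
        cropland_frac=crop, pasture_frac=past,
    )


# ---------------------------------------------------------------------------
# soil

def _random_smooth_field(rng: np.random.Generator, lat: np.ndarray,
                         lon: np.ndarray, n_waves: int = 24,
                         wavelength_deg: float = 35.0) -> np.ndarray:
    """Standardized Gaussian-ish random field via random cosine features.

    Long-wavelength cosines give positive correlation between nearby cells,
    which is all the soil generator needs.
    """
    k = 2.0 * np.pi / wavelength_deg
    freq = rng.normal(0.0, k, size=(n_waves, 2))
    phase = rng.uniform(0.0, 2.0 * np.pi, n_waves)
    amp = rng.normal(0.0, 1.0, n_waves)
    field = np.zeros_like(lat)
    for i in range(n_waves):
        field += amp[i] * np.cos(freq[i, 0] * lat + freq[i, 1] * lon + phase[i])
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_soil(domain: GridDomain, seed: int = 0) -> SoilProperties:
    """Spatially autocorrelated soil fields satisfying all invariants."""
    z = [_random_smooth_field(np.random.default_rng([seed, 2, i]), domain.lat, domain.lon)
         for i in range(5)]
    ph = np.clip(6.5 + 1.1 * z[0], 3.0, 10.0)
    soc = np.exp(2.3 + 0.55 * z[1])                      # median ~10 g/kg
    bulk = np.clip(1.35 + 0.14 * z[2], 0.8, 1.9)
    sand = 0.15 + 0.60 / (1.0 + np.exp(-z[3]))
    clay = (1.0 - sand) * (0.20 + 0.50 / (1.0 + np.exp(-z[4])))
    return SoilProperties(ph=ph, soc=soc, bulk_density=bulk,
                          sand_frac=sand, clay_frac=clay)


# ---------------------------------------------------------------------------
# climate

def climatology(domain: GridDomain, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic monthly climatology (12, n_cells): (temperature, precip).

    Shared by OBS and every member so the delta correction has a common
    anchor; latitude sets the mean state, a seeded smooth field adds
    geography, and the seasonal cycle flips sign across the equator.
    """
    latr = np.deg2rad(domain.lat)
    geo_t = _random_smooth_field(np.random.default_rng([seed, _STREAM_GEO, 0]),
                                 domain.lat, domain.lon)
    geo_p = _random_smooth_field(np.random.default_rng([seed, _STREAM_GEO, 1]),
                                 domain.lat, domain.lon)
    t_mean = 28.0 * np.cos(latr) ** 1.3 - 2.0 + 2.0 * geo_t
    t_amp = 3.0 + 14.0 * np.abs(np.sin(latr))
    months = np.arange(N_MONTHS)
    # northern-hemisphere peak in July, southern in January
    phase = np.where(domain.lat >= 0, 6.5, 0.5)
    temp = t_mean[None, :] - t_amp[None, :] * np.cos(
        2.0 * np.pi * (months[:, None] - phase[None, :]) / 12.0)
    p_mean = np.clip(75.0 * (0.35 + 0.9 * np.cos(latr) ** 2) * np.exp(0.35 * geo_p), 2.0, None)
    p_season = 1.0 + 0.35 * np.cos(2.0 * np.pi * (months[:, None] - phase[None, :]) / 12.0)
    precip = np.clip(p_mean[None, :] * p_season, 0.0, None)
    return temp, precip


def _warming_trend(years: np.ndarray, warming_rate: float) -> np.ndarray:
    """Linear warming (deg C) per year relative to TREND_REF_YEAR."""
    return warming_rate / 10.0 * np.clip(years - TREND_REF_YEAR, 0, None)


def generate_climate(domain: GridDomain, years, pathway: str,
                     n_members: int = 1, warming_rate: float | None = None,
                     bias_sd: float = 0.6, noise_sd: float = 0.5,
                     seed: int = 0) -> ClimateEnsemble:
    """Observed (HIST) and/or member climate series for one pathway.

    Members share the OBS climatology plus a member-specific additive bias
    (temperature, sd ``bias_sd``; multiplicative for precipitation), a
    pathway warming trend and seeded interannual noise.  Member biases
    depend only on (seed, member index), so the same member drawn under
    HIST and under an SSP carries the same bias — the property the delta
    correction exploits.
    """
    years = np.asarray(years, dtype=int)
    if years.size == 0:
        raise InvalidArgumentError("years must be non-empty")
    if n_members < 1:
        raise InvalidArgumentError("n_members must be >= 1")
    if pathway not in PATHWAYS:
        raise InvalidArgumentError(f"unknown pathway {pathway!r}")
    if warming_rate is None:
        warming_rate = DEFAULT_WARMING_RATE[pathway]

    t_clim, p_clim = climatology(domain, seed)
    ny, nc = years.size, domain.n_cells

    obs = None
    if pathway == "HIST":
        rng = np.random.default_rng([seed, _STREAM_OBS_NOISE])
        t = np.broadcast_to(t_clim, (ny, N_MONTHS, nc)).copy()
        p = np.broadcast_to(p_clim, (ny, N_MONTHS, nc)).copy()
        t += noise_sd * rng.standard_normal((ny, 1, nc))
        p = np.clip(p * np.exp(0.12 * rng.standard_normal((ny, 1, nc))
                               * (noise_sd / 0.5 if noise_sd else 0.0)), 0.0, None)
        obs = ClimateSeries(years=years, temperature=t, precipitation=p,
                            member_id="OBS", pathway="HIST")

    trend = _warming_trend(years, warming_rate)
    members = []
    for m in range(n_members):
        rng_b = np.random.default_rng([seed, _STREAM_MEMBER_BIAS, m])
        t_bias = bias_sd * rng_b.standard_normal()
        p_bias = np.exp(0.2 * (bias_sd / 0.6 if bias_sd else 0.0) * rng_b.standard_normal())
        rng_n = np.random.default_rng(
            [seed, _STREAM_MEMBER_NOISE, m, PATHWAYS.index(pathway)])
        t = np.broadcast_to(t_clim, (ny, N_MONTHS, nc)).copy()
        p = np.broadcast_to(p_clim, (ny, N_MONTHS, nc)).copy()
        t += t_bias + trend[:, None, None]
        t += noise_sd * rng_n.standard_normal((ny, 1, nc))
        p = np.clip(p * p_bias * np.exp(0.12 * rng_n.standard_normal((ny, 1, nc))
                                        * (noise_sd / 0.5 if noise_sd else 0.0)), 0.0, None)
        members.append(ClimateSeries(years=years, temperature=t, precipitation=p,
                                     member_id=f"m{m:02d}", pathway=pathway))
    return ClimateEnsemble(pathway=pathway, obs=obs, members=tuple(members))


# ---------------------------------------------------------------------------
# truth surface

@dataclass(frozen=True)
class EFSurface:
    """Closed-form 'true' emission-factor response, in percent of applied N.

    Multiplicative structure: saturating-increasing in N rate, exponential
    in temperature, unimodal in aridity and pH, mild tanh modifier in SOC.
    All factors are positive, so EF >= 0 everywhere; monotonicity in N rate
    and temperature holds by construction.  ``constant`` short-circuits the
    whole thing to a flat surface (used for static-limit tests).
    """

    scale: float = 1.0
    n_half: float = 120.0       # kg N/ha at half saturation
    n_floor: float = 0.35       # response at zero N, relative
    beta_temp: float = 0.045    # per deg C
    t_ref: float = 15.0         # deg C
    ai_opt: float = 0.8
    ai_width: float = 0.9
    ai_floor: float = 0.55
    soc_coef: float = 0.15
    soc_ref: float = 12.0       # g C/kg
    soc_width: float = 8.0
    ph_opt: float = 6.5
    ph_width: float = 2.5
    ph_floor: float = 0.7
    noise_sd: float = 0.0       # label noise, EF percentage points
    constant: float | None = None

    def ef(self, n_rate, tas, aridity, soc, ph) -> np.ndarray:
        n_rate, tas, aridity, soc, ph = np.broadcast_arrays(
            *(np.asarray(x, dtype=float) for x in (n_rate, tas, aridity, soc, ph)))
        if self.constant is not None:
            return np.full(n_rate.shape, float(self.constant))
        L = self.n_floor + (1.0 - self.n_floor) * n_rate / (n_rate + self.n_half)
        T = np.exp(self.beta_temp * (tas - self.t_ref))
        A = self.ai_floor + (1.0 - self.ai_floor) * np.exp(
            -0.5 * ((aridity - self.ai_opt) / self.ai_width) ** 2)
        S = 1.0 + self.soc_coef * np.tanh((soc - self.soc_ref) / self.soc_width)
        P = self.ph_floor + (1.0 - self.ph_floor) * np.exp(
            -0.5 * ((ph - self.ph_opt) / self.ph_width) ** 2)
        return self.scale * L * T * A * S * P

    def ef_table(self, features: pd.DataFrame) -> np.ndarray:
        """Evaluate on a feature table carrying the shared schema."""
        return self.ef(features["n_rate"].to_numpy(), features["tas"].to_numpy(),
                       features["aridity"].to_numpy(), features["soc"].to_numpy(),
                       features["ph"].to_numpy())


def calibrate_surface(surface: EFSurface, features: pd.DataFrame,
                      weights: np.ndarray,
                      target_window: tuple[float, float] = (1.18, 1.22),
                      max_iter: int = 20) -> EFSurface:
    """Rescale so the weighted mean EF lands inside ``target_window``.

    The surface is linear in ``scale`` so one multiplicative step suffices;
    the loop is retained as a guard against degenerate inputs.
    """
    lo, hi = target_window
    if not (0 < lo <= hi):
        raise InvalidArgumentError("invalid target window")
    if surface.constant is not None:
        raise CalibrationError("cannot calibrate a constant surface")
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise CalibrationError("calibration weights sum to zero")
    target = 0.5 * (lo + hi)
    s = surface
    for _ in range(max_iter):
        mean = float(np.average(s.ef_table(features), weights=w))
        if lo <= mean <= hi:
            return s
        if mean <= 0:
            raise CalibrationError("surface mean is non-positive")
        s = replace(s, scale=s.scale * target / mean)
    raise CalibrationError("failed to reach target window")


def generate_true_ef_surface(params: dict | None = None, seed: int = 0,
                             calibrate_features: pd.DataFrame | None = None,
                             calibrate_weights: np.ndarray | None = None,
                             target_window: tuple[float, float] = (1.18, 1.22),
                             ) -> EFSurface:
    """Build (and optionally calibrate) the truth surface.

    ``params`` overrides :class:`EFSurface` defaults; when calibration
    features/weights describing the 2010 world are supplied, the scale is
    adjusted so the weighted mean EF falls inside ``target_window``.
    """
    surface = EFSurface(**(params or {}))
    if surface.constant is not None:
        return surface
    if calibrate_features is not None:
        if calibrate_weights is None:
            raise InvalidArgumentError("calibration requires weights")
        surface = calibrate_surface(surface, calibrate_features,
                                    calibrate_weights, target_window)
    return surface


# ---------------------------------------------------------------------------
# fertilizer

def generate_baseline_fertilizer(domain: GridDomain, mean_rate: float = 80.0,
                                 skew: float = 1.25, seed: int = 0
                                 ) -> FertilizerBaseline:
    """Right-skewed baseline N rates on agricultural cells, zero elsewhere.

    ``skew`` is the log-normal sigma; 0 gives a uniform rate.  The default
    concentrates well over 30% of total N in the top decile of cells, which
    is what seeds the hotspot analysis.
    """
    if mean_rate <= 0:
        raise InvalidArgumentError("mean_rate must be positive")
    if skew < 0:
        raise InvalidArgumentError("skew must be >= 0")
    ag = domain.agricultural_frac > 0
    rates = np.zeros(domain.n_cells)
    n_ag = int(ag.sum())
    if n_ag:
        if skew == 0:
            rates[ag] = mean_rate
        else:
            rng = np.random.default_rng([seed, 3])
            raw = rng.lognormal(mean=0.0, sigma=skew, size=n_ag)
            rates[ag] = raw * (mean_rate / raw.mean())
    return FertilizerBaseline(n_rate_2010=rates)


def top_fraction_n_share(fertilizer: FertilizerBaseline, domain: GridDomain,
                         fraction: float = 0.1) -> float:
    """Share of total fertilizer N carried by the top ``fraction`` of cells
    ranked by application rate (whole-cell counting)."""
    mass = fertilizer.n_rate_2010 * domain.fertilized_area_ha
    total = mass.sum()
    if total <= 0:
        return 0.0
    order = np.argsort(-fertilizer.n_rate_2010, kind="stable")
    k = max(1, int(round(fraction * domain.n_cells)))
    return float(mass[order[:k]].sum() / total)


# ---------------------------------------------------------------------------
# training table

def emit_training_table(surface: EFSurface, climate_obs: ClimateSeries,
                        soil: SoilProperties, fertilizer: FertilizerBaseline,
                        years=None, seed: int = 0) -> pd.DataFrame:
    """One labelled record per fertilized cell-year.

    Features follow :data:`FEATURE_COLUMNS`; the label ``ef`` is the truth
    surface plus Gaussian noise of sd ``surface.noise_sd``.  Cells with zero
    N rate are excluded.  ``cell_id`` and ``year`` columns are carried for
    bookkeeping but are not features.
    """
    from .climate_ensemble import annual_features  # avoids an import cycle

    if years is None:
        years = climate_obs.years
    years = np.asarray(years, dtype=int)
    fert_mask = fertilizer.n_rate_2010 > 0
    if not fert_mask.any():
        raise EmptyTableError("no fertilized cells in the domain")

    feats = annual_features(climate_obs)
    feats = feats[np.isin(feats["year"].to_numpy(), years)].reset_index(drop=True)
    cells = feats["cell"].to_numpy()
    table = pd.DataFrame({
        "cell_id": cells,
        "year": feats["year"].to_numpy(),
        "n_rate": fertilizer.n_rate_2010[cells],
        "tas": feats["tas"].to_numpy(),
        "precip": feats["precip"].to_numpy(),
        "aridity": feats["aridity"].to_numpy(),
        "soc": soil.soc[cells],
        "ph": soil.ph[cells],
        "bulk_density": soil.bulk_density[cells],
        "sand_frac": soil.sand_frac[cells],
        "clay_frac": soil.clay_frac[cells],
    })
    table = table[table["n_rate"] > 0].reset_index(drop=True)
    label = surface.ef_table(table)
    if surface.noise_sd > 0:
        rng = np.random.default_rng([seed, 4])
        label = label + rng.normal(0.0, surface.noise_sd, size=label.size)
    table["ef"] = label
    return table
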