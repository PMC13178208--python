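"""Shared fixtures: small hand-built domains and session-scoped worlds."""

import numpy as np
import pytest

from n2oproj.config import WorldConfig
from n2oproj.datatypes import FertilizerBaseline, GridDomain, SoilProperties
from n2oproj.pipeline import build_world, train_world_emulator


def make_uniform_domain(n_cells, area_ha=1000.0, ag_frac=0.5, n_countries=1):
    """Equal-area, fully agricultural domain with evenly sized countries."""
    country = np.array([f"C{i % n_countries:02d}" for i in range(n_cells)])
    region_pool = ("USA", "EU", "CHN", "BRA", "SAS", "SEAS", "CAN", "OCE",
                   "RUS", "CAM", "CAS", "EQAF", "KAJ", "MIDE", "NAF", "NSA",
                   "SAF", "SSA")
    region = np.array([region_pool[i % n_countries] for i in
                       [int(c[1:]) for c in country]])
    return GridDomain(
        cell_id=np.arange(n_cells),
        lat=np.zeros(n_cells), lon=np.linspace(-170, 170, n_cells),
        area_ha=np.full(n_cells, area_ha),
        country_id=country, region_id=region,
        cropland_frac=np.full(n_cells, ag_frac),
        pasture_frac=np.zeros(n_cells),
    )


def make_uniform_soil(n_cells, soc=10.0, ph=6.5):
    return SoilProperties(
        ph=np.full(n_cells, ph), soc=np.full(n_cells, soc),
        bulk_density=np.full(n_cells, 1.3),
        sand_frac=np.full(n_cells, 0.4), clay_frac=np.full(n_cells, 0.3),
    )


@pytest.fixture
def uniform_domain():
    return make_uniform_domain(10)


@pytest.fixture
def uniform_fertilizer(uniform_domain):
    return FertilizerBaseline(n_rate_2010=np.full(uniform_domain.n_cells, 100.0))


@pytest.fixture(scope="session")
def constant_world():
    """Constant 1% truth surface, zero noise: the static-limit world."""
    cfg = WorldConfig(seed=2, n_cells=300, n_members=3,
                      surface_params={"constant": 1.0})
    world = build_world(cfg)
    emulator = train_world_emulator(world)
    return world, emulator


@pytest.fixture(scope="session")
def noisy_world():
    """Default-shaped world with EF label noise of 0.3 percentage points.

    Cell count matches the standard toy world; the member count is cut to 2
    because members play no role in emulator training.
    """
    cfg = WorldConfig(seed=11, n_cells=2000, n_members=2, ef_noise_sd=0.3)
    world = build_world(cfg)
    emulator = train_world_emulator(world)
    return world, emulator


@pytest.fixture(scope="session")
def small_run_world():
    """Small world + emulator for full scenario runs (3 members)."""
    cfg = WorldConfig(seed=3, n_cells=400, n_members=3, ef_noise_sd=0.3)
    world = build_world(cfg)
    emulator = train_world_emulator(world)
    return world, emulator
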