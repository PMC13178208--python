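"""End-to-end orchestration: world -> emulator -> scenario projections.

Thin glue over the module operations, shared by the CLI, the tests and the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import climate_ensemble as ce
from . import synthetic_world as sw
from .config import WorldConfig
from .datatypes import ClimateEnsemble, FertilizerBaseline, GridDomain, SoilProperties
from .ef_engine import EFEmulator, train_emulator
from .projection_core import ScenarioProjection, project_scenario
from .scenario_fertilizer import SCENARIO_IDS, build_scenario_field, default_scenario


@dataclass
class World:
    """A fully generated synthetic world (historical side only)."""

    config: WorldConfig
    domain: GridDomain
    soil: SoilProperties
    hist_climate: ClimateEnsemble
    surface: sw.EFSurface
    baseline: FertilizerBaseline
    training_table: pd.DataFrame


def build_world(config: WorldConfig) -> World:
    """Generate domain, soil, historical climate, calibrated truth surface,
    baseline fertilizer and the emulator training table."""
    seed = config.seed
    domain = sw.generate_domain(config.n_cells, config.n_countries, seed)
    soil = sw.generate_soil(domain, seed)
    hist = sw.generate_climate(domain, list(config.hist_years), "HIST",
                               n_members=config.n_members,
                               bias_sd=config.bias_sd,
                               noise_sd=config.climate_noise_sd, seed=seed)
    baseline = sw.generate_baseline_fertilizer(
        domain, config.mean_n_rate, config.fertilizer_skew, seed)

    params = dict(config.surface_params)
    params.setdefault("noise_sd", config.ef_noise_sd)
    if params.get("constant") is not None:
        surface = sw.generate_true_ef_surface(params, seed)
    else:
        # calibrate on the 2010 observed world, fertilized-area weighted
        feats_2010 = ce.feature_table(
            hist.obs, soil, baseline.n_rate_2010[None, :].repeat(1, axis=0),
            years=np.array([2010]))
        feats_2010 = feats_2010[feats_2010["n_rate"] > 0]
        weights = domain.fertilized_area_ha[feats_2010["cell_id"].to_numpy()]
        surface = sw.generate_true_ef_surface(
            params, seed, calibrate_features=feats_2010,
            calibrate_weights=weights, target_window=config.ef_target_window)

    table = sw.emit_training_table(surface, hist.obs, soil, baseline,
                                   years=list(config.hist_years), seed=seed)
    return World(config=config, domain=domain, soil=soil, hist_climate=hist,
                 surface=surface, baseline=baseline, training_table=table)


def train_world_emulator(world: World, hyperparams: dict | None = None) -> EFEmulator:
    cfg = world.config
    return train_emulator(world.training_table, hyperparams, seed=cfg.seed,
                          rmse_ceiling=cfg.rmse_ceiling, ef_max=cfg.ef_max)


def scenario_climate(world: World, pathway: str) -> list:
    """Bias-corrected projection members for one pathway."""
    cfg = world.config
    future = sw.generate_climate(world.domain, list(cfg.proj_years), pathway,
                                 n_members=cfg.n_members, bias_sd=cfg.bias_sd,
                                 noise_sd=cfg.climate_noise_sd, seed=cfg.seed)
    return ce.correct_ensemble(future.members, world.hist_climate.members,
                               world.hist_climate.obs, cfg.reference_period)


def run_scenario(world: World, emulator: EFEmulator, scenario_id: str, *,
                 keep_cells: bool = True,
                 corrected_members=None) -> ScenarioProjection:
    """Build scenario fertilizer, bias-correct its climate members and project."""
    scenario = default_scenario(scenario_id, world.domain)
    fert = build_scenario_field(scenario, world.domain, world.baseline,
                                list(world.config.proj_years))
    if corrected_members is None:
        corrected_members = scenario_climate(world, scenario.climate_pathway)
    return project_scenario(scenario, emulator, corrected_members, fert,
                            world.domain, world.soil, keep_cells=keep_cells)


def run_all_scenarios(world: World, emulator: EFEmulator, *,
                      scenario_ids=SCENARIO_IDS, keep_cells: bool = False
                      ) -> dict[str, ScenarioProjection]:
    """Project every scenario, reusing corrected climate per pathway."""
    by_pathway: dict[str, list] = {}
    out = {}
    for sid in scenario_ids:
        pathway = default_scenario(sid, world.domain).climate_pathway
        if pathway not in by_pathway:
            by_pathway[pathway] = scenario_climate(world, pathway)
        out[sid] = run_scenario(world, emulator, sid, keep_cells=keep_cells,
                                corrected_members=by_pathway[pathway])
    return out
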