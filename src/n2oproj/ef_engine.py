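"""Emission-factor emulator and emission computation.

A seeded tree-ensemble regressor learns EF (percent of applied N emitted
as N2O-N) from the shared feature schema; predictions are clipped to
[0, ef_max].  Emissions are EF/100 x N rate x fertilized area, with the
static path using EF = 1.0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import train_test_split

from .datatypes import GridDomain
from .errors import DataError, InvalidArgumentError, SchemaError
from .synthetic_world import FEATURE_COLUMNS, EFSurface

MIN_TRAINING_RECORDS = 500
DEFAULT_EF_MAX = 25.0          # percent; generous extrapolation cap
DEFAULT_RMSE_CEILING = 1.0     # EF percentage points

SERIAL_FORMAT_VERSION = 1

STATIC_EF_PERCENT = 1.0        # Tier-1 fixed emission factor


@dataclass
class EFEmulator:
    """Fitted EF regressor plus its schema and training metadata.

    Parameters
    ----------
    model : fitted scikit-learn regressor.
    feature_names : ordered schema the model was trained on.
    holdout_rmse : RMSE on the 20% held-out split, EF percentage points.
    n_records, seed : training provenance.
    ef_max : upper clip bound for predictions (lower bound is 0).
    """

    model: object
    feature_names: tuple[str, ...]
    holdout_rmse: float
    n_records: int
    seed: int
    ef_max: float = DEFAULT_EF_MAX

    def predict(self, feature_table: pd.DataFrame) -> np.ndarray:
        return predict_ef(self, feature_table)

    def save(self, path) -> None:
        joblib.dump({"format_version": SERIAL_FORMAT_VERSION,
                     "emulator": self}, path)

    @classmethod
    def load(cls, path) -> "EFEmulator":
        payload = joblib.load(path)
        if payload.get("format_version") != SERIAL_FORMAT_VERSION:
            raise DataError("unsupported emulator file version")
        return payload["emulator"]


def _check_schema(table: pd.DataFrame, feature_names) -> pd.DataFrame:
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise SchemaError(f"missing feature columns: {missing}")
    X = table.loc[:, list(feature_names)]
    if X.isna().any().any():
        raise SchemaError("feature table contains missing values")
    return X


def _make_regressor(hyperparams: dict | None, seed: int):
    hp = dict(hyperparams or {})
    family = hp.pop("model", "hist_gbm")
    if family == "hist_gbm":
        hp.setdefault("max_iter", 300)
        hp.setdefault("learning_rate", 0.08)
        hp.setdefault("min_samples_leaf", 10)
        return HistGradientBoostingRegressor(random_state=seed, **hp)
    if family == "random_forest":
        hp.setdefault("n_estimators", 200)
        hp.setdefault("n_jobs", 1)
        return RandomForestRegressor(random_state=seed, **hp)
    raise InvalidArgumentError(f"unknown regressor family {family!r}")


def train_emulator(training_table: pd.DataFrame, hyperparams: dict | None = None,
                   seed: int = 0, *, rmse_ceiling: float = DEFAULT_RMSE_CEILING,
                   test_size: float = 0.2, ef_max: float = DEFAULT_EF_MAX,
                   ) -> EFEmulator:
    """Fit the EF emulator on a labelled training table.

    A 20% held-out split measures generalization; training refuses to
    return an emulator whose held-out RMSE exceeds ``rmse_ceiling``.
    Deterministic for a fixed (table, hyperparams, seed).
    """
    if len(training_table) < MIN_TRAINING_RECORDS:
        raise DataError(
            f"need >= {MIN_TRAINING_RECORDS} records, got {len(training_table)}")
    if "ef" not in training_table.columns:
        raise SchemaError("training table lacks an 'ef' label column")
    X = _check_schema(training_table, FEATURE_COLUMNS)
    y = training_table["ef"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise SchemaError("labels contain missing values")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X.to_numpy(dtype=float), y, test_size=test_size, random_state=seed)
    model = _make_regressor(hyperparams, seed)
    model.fit(X_tr, y_tr)
    rmse = float(np.sqrt(mean_squared_error(y_te, model.predict(X_te))))
    if rmse > rmse_ceiling:
        raise DataError(
            f"held-out RMSE {rmse:.3f} exceeds ceiling {rmse_ceiling:.3f}")
    return EFEmulator(model=model, feature_names=FEATURE_COLUMNS,
                      holdout_rmse=rmse, n_records=len(training_table),
                      seed=seed, ef_max=ef_max)


def predict_ef(emulator: EFEmulator, feature_table: pd.DataFrame) -> np.ndarray:
    """Predicted EF percent per row, clipped to [0, ef_max]."""
    if len(feature_table) == 0:
        return np.empty(0)
    X = _check_schema(feature_table, emulator.feature_names)
    pred = emulator.model.predict(X.to_numpy(dtype=float))
    return np.clip(pred, 0.0, emulator.ef_max)


# ---------------------------------------------------------------------------
# emissions

@dataclass(frozen=True)
class EmissionField:
    """Per-cell emissions for one method/scenario/member.

    ``cell_tg`` is N2O-N in Tg per cell (last axis = cells; leading axes,
    if any, are years).  ``rate_g_m2`` is the emission rate per unit
    fertilized area.
    """

    cell_tg: np.ndarray
    rate_g_m2: np.ndarray
    method: str                      # "dynamic" | "static"
    scenario_id: str | None = None
    member_id: str | None = None

    def global_total(self) -> np.ndarray | float:
        total = self.cell_tg.sum(axis=-1)
        return float(total) if np.ndim(total) == 0 else total


def compute_emissions(ef_percent, n_rate, domain: GridDomain, *,
                      method: str = "dynamic", scenario_id: str | None = None,
                      member_id: str | None = None) -> EmissionField:
    """Cellwise N2O-N emissions from EF (percent) and N rate (kg N/ha).

    emission_kg = EF/100 x n_rate x fertilized_area_ha;
    rate_g_m2  = EF/100 x n_rate x 0.1  (kg/ha -> g/m2).
    Broadcasts over leading axes (e.g. years).
    """
    n_rate = np.asarray(n_rate, dtype=float)
    if np.any(n_rate < 0):
        raise InvalidArgumentError("fertilizer rates must be >= 0")
    ef = np.broadcast_to(np.asarray(ef_percent, dtype=float), n_rate.shape)
    if np.any(ef < 0):
        raise InvalidArgumentError("EF must be >= 0")
    kg = ef / 100.0 * n_rate * domain.fertilized_area_ha
    return EmissionField(cell_tg=kg * 1e-9,
                         rate_g_m2=ef / 100.0 * n_rate * 0.1,
                         method=method, scenario_id=scenario_id,
                         member_id=member_id)


def static_emissions(n_rate, domain: GridDomain, *, scenario_id=None) -> EmissionField:
    """Tier-1 fixed-EF emissions: EF = 1.0 percent exactly."""
    return compute_emissions(STATIC_EF_PERCENT, n_rate, domain,
                             method="static", scenario_id=scenario_id)


# ---------------------------------------------------------------------------
# validation against the truth surface

def validate_against_truth(emulator: EFEmulator, surface: EFSurface,
                           probe_grid: pd.DataFrame, n_bins: int = 10,
                           csv_path=None) -> pd.DataFrame:
    """RMSE of emulator vs truth along binned aridity and SOC gradients.

    Returns a report with rows for each (gradient, bin) plus a pooled row
    per gradient; optionally written as CSV.
    """
    truth = surface.ef_table(probe_grid)
    pred = predict_ef(emulator, probe_grid)
    err = pred - truth
    rows = []
    for gradient in ("aridity", "soc"):
        vals = probe_grid[gradient].to_numpy(dtype=float)
        edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        idx = np.clip(np.searchsorted(edges, vals, side="right") - 1,
                      0, len(edges) - 2)
        for b in range(len(edges) - 1):
            sel = idx == b
            if not sel.any():
                continue
            rows.append({"gradient": gradient, "bin": b,
                         "bin_low": edges[b], "bin_high": edges[b + 1],
                         "n": int(sel.sum()),
                         "rmse": float(np.sqrt(np.mean(err[sel] ** 2)))})
        rows.append({"gradient": gradient, "bin": -1,
                     "bin_low": vals.min(), "bin_high": vals.max(),
                     "n": int(err.size),
                     "rmse": float(np.sqrt(np.mean(err ** 2)))})
    report = pd.DataFrame(rows)
    if csv_path is not None:
        report.to_csv(csv_path, index=False)
    return report


def gradient_rmse(report: pd.DataFrame, gradient: str) -> float:
    """Mean of the per-bin RMSEs along one gradient (pooled row excluded)."""
    sel = report[(report["gradient"] == gradient) & (report["bin"] >= 0)]
    if sel.empty:
        raise InvalidArgumentError(f"no bins for gradient {gradient!r}")
    return float(sel["rmse"].mean())
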