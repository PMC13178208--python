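"""Run configuration: a flat dataclass round-tripped through YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidArgumentError


@dataclass
class WorldConfig:
    """Knobs for the synthetic world and the projection run.

    Defaults give the standard toy world: 2000 cells, 18 countries (one
    per region), 37 members, years 1990-2050.
    """

    seed: int = 0
    n_cells: int = 2000
    n_countries: int = 18
    hist_start: int = 1990
    hist_end: int = 2020
    proj_start: int = 2010
    proj_end: int = 2050
    n_members: int = 37
    bias_sd: float = 0.6
    climate_noise_sd: float = 0.5
    mean_n_rate: float = 80.0
    fertilizer_skew: float = 1.25
    surface_params: dict = field(default_factory=dict)
    ef_noise_sd: float = 0.0
    ef_target_window: tuple[float, float] = (1.18, 1.22)
    reference_period: tuple[int, int] = (1995, 2014)
    rmse_ceiling: float = 1.0
    ef_max: float = 25.0
    ni_efficiency: float = 0.34
    gwp100: float = 265.0

    def __post_init__(self) -> None:
        if self.n_cells < self.n_countries:
            raise InvalidArgumentError("n_cells must be >= n_countries")
        if self.hist_start > self.hist_end or self.proj_start > self.proj_end:
            raise InvalidArgumentError("year ranges are inverted")

    @property
    def hist_years(self) -> range:
        return range(self.hist_start, self.hist_end + 1)

    @property
    def proj_years(self) -> range:
        return range(self.proj_start, self.proj_end + 1)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["ef_target_window"] = list(self.ef_target_window)
        d["reference_period"] = list(self.reference_period)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("ef_target_window", "reference_period"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
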