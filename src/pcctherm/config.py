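"""Run configuration: one YAML document drives the full pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import EnergyBinning, PhantomGeometry
from .network import (
    DEFAULT_N_PER_MATERIAL,
    DEFAULT_NOISE_SD_REL,
    DEFAULT_T_RANGE,
    RegressorSpec,
)
from .synthetic import DEFAULT_FLUX_PER_BIN, SensitivityLaw


@dataclass
class RunConfig:
    """Geometry, binning, generator, regressor and seed settings.

    Every stochastic stage has its own explicit seed so any output can be
    reproduced bit-for-bit from the config alone.
    """

    geometry: PhantomGeometry = field(
        default_factory=PhantomGeometry.self_consistent)
    binning: EnergyBinning = field(default_factory=EnergyBinning)
    law: SensitivityLaw = field(default_factory=SensitivityLaw)
    regressor: RegressorSpec = field(default_factory=RegressorSpec)
    n_per_material: int = DEFAULT_N_PER_MATERIAL
    t_range: tuple[float, float] = DEFAULT_T_RANGE
    noise_sd_rel: float = DEFAULT_NOISE_SD_REL
    flux_per_bin: tuple[float, ...] = tuple(DEFAULT_FLUX_PER_BIN)
    projection_noise: bool = True
    seed_training: int = 0
    seed_scene: int = 0
    seed_test_materials: int = 0
    n_ci_draws: int = 1000

    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple, np.ndarray)):
                return [plain(v) for v in x]
            if isinstance(x, np.generic):
                return x.item()
            return x

        return plain(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "geometry" in d:
            g = dict(d["geometry"])
            g["detector_shape"] = tuple(g["detector_shape"])
            d["geometry"] = PhantomGeometry(**g)
        if "binning" in d:
            d["binning"] = EnergyBinning(tuple(d["binning"]["edges_kev"]))
        if "law" in d:
            law = dict(d["law"])
            law["water_slope_per_bin"] = tuple(law["water_slope_per_bin"])
            d["law"] = SensitivityLaw(**law)
        if "regressor" in d:
            spec = dict(d["regressor"])
            spec["layer_sizes"] = tuple(spec["layer_sizes"])
            d["regressor"] = RegressorSpec(**spec)
        if "t_range" in d:
            d["t_range"] = tuple(d["t_range"])
        if "flux_per_bin" in d:
            d["flux_per_bin"] = tuple(d["flux_per_bin"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        """Stable digest of the full configuration, for run provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
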