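"""YAML run configuration with strict schema validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import yaml

from .geometry import AcquisitionGeometry
from .reconstruct import TileLayout
from .screens import NoiseSpec, ScreenSpec
from .solver import SolverConfig

__all__ = ["RunConfig", "load_config"]

_GEOMETRY_KEYS = {"wavelength", "numerical_aperture", "sample_pixel_pitch",
                  "scan_step", "scan_shape", "detection_extent",
                  "conjugate_distance", "medium_index"}
_SOLVER_KEYS = {"max_iterations", "tolerance", "reference", "amplitude_weighting"}
_TILING_KEYS = {"tile_size", "overlap"}
_SIM_KEYS = {"object_kind", "object_params", "screen", "noise", "model", "basis"}
_SCREEN_KEYS = {"rms_phase", "correlation_length", "seed"}
_NOISE_KEYS = {"multiple_scattering_power_ratio", "seed"}
_TOP_KEYS = {"geometry", "solver", "tiling", "simulation", "seed", "output"}


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated configuration for a simulate/correct/reconstruct run."""

    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    solver: SolverConfig = field(default_factory=SolverConfig)
    tiling: Optional[TileLayout] = None
    simulation: Dict = field(default_factory=dict)
    seed: int = 0
    output: Optional[str] = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys(raw, _TOP_KEYS, "config")
        geo_block = dict(raw.get("geometry", {}))
        _check_keys(geo_block, _GEOMETRY_KEYS, "geometry")
        if "scan_shape" in geo_block:
            geo_block["scan_shape"] = tuple(geo_block["scan_shape"])
        geometry = AcquisitionGeometry(**geo_block)

        sol_block = dict(raw.get("solver", {}))
        _check_keys(sol_block, _SOLVER_KEYS, "solver")
        solver = SolverConfig(**sol_block)

        tiling = None
        if "tiling" in raw:
            tile_block = dict(raw["tiling"])
            _check_keys(tile_block, _TILING_KEYS, "tiling")
            tiling = TileLayout(**tile_block)

        seed = int(raw.get("seed", 0))
        sim_block = dict(raw.get("simulation", {}))
        _check_keys(sim_block, _SIM_KEYS, "simulation")
        if "screen" in sim_block and sim_block["screen"] is not None:
            sb = dict(sim_block["screen"])
            _check_keys(sb, _SCREEN_KEYS, "simulation.screen")
            sb.setdefault("seed", seed)
            sim_block["screen"] = ScreenSpec(**sb)
        if "noise" in sim_block and sim_block["noise"] is not None:
            nb = dict(sim_block["noise"])
            _check_keys(nb, _NOISE_KEYS, "simulation.noise")
            nb.setdefault("seed", seed + 1)
            sim_block["noise"] = NoiseSpec(**nb)

        return cls(geometry=geometry, solver=solver, tiling=tiling,
                   simulation=sim_block, seed=seed,
                   output=raw.get("output"))


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.from_dict(raw)
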