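"""Plain-text run configuration.

A config file is a flat ``key = value`` dialect (one assignment per line,
``#`` comments, blank lines ignored). Unknown keys are rejected so typos
cannot silently fall back to defaults. All defaults trace to the measured
study values where one exists: viscosities 1.5 / 7.35 cP, density
1.025 kg/L, 25 frames per 0.25 s cycle, groove dimension statistics
12.5+-3.1 / 8.7+-0.8 / 21.7+-10.7 um.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .geometry import GeometryParams, MotionModel
from .stokes import FluidProperties

__all__ = ["RunConfig", "ConfigError", "read_config", "write_config"]

_VISCOSITY_PRESETS = {"plasma": 1.5e-3, "blood": 7.35e-3}


class ConfigError(ValueError):
    """Bad configuration file or value."""


@dataclass
class RunConfig:
    """Flat bag of every generator / solver / scenario parameter."""

    # geometry (um)
    inner_diameter: float = 40.0
    groove_long: float = 12.5
    groove_long_sd: float = 3.1
    groove_radial: float = 8.7
    groove_radial_sd: float = 0.8
    groove_circ: float = 21.7
    groove_circ_sd: float = 10.7
    n_grooves: int = 3
    endocardial_thickness: float = 5.0
    cell_diameter: float = 7.0
    inlet_width: float = 8.0
    outlet_width: float = 8.0
    curvature_ratio: float = 0.6
    node_spacing: float = 1.0
    groove_squeeze: float = 0.35
    # motion
    cycle_duration: float = 0.25
    n_frames: int = 25
    max_rotation: float = 0.03
    systole_end: float = 0.36
    translation_amplitude: float = 4.0
    # fluid / solver
    viscosity: str | float = "plasma"
    density: float = 1025.0
    resolution: float = 1.0
    # run
    seed: int = 0
    outdir: str = "trabflow_out"
    # units are fixed package-wide; declared for the manifest
    length_unit: str = "um"
    time_unit: str = "s"
    stress_unit: str = "Pa"

    def geometry_params(self) -> GeometryParams:
        names = {f.name for f in fields(GeometryParams)}
        kw = {k: v for k, v in asdict(self).items() if k in names}
        p = GeometryParams(**kw)
        p.validate()
        return p

    def motion_model(self) -> MotionModel:
        from functools import partial
        from .geometry import default_translation_waveform, default_volume_waveform
        m = MotionModel(
            cycle_duration=self.cycle_duration,
            n_frames=self.n_frames,
            max_rotation=self.max_rotation,
            systole_end=self.systole_end,
            volume_waveform=partial(default_volume_waveform,
                                    systole_end=self.systole_end),
            translation_waveform=partial(default_translation_waveform,
                                         amplitude=self.translation_amplitude,
                                         systole_end=self.systole_end),
        )
        m.validate()
        return m

    def fluid(self) -> FluidProperties:
        mu = _VISCOSITY_PRESETS.get(self.viscosity, self.viscosity) \
            if isinstance(self.viscosity, str) else self.viscosity
        if not isinstance(mu, (int, float)):
            raise ConfigError(f"unknown viscosity preset '{self.viscosity}'")
        if mu <= 0:
            raise ConfigError("viscosity must be > 0")
        return FluidProperties(viscosity=float(mu), density=self.density)

    def validate(self) -> None:
        self.geometry_params()
        self.motion_model()
        self.fluid()
        if self.resolution <= 0:
            raise ConfigError("resolution must be > 0")

    def hash(self) -> str:
        """Reproducible content hash of the configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_config(path) -> RunConfig:
    """Parse and validate a key=value config file; missing keys take their
    defaults, unknown keys raise naming the key."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    known = {f.name: f for f in fields(RunConfig)}
    values: dict = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ConfigError(f"{path}:{lineno}: unknown key '{key}'")
        values[key] = _coerce(val, known[key].type, key)
    cfg = RunConfig(**values)
    try:
        cfg.validate()
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def _coerce(val: str, annot, key: str):
    if annot == "int":
        try:
            return int(val)
        except ValueError as exc:
            raise ConfigError(f"key '{key}': expected integer, got '{val}'") from exc
    if annot == "float":
        try:
            return float(val)
        except ValueError as exc:
            raise ConfigError(f"key '{key}': expected number, got '{val}'") from exc
    if annot == "str | float":
        try:
            return float(val)
        except ValueError:
            return val
    return val


def write_config(cfg: RunConfig, path) -> Path:
    """Serialize a config so that ``read_config`` round-trips it."""
    path = Path(path)
    lines = [f"{k} = {v}" for k, v in asdict(cfg).items()]
    path.write_text("\n".join(lines) + "\n")
    return path
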