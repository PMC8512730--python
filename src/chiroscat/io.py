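"""Configuration files, geometry exchange, and result tables.

Configs are YAML with explicit units in key names (``_nm``, ``_rad``,
``_deg``); unknown keys are rejected with their full key path.  Geometry
files are plain text, one integer lattice triple per line, with a
'#'-commented header recording spacing, origin, refractive indices -- the
ADDA dipole-file layout, with a DDSCAT-style variant behind a flag.  All
writers are deterministic ('.' decimal, fixed column order); all readers
reject malformed input rather than coercing it.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .geometry import DipoleModel, NucleosomeShape, SolenoidSpec

__all__ = ["RunConfig", "read_config", "write_config", "write_geometry", "read_geometry"]

_HANDEDNESS = {"right": 1, "left": -1, 1: 1, -1: -1}

_GEOMETRY_DEFAULTS = {
    "radius_nm": 10.0,
    "pitch_nm": 11.0,
    "handedness": "right",
    "turns": 1,
    "nucleosomes_per_turn": 6,
    "shape": "cylinder",
    "diameter_nm": 11.0,
    "height_nm": 5.5,
    "orientation_mode": "radial",
    "phase0_rad": 0.0,
    "tilt_rad": 0.0,
}
_OPTICS_DEFAULTS = {"wavelength_nm": 300.0, "n_particle": 1.68, "n_host": 1.33}
_DISCRETIZATION_DEFAULTS = {"dipoles_per_longest": 60}
_OBSERVABLE_DEFAULTS = {
    "mode": "fixed",
    "theta_step_deg": 1.0,
    "tol": 1e-5,
    "n_alpha": 8,
    "n_beta": 8,
    "n_gamma": 4,
}
_SWEEP_DEFAULTS = {"kind": None, "values": None}
_OUTPUT_DEFAULTS = {"path": None}

_SCHEMA = {
    "geometry": _GEOMETRY_DEFAULTS,
    "optics": _OPTICS_DEFAULTS,
    "discretization": _DISCRETIZATION_DEFAULTS,
    "observable": _OBSERVABLE_DEFAULTS,
    "sweep": _SWEEP_DEFAULTS,
    "output": _OUTPUT_DEFAULTS,
}


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled.

    The default configuration is the standard chromatin solenoid: one
    right-handed turn, R = 10 nm, P = 11 nm, six cylindrical nucleosomes
    (11 x 5.5 nm) per turn, n = 1.68 in water (1.33), lambda = 300 nm,
    60 dipoles across the longest dimension.
    """

    geometry: dict = field(default_factory=lambda: dict(_GEOMETRY_DEFAULTS))
    optics: dict = field(default_factory=lambda: dict(_OPTICS_DEFAULTS))
    discretization: dict = field(default_factory=lambda: dict(_DISCRETIZATION_DEFAULTS))
    observable: dict = field(default_factory=lambda: dict(_OBSERVABLE_DEFAULTS))
    sweep: dict = field(default_factory=lambda: dict(_SWEEP_DEFAULTS))
    output: dict = field(default_factory=lambda: dict(_OUTPUT_DEFAULTS))

    def solenoid_spec(self) -> SolenoidSpec:
        g = self.geometry
        shape = NucleosomeShape(
            kind=g["shape"],
            diameter=float(g["diameter_nm"]),
            height=float(g["height_nm"]),
        )
        return SolenoidSpec(
            radius=float(g["radius_nm"]),
            pitch=float(g["pitch_nm"]),
            handedness=_HANDEDNESS[g["handedness"]],
            turns=int(g["turns"]),
            nucleosomes_per_turn=int(g["nucleosomes_per_turn"]),
            phase0=float(g["phase0_rad"]),
            orientation_mode=g["orientation_mode"],
            tilt=float(g["tilt_rad"]),
            shape=shape,
        )

    @property
    def rel_index(self) -> complex:
        return complex(self.optics["n_particle"]) / self.optics["n_host"]

    def as_dict(self) -> dict:
        return {k: dict(v) for k, v in asdict(self).items()}


def _validate_block(name: str, given: dict, defaults: dict) -> dict:
    unknown = sorted(set(given) - set(defaults))
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(f'{name}.{k}' for k in unknown)}")
    merged = dict(defaults)
    merged.update(given)
    return merged


def read_config(path) -> RunConfig:
    """Read and validate a YAML run configuration; empty files yield the
    full default (standard solenoid) configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = sorted(set(data) - set(_SCHEMA))
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    blocks = {}
    for name, defaults in _SCHEMA.items():
        given = data.get(name, {}) or {}
        if not isinstance(given, dict):
            raise ValueError(f"config block {name!r} must be a mapping")
        blocks[name] = _validate_block(name, given, defaults)
    cfg = RunConfig(**blocks)
    if cfg.geometry["handedness"] not in _HANDEDNESS:
        raise ValueError(f"geometry.handedness must be 'right' or 'left', got {cfg.geometry['handedness']!r}")
    cfg.solenoid_spec()  # trips geometry validation early
    return cfg


def write_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# Geometry files


def write_geometry(model: DipoleModel, path, dialect: str = "adda") -> None:
    """Write a dipole model as plain text, one site per line.

    ``adda``: '#'-commented header with spacing, origin and indices, then
    bare ``i j k`` integer triples.  ``ddscat``: a DDSCAT shape.dat-style
    layout (site counter then ``ix iy iz 1 1 1``) after the same header.
    """
    if dialect not in ("adda", "ddscat"):
        raise ValueError(f"dialect must be 'adda' or 'ddscat', got {dialect!r}")
    m = np.atleast_1d(np.asarray(model.rel_index, dtype=complex))
    if m.size != 1:
        raise ValueError("geometry files support a uniform refractive index only")
    lines = [
        "#chiroscat dipole geometry",
        f"#dialect: {dialect}",
        f"#spacing_nm: {float(model.spacing)!r}",
        f"#origin_nm: {float(model.origin[0])!r} {float(model.origin[1])!r} {float(model.origin[2])!r}",
        f"#rel_index: {float(m[0].real)!r} {float(m[0].imag)!r}",
        f"#host_index: {float(model.host_index)!r}",
        f"#n_dipoles: {model.n_dipoles}",
    ]
    if dialect == "adda":
        lines += [f"{i} {j} {k}" for i, j, k in model.sites]
    else:
        lines.append(f"#NAT = {model.n_dipoles}")
        lines += [f"{a + 1} {i} {j} {k} 1 1 1" for a, (i, j, k) in enumerate(model.sites)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_geometry(path) -> DipoleModel:
    """Read a geometry file written by :func:`write_geometry`.

    The round trip reproduces sites, spacing and origin exactly.  Malformed
    lines are reported with their line number.
    """
    header: dict[str, str] = {}
    sites = []
    dialect = "adda"
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
            continue
        parts = line.split()
        try:
            if header.get("dialect", "adda") == "ddscat":
                if len(parts) != 7:
                    raise ValueError("expected 7 fields")
                sites.append([int(parts[1]), int(parts[2]), int(parts[3])])
            else:
                if len(parts) != 3:
                    raise ValueError("expected 3 fields")
                sites.append([int(p) for p in parts])
        except ValueError as err:
            raise ValueError(f"{path}: malformed geometry line {lineno}: {raw!r} ({err})") from None
    dialect = header.get("dialect", "adda")
    try:
        spacing = float(header["spacing_nm"])
        origin = np.array([float(x) for x in header["origin_nm"].split()])
        re_m, im_m = (float(x) for x in header["rel_index"].split())
        host = float(header["host_index"])
    except KeyError as err:
        raise ValueError(f"{path}: geometry header is missing key {err}") from None
    model = DipoleModel(
        spacing=spacing, origin=origin, sites=np.array(sites, dtype=np.int64),
        rel_index=complex(re_m, im_m), host_index=host,
    )
    declared = header.get("n_dipoles")
    if declared is not None and int(declared) != model.n_dipoles:
        raise ValueError(
            f"{path}: header declares {declared} dipoles but file contains {model.n_dipoles}"
        )
    return model
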