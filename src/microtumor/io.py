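"""Plain-text serialization: lattice fields as CSV with a JSON sidecar.

A saved simulation is three CSV matrices (``N.csv``, ``D.csv``,
``RN.csv``) plus ``meta.json`` carrying the lattice config, kinetic
parameters, integration controls and seeds.  Floats are written with 17
significant digits so the round trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .lattice import CellField, KineticParams, LatticeConfig

__all__ = [
    "save_field",
    "load_field",
    "save_pattern_json",
    "load_config",
    "UnknownConfigKeyError",
]

_FLOAT_FMT = "%.17g"


class UnknownConfigKeyError(ValueError):
    """Configuration file contains keys the package does not understand."""


def save_field(
    directory: str | Path,
    field: CellField,
    config: LatticeConfig,
    params: KineticParams,
    seed: int | None = None,
    extra: dict | None = None,
) -> dict[str, Path]:
    """Write N/D/R_N CSV matrices and the JSON sidecar; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, grid in (("N", field.N), ("D", field.D), ("RN", field.R_N_cell)):
        p = directory / f"{name}.csv"
        np.savetxt(p, grid, delimiter=",", fmt=_FLOAT_FMT)
        paths[name] = p
    meta = {
        "config": dataclasses.asdict(config),
        "params": dataclasses.asdict(params),
        "seed": seed,
    }
    if extra:
        meta.update(extra)
    sidecar = directory / "meta.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    paths["meta"] = sidecar
    return paths


def load_field(directory: str | Path) -> tuple[CellField, LatticeConfig, KineticParams, dict]:
    """Round-trip reader for :func:`save_field` output."""
    directory = Path(directory)
    grids = {
        name: np.loadtxt(directory / f"{name}.csv", delimiter=",", ndmin=2)
        for name in ("N", "D", "RN")
    }
    meta = json.loads((directory / "meta.json").read_text())
    config = LatticeConfig(**meta["config"])
    params = KineticParams(**meta["params"])
    field = CellField(grids["N"], grids["D"], grids["RN"])
    return field, config, params, meta


def save_pattern_json(path: str | Path, summary) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary.to_dict(), indent=2))
    return path


_CONFIG_SECTIONS = {
    "lattice": {"rows", "cols", "w1", "w2", "periodic"},
    "kinetics": {"R_D", "gamma_N", "gamma_D", "k_cis", "K_act", "h_act",
                 "K_rep", "h_rep"},
    "integration": {"dt", "tol", "max_steps"},
    "heterogeneity": {"R_N_mean", "sigma", "mode", "contrast", "fraction_high",
                      "aggregated", "seed"},
    "sweep": {"r_axis", "sigma_axis", "replicates"},
}


def load_config(path: str | Path) -> dict:
    """Parse and validate a YAML run configuration.

    Unknown sections or keys are an error that names them, so a typo in a
    config cannot silently fall back to a default.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise UnknownConfigKeyError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = []
    for section, content in raw.items():
        if section not in _CONFIG_SECTIONS:
            unknown.append(section)
            continue
        if content is None:
            continue
        if not isinstance(content, dict):
            raise UnknownConfigKeyError(f"section {section!r} must be a mapping")
        for key in content:
            if key not in _CONFIG_SECTIONS[section]:
                unknown.append(f"{section}.{key}")
    if unknown:
        raise UnknownConfigKeyError(f"unknown configuration keys: {sorted(unknown)}")
    return raw
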