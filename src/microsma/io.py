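"""Configuration, result serialisation and seeded fixture generation.

The canonical config dialect is JSON (YAML is accepted for convenience);
the only result format is CSV.  Config validation is strict: unknown keys
are rejected with the offending key named, and every block is validated
against its owning module's invariants before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .driver import LoadPath, PathResult, StressPoint
from .material import MaterialParams, default_niti
from .scenarios import GeometryMap, ScenarioSpec

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_config",
    "write_path_csv",
    "read_path_csv",
    "generate_random_fixture",
    "PATH_CSV_COLUMNS",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


#: Exact result-CSV schema: one row per step, strain shears reported as
#: tensor (not engineering) components; e## is the total strain and
#: etr## the transformation part.
PATH_CSV_COLUMNS = [
    "step", "T_C",
    "s11", "s22", "s33", "s12", "s13", "s23",
    "sigma_eff_MPa", "xi",
    "e11", "e22", "e33", "e12", "e13", "e23",
    "etr11", "etr22", "etr33", "etr12", "etr13", "etr23",
    "vm_MPa", "max_principal_strain",
]

_TENSOR_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass(frozen=True)
class RunConfig:
    """A fully validated run: material + scenario + quadrature + output."""

    material: MaterialParams
    scenario: ScenarioSpec
    quadrature_scheme: str = "bazant_oh_42"
    quadrature_resolution: tuple[int, int] | None = None
    output_path: str = "result.csv"
    output_format: str = "csv"
    seed: int = 0
    log_level: str = "INFO"

    def params_hash(self) -> str:
        blob = json.dumps(self.material.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _require_keys(block: dict, allowed: set[str], context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")


def _parse_scenario(block: dict) -> ScenarioSpec:
    allowed = {
        "name", "force", "torque", "temperature", "geometry", "steps",
        "recovery_temperature",
    }
    _require_keys(block, allowed, "scenario block")
    if "name" not in block:
        raise ConfigError("scenario block requires a 'name'")
    geometry = GeometryMap()
    if "geometry" in block:
        geom = block["geometry"]
        _require_keys(geom, {"area", "shear_modulus_factor"}, "scenario.geometry block")
        geometry = GeometryMap(
            area=float(geom.get("area", geometry.area)),
            shear_factor=float(geom.get("shear_modulus_factor", geometry.shear_factor)),
        )
    kwargs = {k: v for k, v in block.items() if k not in ("geometry",)}
    try:
        return ScenarioSpec(geometry=geometry, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid scenario block: {exc}") from exc


def read_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON (canonical) or YAML run configuration.

    Raises :class:`ConfigError` naming the offending key or constraint on
    any problem.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path.name}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")

    allowed = {"material", "scenario", "quadrature", "output", "seed", "log_level"}
    _require_keys(data, allowed, "config")
    if "scenario" not in data:
        raise ConfigError("config requires a 'scenario' block")

    try:
        material = (
            MaterialParams.from_dict(data["material"])
            if "material" in data
            else default_niti()
        )
    except ValueError as exc:
        raise ConfigError(f"invalid material block: {exc}") from exc

    scenario = _parse_scenario(data["scenario"])

    scheme, resolution = "bazant_oh_42", None
    if "quadrature" in data:
        q = data["quadrature"]
        _require_keys(q, {"scheme", "resolution"}, "quadrature block")
        scheme = q.get("scheme", scheme)
        if scheme not in ("bazant_oh_42", "dense_grid"):
            raise ConfigError(f"unknown quadrature scheme {scheme!r}")
        if "resolution" in q:
            resolution = tuple(int(x) for x in q["resolution"])

    out_path, out_format = "result.csv", "csv"
    if "output" in data:
        o = data["output"]
        _require_keys(o, {"path", "format"}, "output block")
        out_path = o.get("path", out_path)
        out_format = o.get("format", out_format)
        if out_format != "csv":
            raise ConfigError(f"unsupported output format {out_format!r} (only 'csv')")

    log_level = str(data.get("log_level", "INFO")).upper()
    if log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        raise ConfigError(f"unknown log_level {log_level!r}")

    return RunConfig(
        material=material,
        scenario=scenario,
        quadrature_scheme=scheme,
        quadrature_resolution=resolution,
        output_path=str(out_path),
        output_format=out_format,
        seed=int(data.get("seed", 0)),
        log_level=log_level,
    )


def write_path_csv(result: PathResult, path: str | Path) -> None:
    """Write one row per step with the documented column schema.

    Values are written with 17 significant digits so a round-trip read
    reproduces them to 1e-12 or better.
    """
    rows = []
    for s in result.steps:
        row = [s.step, s.T]
        row += [s.sigma[i, j] for i, j in _TENSOR_IDX]
        row += [s.sigma_eff, s.xi]
        row += [s.eps_total[i, j] for i, j in _TENSOR_IDX]
        row += [s.eps_transform[i, j] for i, j in _TENSOR_IDX]
        row += [s.von_mises_stress, s.max_principal_strain]
        rows.append(row)
    frame = pd.DataFrame(rows, columns=PATH_CSV_COLUMNS)
    frame["step"] = frame["step"].astype(int)
    frame.to_csv(path, index=False, float_format="%.17g")
    logger.info("wrote %d steps to %s", len(frame), path)


def read_path_csv(path: str | Path) -> pd.DataFrame:
    """Read a result CSV back; schema is checked against the documented one."""
    frame = pd.read_csv(path)
    if list(frame.columns) != PATH_CSV_COLUMNS:
        raise ValueError(
            f"unexpected result-CSV columns: {list(frame.columns)}"
        )
    return frame


def generate_random_fixture(
    seed: int,
    n_steps: int,
    stress_scale: float,
    steps_per_segment: int = 5,
    params: MaterialParams | None = None,
) -> LoadPath:
    """Reproducible random piecewise-linear stress--temperature path.

    ``n_steps`` random symmetric stress targets (entries of magnitude
    ~``stress_scale`` MPa) with temperatures drawn uniformly from
    ``[Ms + 1, 65]`` deg C.  Identical seeds give identical paths.
    """
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps}")
    params = params or default_niti()
    rng = np.random.default_rng(seed)
    segments = []
    for _ in range(n_steps):
        a = rng.normal(size=(3, 3)) * stress_scale
        sigma = 0.5 * (a + a.T)
        T = rng.uniform(params.Ms + 1.0, 65.0)
        segments.append((StressPoint(sigma=sigma, T=T), steps_per_segment))
    return LoadPath(segments=segments)
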