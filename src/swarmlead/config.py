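"""Structured-text configuration, run manifests, and output writing.

Runs are described by a TOML file with sections ``[model]``, ``[params]``,
``[grid]``, ``[ic]`` and ``[run]``. Every model parameter is addressable
by name, unknown keys are rejected (typo protection), and the initial
condition seed is mandatory so any run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import time
import tomllib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .params import Grid, InitialConditionSpec, ModelParams
from .simulate import RunSpec, SimulationResult

__all__ = [
    "ConfigBundle",
    "RunManifest",
    "load_config",
    "config_from_dict",
    "dump_config",
    "write_outputs",
]

_PARAM_KEYS = {
    "gamma", "beta_plus", "beta_minus", "lambda1", "lambda2", "y0",
    "qa", "ql", "alpha", "alpha_plus", "alpha_minus", "eta",
    "sa", "sl", "ma", "ml", "L",
}
_GRID_KEYS = {"n_cells"}
_IC_KEYS = {"Mu", "Mv", "x0_u", "x0_v", "x0", "amplitude", "seed"}
_RUN_KEYS = {"t_end", "dt", "snapshot_every", "cfl"}
_MODEL_KEYS = {"variant"}


@dataclass(frozen=True)
class ConfigBundle:
    """Validated objects parsed from one configuration."""

    model: str
    params: ModelParams
    grid: Grid
    follower_ic: InitialConditionSpec
    leader_ic: InitialConditionSpec
    run: RunSpec
    raw: dict = field(repr=False)


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in [{section}]; "
            f"allowed: {sorted(allowed)}"
        )


def config_from_dict(cfg: dict[str, Any]) -> ConfigBundle:
    """Build validated parameter objects from a nested config mapping."""
    _check_keys("<top>", cfg, {"model", "params", "grid", "ic", "run"})
    model_sec = cfg.get("model", {})
    _check_keys("model", model_sec, _MODEL_KEYS)
    model = model_sec.get("variant", "M2")
    if model not in ("M1", "M2", "M3"):
        raise ValueError(f"[model] variant must be M1, M2 or M3, got {model!r}")

    params_sec = dict(cfg.get("params", {}))
    _check_keys("params", params_sec, _PARAM_KEYS)
    params = ModelParams(**params_sec)

    grid_sec = dict(cfg.get("grid", {}))
    _check_keys("grid", grid_sec, _GRID_KEYS)
    grid = Grid(n_cells=int(grid_sec.get("n_cells", 800)), L=params.L)

    ic_sec = dict(cfg.get("ic", {}))
    _check_keys("ic", ic_sec, _IC_KEYS)
    if "seed" not in ic_sec:
        raise ValueError("[ic] seed is mandatory for reproducibility")
    seed = int(ic_sec["seed"])
    amplitude = float(ic_sec.get("amplitude", 0.05))
    x0_default = 6.5 if model == "M1" else 5.0
    x0_u = float(ic_sec.get("x0_u", ic_sec.get("x0", x0_default)))
    x0_v = float(ic_sec.get("x0_v", ic_sec.get("x0", x0_default)))
    follower_ic = InitialConditionSpec(
        M=float(ic_sec.get("Mu", 12.61)), x0=x0_u, amplitude=amplitude, seed=seed,
    )
    leader_ic = InitialConditionSpec(
        M=float(ic_sec.get("Mv", 12.61)), x0=x0_v, amplitude=amplitude,
        seed=seed + 1,  # independent orientation draw for the leaders
    )

    run_sec = dict(cfg.get("run", {}))
    _check_keys("run", run_sec, _RUN_KEYS)
    run = RunSpec(
        t_end=float(run_sec.get("t_end", 400.0)),
        model=model,
        dt=float(run_sec["dt"]) if "dt" in run_sec else None,
        snapshot_every=int(run_sec.get("snapshot_every", 50)),
        cfl=float(run_sec.get("cfl", 0.9)),
    )
    return ConfigBundle(model, params, grid, follower_ic, leader_ic, run, cfg)


def load_config(path: str | Path) -> ConfigBundle:
    """Parse and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return config_from_dict(cfg)


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace('"', '\\"') + '"'


def dump_config(cfg: dict[str, Any]) -> str:
    """Serialize a (two-level) config mapping back to TOML text."""
    lines = []
    for section, body in cfg.items():
        lines.append(f"[{section}]")
        for key, value in body.items():
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    return "\n".join(lines)


@dataclass
class RunManifest:
    """Provenance record written next to every run's outputs."""

    config: dict
    seed: int
    version: str
    outputs: dict[str, str]
    wall_seconds: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def write_outputs(
    result: SimulationResult,
    metrics,
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Write snapshots, text exports, metrics, and the manifest.

    Produces ``snapshots.npz`` (named arrays), one tab-separated profile
    file per recorded time under ``profiles/``, ``metrics.tsv``, and
    ``manifest.json``. Overwrites existing files with a warning.
    """
    from . import __version__

    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()):
        warnings.warn(f"output directory {out} is not empty; overwriting")

    arrays = {
        "x": result.grid.cell_centers,
        "t": result.times,
        "u_plus": np.array([s.u_plus for s in result.snapshots]),
        "u_minus": np.array([s.u_minus for s in result.snapshots]),
        "v_plus": np.array([s.v_plus for s in result.snapshots]),
        "v_minus": np.array([s.v_minus for s in result.snapshots]),
    }
    if result.leader_center_unwrapped is not None:
        arrays["leader_center"] = result.leader_center_unwrapped
    np.savez(out / "snapshots.npz", **arrays)

    profiles = out / "profiles"
    profiles.mkdir(exist_ok=True)
    header = "x\tu_plus\tu_minus\tv_plus\tv_minus"
    for t, s in zip(result.times, result.snapshots):
        table = np.column_stack(
            [result.grid.cell_centers, s.u_plus, s.u_minus, s.v_plus, s.v_minus]
        )
        np.savetxt(profiles / f"t_{t:012.4f}.tsv", table,
                   delimiter="\t", header=header, comments="")

    if metrics is not None:
        import pandas as pd

        pd.DataFrame([asdict(metrics)]).to_csv(
            out / "metrics.tsv", sep="\t", index=False
        )

    manifest = RunManifest(
        config=config or {},
        seed=seed if seed is not None else -1,
        version=__version__,
        outputs={
            "snapshots": "snapshots.npz",
            "profiles": "profiles/",
            "metrics": "metrics.tsv" if metrics is not None else "",
        },
        wall_seconds=time.perf_counter() - t0,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
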