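"""Configuration, fixtures and tabular output.

Run configurations are flat, namespaced mappings (``model``, ``plant.*`` or
``rsl.*``, ``env.*``, ``solver.*``, ``output.*``, ``seed``) read from YAML or
JSON; YAML input is converted to JSON before hashing so the provenance hash
is format-independent.  Validation is aggregated: every offending key is
reported, with its location and the allowed range, in one error.

A small fixture library ships the named scenarios used throughout the test
suite and the documentation: ``constant-balanced``, ``n-poor``,
``seasonal-light`` and ``starvation`` for the root-shoot model, and
``fig3a``, ``fig3b``, ``fig3c`` for the root-stem-leaf comparison.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from plantdeb.environment import EnvironmentScenario, make_scenario
from plantdeb.root_shoot import PlantParams, PlantState, mass_balance_audit
from plantdeb.root_shoot import simulate as rs_simulate
from plantdeb.root_stem_leaf import (
    LEAF_DEFICIENT_START,
    RSLParams,
    RSLState,
    classify_outcome,
    run_alpha_sweep,
)
from plantdeb.root_stem_leaf import simulate as rsl_simulate
from plantdeb.sim_engine import SolverSettings, Trajectory, growth_rate, params_hash

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "default_config",
    "run",
    "write_summary",
    "FIXTURES",
    "RSL_FIXTURES",
    "fixture_config",
    "read_trajectory_csv",
    "audit_trajectory_file",
]


class ConfigError(ValueError):
    """Aggregated, human-readable configuration error."""


MODELS = ("root_shoot", "root_stem_leaf")

_DEFAULT_ENV = {
    "kind": "constant",
    "co2": 4.0,
    "light": 4.0,
    "soil_n": 4.0,
    "temperature": 293.15,
}
_DEFAULT_SOLVER = {
    "rel_tol": 1e-8,
    "abs_tol": 1e-10,
    "stiff": True,
    "t0": 0.0,
    "t1": 1000.0,
    "record_every": 2.0,
}


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled."""

    model: str = "root_shoot"
    plant: PlantParams = field(default_factory=PlantParams)
    rsl: RSLParams = field(default_factory=RSLParams)
    env: dict = field(default_factory=lambda: dict(_DEFAULT_ENV))
    solver: SolverSettings = field(default_factory=lambda: _solver_from(_DEFAULT_SOLVER))
    initial_state: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    seed: int = 0
    label: str = "run"

    def scenario(self) -> EnvironmentScenario:
        env = dict(self.env)
        kind = env.pop("kind", "constant")
        if kind == "noisy":
            env.setdefault("seed", self.seed)
        return make_scenario(kind, env)

    def to_json(self) -> str:
        solver = {
            "rel_tol": self.solver.rel_tol,
            "abs_tol": self.solver.abs_tol,
            "stiff": self.solver.stiff,
            "t0": self.solver.t_span[0],
            "t1": self.solver.t_span[1],
            "record_every": self.solver.record_every,
        }
        if math.isfinite(self.solver.max_step):
            solver["max_step"] = self.solver.max_step
        payload = {
            "model": self.model,
            "plant": dataclasses.asdict(self.plant),
            "rsl": {
                **dataclasses.asdict(self.rsl),
                "rule": self.rsl.rule.value,
            },
            "env": self.env,
            "solver": solver,
            "initial_state": self.initial_state,
            "output": self.output,
            "seed": self.seed,
            "label": self.label,
        }
        return json.dumps(payload, sort_keys=True, indent=2, default=str)

    @property
    def hash(self) -> str:
        return params_hash(json.loads(self.to_json()))


def _solver_from(block: Mapping) -> SolverSettings:
    return SolverSettings(
        rel_tol=float(block.get("rel_tol", 1e-8)),
        abs_tol=float(block.get("abs_tol", 1e-10)),
        max_step=float(block.get("max_step", math.inf)),
        stiff=bool(block.get("stiff", True)),
        t_span=(float(block.get("t0", 0.0)), float(block.get("t1", 1000.0))),
        record_every=float(block.get("record_every", 2.0)),
    )


def _check_block(name: str, block: Any, allowed: set[str], errors: list[str]) -> dict:
    if block is None:
        return {}
    if not isinstance(block, Mapping):
        errors.append(f"{name}: expected a mapping, got {type(block).__name__}")
        return {}
    out = {}
    for key, val in block.items():
        if key not in allowed:
            errors.append(f"{name}.{key}: unknown key (allowed: {sorted(allowed)})")
        else:
            out[key] = val
    return out


def _coerce_numbers(block: dict) -> dict:
    """Turn numeric strings into floats (YAML 1.1 reads '1e-10' as a string)."""
    out = {}
    for key, val in block.items():
        if isinstance(val, str):
            try:
                out[key] = float(val)
                continue
            except ValueError:
                pass
        out[key] = val
    return out


_PLANT_KEYS = {f.name for f in dataclasses.fields(PlantParams)}
_RSL_KEYS = {f.name for f in dataclasses.fields(RSLParams)}
_SOLVER_KEYS = {"rel_tol", "abs_tol", "max_step", "stiff", "t0", "t1", "record_every"}
_ENV_KEYS = {"kind", "co2", "light", "soil_n", "temperature", "base", "noise_sd", "noise_dt", "seed", "label"}
_STATE_KEYS = {f.name for f in dataclasses.fields(PlantState)} | {"m_L", "m_S", "m_R"}
_OUTPUT_KEYS = {"out_dir", "format", "trajectory_file", "summary_file"}
_TOP_KEYS = {"model", "plant", "rsl", "env", "solver", "initial_state", "output", "seed", "label"}


def parse_config(raw: Mapping | None) -> RunConfig:
    """Validate a raw configuration mapping; aggregate every violation."""
    raw = dict(raw or {})
    errors: list[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"{key}: unknown top-level key (allowed: {sorted(_TOP_KEYS)})")

    model = raw.get("model", "root_shoot")
    if model not in MODELS:
        errors.append(f"model: must be one of {MODELS}, got {model!r}")

    plant_block = _coerce_numbers(_check_block("plant", raw.get("plant"), _PLANT_KEYS, errors))
    rsl_block = _coerce_numbers(_check_block("rsl", raw.get("rsl"), _RSL_KEYS, errors))
    solver_block = _coerce_numbers(
        _check_block("solver", raw.get("solver"), _SOLVER_KEYS, errors)
    )
    env_block = _check_block("env", raw.get("env"), _ENV_KEYS, errors)
    state_block = _check_block("initial_state", raw.get("initial_state"), _STATE_KEYS, errors)
    output_block = _check_block("output", raw.get("output"), _OUTPUT_KEYS, errors)

    plant = rsl = solver = None
    try:
        plant = PlantParams(**plant_block)
    except (ValueError, TypeError) as exc:
        errors.append(f"plant: {exc}")
    try:
        rsl = RSLParams(**rsl_block)
    except (ValueError, TypeError) as exc:
        errors.append(f"rsl: {exc}")
    try:
        solver = _solver_from(solver_block or _DEFAULT_SOLVER)
    except (ValueError, TypeError) as exc:
        errors.append(f"solver: {exc}")

    env = dict(_DEFAULT_ENV)
    env.update(env_block)

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(str(e) for e in errors))
    return RunConfig(
        model=model,
        plant=plant,
        rsl=rsl,
        env=env,
        solver=solver,
        initial_state=dict(state_block),
        output=dict(output_block),
        seed=int(raw.get("seed", 0)),
        label=str(raw.get("label", "run")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration file.

    An empty file yields the full default configuration.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text) if text.strip() else None
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is not None and not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(raw).__name__}")
    cfg = parse_config(raw)
    cfg.label = cfg.label if cfg.label != "run" else path.stem
    return cfg


def default_config() -> RunConfig:
    return parse_config({})


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURES: dict[str, dict] = {
    "constant-balanced": {
        "model": "root_shoot",
        "label": "constant-balanced",
        "env": {"kind": "constant", "co2": 4.0, "light": 4.0, "soil_n": 4.0,
                "temperature": 293.15},
        "solver": {"t0": 0.0, "t1": 1000.0, "record_every": 2.0},
    },
    "n-poor": {
        "model": "root_shoot",
        "label": "n-poor",
        "env": {"kind": "step", "co2": 4.0, "light": 4.0,
                "soil_n": {"before": 4.0, "after": 0.0, "t_switch": 100.0},
                "temperature": 293.15},
        "solver": {"t0": 0.0, "t1": 300.0, "record_every": 1.0},
    },
    "seasonal-light": {
        "model": "root_shoot",
        "label": "seasonal-light",
        "env": {"kind": "seasonal", "co2": 4.0,
                "light": {"mean": 4.0, "amplitude": 2.0, "period": 365.0},
                "soil_n": 4.0, "temperature": 293.15},
        "solver": {"t0": 0.0, "t1": 730.0, "record_every": 1.0},
    },
    "starvation": {
        "model": "root_shoot",
        "label": "starvation",
        "env": {"kind": "constant", "co2": 0.0, "light": 0.0, "soil_n": 0.0,
                "temperature": 293.15},
        "initial_state": {"m_EC_S": 0.1, "m_EN_S": 0.1, "m_EC_R": 0.1, "m_EN_R": 0.1},
        "solver": {"t0": 0.0, "t1": 200.0, "record_every": 0.5},
    },
}

RSL_FIXTURES: dict[str, dict] = {
    "fig3a": {
        "model": "root_stem_leaf",
        "label": "fig3a",
        "rsl": {"rule": "minimum"},
        "solver": {"t0": 0.0, "t1": 700.0, "record_every": 2.0, "stiff": False},
    },
    "fig3b": {
        "model": "root_stem_leaf",
        "label": "fig3b",
        "rsl": {"rule": "pcsu"},
        "solver": {"t0": 0.0, "t1": 200.0, "record_every": 1.0, "stiff": False},
    },
    "fig3c": {
        "model": "root_stem_leaf",
        "label": "fig3c",
        "rsl": {"rule": "pcsu"},
    },
}

#: default availability-ratio grid of the fraction sweep: log10 alpha in [-2, 2]
ALPHA_GRID = np.logspace(-2.0, 2.0, 41)


def fixture_config(name: str) -> RunConfig:
    """Named fixture as a validated :class:`RunConfig`."""
    lib = {**FIXTURES, **RSL_FIXTURES}
    if name not in lib:
        raise ConfigError(f"unknown fixture {name!r}; available: {sorted(lib)}")
    return parse_config(lib[name])


# ---------------------------------------------------------------------------
# running and summarizing
# ---------------------------------------------------------------------------

def _initial_state(cfg: RunConfig):
    if cfg.model == "root_shoot":
        return PlantState(**{k: v for k, v in cfg.initial_state.items() if k != "alive"})
    masses = {k: cfg.initial_state.get(k, d)
              for k, d in zip(("m_L", "m_S", "m_R"), LEAF_DEFICIENT_START)}
    return RSLState(**masses)


def run(cfg: RunConfig) -> tuple[Trajectory, dict]:
    """Execute a configured simulation; returns the trajectory and summary."""
    state0 = _initial_state(cfg)
    if cfg.model == "root_shoot":
        traj = rs_simulate(state0, cfg.scenario(), cfg.plant, cfg.solver)
        err_C, err_N = mass_balance_audit(traj, cfg.plant)
        summary = {
            "model": cfg.model,
            "label": cfg.label,
            "params_hash": cfg.hash,
            "seed": cfg.seed,
            "t_final": float(traj.times[-1]),
            "final_state": traj.final_state,
            "events": [
                {"type": e[0], "time": e[1], **e[2]} for e in traj.events
            ],
            "audit": {"rel_error_C": err_C, "rel_error_N": err_N},
        }
        if not traj.events and traj["M_V_S"][-1] > 0 and traj["M_V_R"][-1] > 0:
            g_S, r2_S = growth_rate(traj, "M_V_S")
            g_R, r2_R = growth_rate(traj, "M_V_R")
            summary["growth_rates"] = {
                "shoot": g_S, "root": g_R, "r2_shoot": r2_S, "r2_root": r2_R,
            }
    else:
        traj = rsl_simulate(state0, cfg.rsl, cfg.solver)
        outcome = classify_outcome(traj)
        m_end = {n: float(traj[n][-1]) for n in ("m_L", "m_S", "m_R")}
        total = sum(m_end.values())
        summary = {
            "model": cfg.model,
            "label": cfg.label,
            "rule": cfg.rsl.rule.value,
            "alpha": cfg.rsl.alpha,
            "params_hash": cfg.hash,
            "seed": cfg.seed,
            "t_final": float(traj.times[-1]),
            "final_state": m_end,
            "fractions": {k: (v / total if total > 0 else 0.0) for k, v in m_end.items()},
            "outcome": outcome.value,
        }
    traj.metadata["params_hash"] = cfg.hash
    traj.metadata["label"] = cfg.label
    traj.metadata["seed"] = cfg.seed
    return traj, summary


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=str), encoding="utf-8")


# ---------------------------------------------------------------------------
# trajectory round trip and re-audit
# ---------------------------------------------------------------------------

def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :meth:`Trajectory.to_csv`."""
    path = Path(path)
    meta: dict = {}
    events: list = []
    header_lines = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if body.startswith("event:"):
                events.append(("recorded", math.nan, {"raw": body}))
            elif ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ConfigError(f"cannot parse trajectory CSV {path}: {exc}") from exc
    if "t" not in df.columns:
        raise ConfigError(f"trajectory CSV {path} has no 't' column")
    state_cols = [c for c in df.columns if c != "t" and not c.startswith("J.")]
    ledger_cols = [c for c in df.columns if c.startswith("J.")]
    if df[state_cols].isna().any().any() or df["t"].isna().any():
        raise ConfigError(f"trajectory CSV {path} contains missing values (truncated file?)")
    ledgers = None
    if ledger_cols:
        ledgers = df[ledger_cols].rename(columns=lambda c: c[2:])
    return Trajectory(
        times=df["t"].to_numpy(),
        states=df[state_cols].to_numpy(),
        state_names=tuple(state_cols),
        ledgers=ledgers,
        events=events,
        metadata=meta,
    )


def audit_trajectory_file(path: str | Path, params: PlantParams) -> tuple[float, float]:
    """Recompute the elemental mass-balance audit from a saved trajectory."""
    traj = read_trajectory_csv(path)
    missing = [n for n in (
        "M_V_S", "M_V_R", "m_EC_S", "m_EN_S", "m_EC_R", "m_EN_R",
        "M_P", "M_litter_C", "M_litter_N", "M_CO2", "N_excess", "A_C_cum", "A_N_cum",
    ) if n not in traj.state_names]
    if missing:
        raise ConfigError(f"trajectory lacks root-shoot state columns: {missing}")
    return mass_balance_audit(traj, params)
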