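"""Numerical integration, event detection and trajectory assembly.

Reserve turnover is fast relative to structural growth, so the default
integrator is the implicit Radau method with tight tolerances
(``rel_tol=1e-8``, ``abs_tol=1e-10``); explicit RK45 is available for
non-stiff test problems.  States are clipped to zero when the integrator
undershoots by less than a small tolerance; larger negative excursions are a
hard error rather than silently projected, to protect the mass audit.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "SolverSettings",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "growth_rate",
    "time_rescale_check",
]

#: a state component below -NEG_TOL after integration is a hard error
NEG_TOL = 1e-9


class IntegrationError(RuntimeError):
    """Solver failure; carries the last valid state if available."""

    def __init__(self, message: str, last_state=None, last_time=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


@dataclass(frozen=True)
class SolverSettings:
    """Integration settings shared by both plant models."""

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = math.inf
    stiff: bool = True
    t_span: tuple[float, float] = (0.0, 100.0)
    record_every: float = 1.0

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.t_span[1] <= self.t_span[0]:
            raise ValueError(f"t_span must be increasing, got {self.t_span}")
        if self.record_every <= 0:
            raise ValueError("record_every must be positive")

    @property
    def method(self) -> str:
        return "Radau" if self.stiff else "RK45"


@dataclass
class Trajectory:
    """Time-indexed record of a simulation.

    Attributes
    ----------
    times:
        Strictly increasing record times (days).
    states:
        Array of shape ``(len(times), n_state)``.
    state_names:
        Column names for ``states``.
    ledgers:
        Optional DataFrame of instantaneous fluxes, one row per record time.
    events:
        List of ``(type, time, payload)`` tuples.
    metadata:
        Parameter hash, solver settings, seed and similar provenance.
    """

    times: np.ndarray
    states: np.ndarray
    state_names: tuple[str, ...]
    ledgers: pd.DataFrame | None = None
    events: list[tuple[str, float, dict]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape != (self.times.size, len(self.state_names)):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{self.times.size} times x {len(self.state_names)} names"
            )

    def __getitem__(self, name: str) -> np.ndarray:
        """Time series of one state variable by name."""
        return self.states[:, self.state_names.index(name)]

    @property
    def final_state(self) -> dict[str, float]:
        return dict(zip(self.state_names, self.states[-1]))

    def to_frame(self) -> pd.DataFrame:
        """States (and ledgers, if present) as one DataFrame indexed by time."""
        df = pd.DataFrame(self.states, columns=list(self.state_names))
        df.insert(0, "t", self.times)
        if self.ledgers is not None:
            led = self.ledgers.add_prefix("J.")
            df = pd.concat([df.reset_index(drop=True), led.reset_index(drop=True)], axis=1)
        return df

    def to_csv(self, path) -> None:
        """Write the trajectory as RFC 4180 CSV with '# key: value' header lines."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for key in sorted(self.metadata):
                fh.write(f"# {key}: {self.metadata[key]}\n")
            for etype, etime, payload in self.events:
                fh.write(f"# event: {etype} t={etime!r} {json.dumps(payload)}\n")
            # %.17g round-trips float64 exactly, so a saved trajectory
            # re-audits to the same numbers
            self.to_frame().to_csv(fh, index=False, float_format="%.17g")


def params_hash(obj) -> str:
    """Stable short hash of a JSON-serializable parameter mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: Sequence[float],
    settings: SolverSettings,
    state_names: Sequence[str] | None = None,
    ledger_fn: Callable[[float, np.ndarray], dict] | None = None,
    events: Sequence[Callable[[float, np.ndarray], float]] | None = None,
    metadata: dict | None = None,
) -> Trajectory:
    """Adaptively integrate ``dy/dt = rhs(t, y)`` and assemble a trajectory.

    Parameters
    ----------
    rhs:
        Right-hand side; must be finite at ``(t0, y0)``.
    y0:
        Initial state.
    settings:
        Tolerances, time span and output cadence.
    state_names:
        Names for the state vector components (defaults to ``y0..yN``).
    ledger_fn:
        Optional callable returning a dict of instantaneous fluxes, evaluated
        at every record time.
    events:
        scipy-style event functions; an event with ``terminal = True`` stops
        the integration and is recorded on the trajectory.
    """
    y0 = np.asarray(y0, dtype=float)
    t0, t1 = settings.t_span
    f0 = np.asarray(rhs(t0, y0), dtype=float)
    if not np.all(np.isfinite(f0)):
        raise IntegrationError(
            f"right-hand side not finite at t0: {f0}", last_state=y0, last_time=t0
        )
    n_rec = max(2, int(round((t1 - t0) / settings.record_every)) + 1)
    t_eval = np.linspace(t0, t1, n_rec)
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method=settings.method,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
        max_step=settings.max_step,
        t_eval=t_eval,
        events=list(events) if events else None,
        dense_output=True,
    )
    if not sol.success and sol.status != 1:
        last_y = sol.y[:, -1] if sol.y.size else y0
        last_t = sol.t[-1] if sol.t.size else t0
        raise IntegrationError(
            f"solver failed: {sol.message}", last_state=last_y, last_time=last_t
        )

    times = sol.t
    states = sol.y.T
    recorded_events: list[tuple[str, float, dict]] = []
    if sol.status == 1 and events:
        # terminated by a terminal event: append the event state as final record
        for i, (ev_times, ev_states) in enumerate(zip(sol.t_events, sol.y_events)):
            name = getattr(events[i], "name", f"event_{i}")
            for et, ey in zip(ev_times, ev_states):
                recorded_events.append(
                    ("terminal", float(et), {"name": name, "state": [float(v) for v in ey]})
                )
                if times.size == 0 or et > times[-1] + 1e-12:
                    times = np.append(times, et)
                    states = np.vstack([states, ey])
    elif events:
        for i, ev_times in enumerate(sol.t_events):
            name = getattr(events[i], "name", f"event_{i}")
            for et in ev_times:
                recorded_events.append(("crossing", float(et), {"name": name}))

    worst = states.min(initial=0.0)
    if worst < -NEG_TOL * max(1.0, float(np.abs(states).max())):
        raise IntegrationError(
            f"state went negative beyond tolerance (min={worst}); "
            "model wiring or tolerances are inconsistent"
        )
    states = np.clip(states, 0.0, None)

    names = tuple(state_names) if state_names else tuple(f"y{i}" for i in range(y0.size))
    ledgers = None
    if ledger_fn is not None:
        rows = [ledger_fn(t, y) for t, y in zip(times, states)]
        ledgers = pd.DataFrame(rows)
    meta = dict(metadata or {})
    meta.setdefault("solver", settings.method)
    meta.setdefault("rel_tol", settings.rel_tol)
    meta.setdefault("abs_tol", settings.abs_tol)
    return Trajectory(
        times=times,
        states=states,
        state_names=names,
        ledgers=ledgers,
        events=recorded_events,
        metadata=meta,
    )


def growth_rate(
    trajectory: Trajectory, variable: str, tail_fraction: float = 0.2
) -> tuple[float, float]:
    """Specific growth rate of one variable over the trajectory tail.

    Fits ``log(x)`` against ``t`` by least squares over the final
    ``tail_fraction`` of the record and returns ``(slope, R^2)``.  In the
    exponential balanced-growth regime the slope is the specific growth rate
    in d^-1 and R^2 is 1 to solver precision.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    x = trajectory[variable]
    t = trajectory.times
    n = max(3, int(math.ceil(tail_fraction * t.size)))
    xt, tt = x[-n:], t[-n:]
    if np.any(xt <= 0):
        raise ValueError(
            f"variable {variable!r} must be positive over the tail for a log-linear fit"
        )
    logx = np.log(xt)
    slope, intercept = np.polyfit(tt, logx, 1)
    pred = slope * tt + intercept
    ss_res = float(np.sum((logx - pred) ** 2))
    ss_tot = float(np.sum((logx - logx.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def time_rescale_check(
    make_rhs: Callable[[float], Callable[[float, np.ndarray], np.ndarray]],
    y0: Sequence[float],
    T1: float,
    T2: float,
    T_ref: float,
    T_A: float,
    settings: SolverSettings,
) -> float:
    """Max relative state discrepancy between a run at ``T2`` and the
    time-rescaled run at ``T1``.

    When every rate parameter shares one Arrhenius temperature ``T_A``, the
    whole right-hand side scales by a common factor ``c(T)``, so the solution
    at ``T2`` equals the solution at ``T1`` with time compressed by
    ``c(T2)/c(T1)``.  ``make_rhs(T)`` must return the autonomous RHS at
    constant temperature ``T``.
    """
    from plantdeb.environment import arrhenius_factor

    c1 = arrhenius_factor(T1, T_ref, T_A)
    c2 = arrhenius_factor(T2, T_ref, T_A)
    ratio = c2 / c1
    t0, t1 = settings.t_span
    traj1 = integrate(make_rhs(T1), y0, settings)
    settings2 = SolverSettings(
        rel_tol=settings.rel_tol,
        abs_tol=settings.abs_tol,
        max_step=settings.max_step,
        stiff=settings.stiff,
        t_span=(t0 / ratio, t1 / ratio),
        record_every=settings.record_every / ratio,
    )
    traj2 = integrate(make_rhs(T2), y0, settings2)
    # compare y2(t / ratio) with y1(t) on the T1 record grid
    y2_interp = np.column_stack(
        [
            np.interp(traj1.times / ratio, traj2.times, traj2.states[:, k])
            for k in range(traj2.states.shape[1])
        ]
    )
    scale = np.maximum(np.abs(traj1.states), np.abs(y2_interp))
    scale = np.maximum(scale, scale.max() * 1e-6 + 1e-300)
    return float(np.max(np.abs(traj1.states - y2_interp) / scale))
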