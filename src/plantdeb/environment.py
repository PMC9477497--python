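"""Prescribed environmental forcing.

The plant models treat the environment as a boundary condition: CO2, light,
soil nitrogen and temperature are given functions of time that the plant does
not deplete.  Four scenario kinds cover the shipped fixtures (constant, step,
seasonal, noisy); temperature sensitivity of rates uses the standard
Arrhenius correction ``exp(T_A/T_ref - T_A/T)``.

Units are normalized by default: resource channels are expressed relative to
their half-saturation constants (so a level of 1.0 means half-saturating
supply when K = 1), light is a 0-1 factor and temperature is in kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

__all__ = ["EnvironmentScenario", "ScenarioError", "arrhenius_factor", "make_scenario"]

CHANNELS = ("co2", "light", "soil_n", "temperature")


class ScenarioError(ValueError):
    """Raised for invalid scenario configuration."""


def arrhenius_factor(T: float, T_ref: float, T_A: float) -> float:
    """Dimensionless Arrhenius rate multiplier ``exp(T_A/T_ref - T_A/T)``.

    Equals 1 at ``T = T_ref`` and is monotone increasing in ``T`` for
    ``T_A > 0``.  ``T_A = 0`` disables temperature sensitivity.
    """
    if T <= 0 or T_ref <= 0:
        raise ScenarioError(f"temperatures must be positive kelvin, got T={T}, T_ref={T_ref}")
    if T_A < 0:
        raise ScenarioError(f"Arrhenius temperature must be nonnegative, got {T_A}")
    return math.exp(T_A / T_ref - T_A / T)


@dataclass(frozen=True)
class EnvironmentScenario:
    """Time-dependent environmental forcing channels.

    Each channel is a pure function of time (days); repeated evaluation at
    the same time returns identical values, which the adaptive integrator
    relies on.
    """

    co2: Callable[[float], float]
    light: Callable[[float], float]
    soil_n: Callable[[float], float]
    temperature: Callable[[float], float]
    seed: int | None = None
    label: str = "scenario"

    def at(self, t: float) -> dict[str, float]:
        """All channel values at time ``t`` as a dict."""
        return {name: float(getattr(self, name)(t)) for name in CHANNELS}

    def table(self, times) -> "np.ndarray":
        """Channel values at an array of times, shape (len(times), 4)."""
        times = np.asarray(times, dtype=float)
        return np.column_stack(
            [[getattr(self, name)(t) for t in times] for name in CHANNELS]
        )


def _constant(params: Mapping) -> dict[str, Callable[[float], float]]:
    missing = [c for c in CHANNELS if c not in params]
    if missing:
        raise ScenarioError(f"constant scenario: missing channel levels {missing}")
    funcs = {}
    for c in CHANNELS:
        level = float(params[c])
        _check_level(c, level)
        funcs[c] = (lambda lv: lambda t: lv)(level)
    return funcs


def _step(params: Mapping) -> dict[str, Callable[[float], float]]:
    missing = [c for c in CHANNELS if c not in params]
    if missing:
        raise ScenarioError(f"step scenario: missing channel levels {missing}")
    funcs = {}
    for c in CHANNELS:
        spec = params[c]
        if isinstance(spec, Mapping):
            for key in ("before", "after", "t_switch"):
                if key not in spec:
                    raise ScenarioError(f"step scenario: channel {c!r} missing key {key!r}")
            before, after, t_sw = (
                float(spec["before"]),
                float(spec["after"]),
                float(spec["t_switch"]),
            )
            _check_level(c, before)
            _check_level(c, after)
            funcs[c] = (
                lambda b, a, ts: lambda t: b if t < ts else a
            )(before, after, t_sw)
        else:
            level = float(spec)
            _check_level(c, level)
            funcs[c] = (lambda lv: lambda t: lv)(level)
    return funcs


def _seasonal(params: Mapping) -> dict[str, Callable[[float], float]]:
    missing = [c for c in CHANNELS if c not in params]
    if missing:
        raise ScenarioError(f"seasonal scenario: missing channel specs {missing}")
    funcs = {}
    for c in CHANNELS:
        spec = params[c]
        if isinstance(spec, Mapping):
            for key in ("mean", "amplitude", "period"):
                if key not in spec:
                    raise ScenarioError(f"seasonal scenario: channel {c!r} missing key {key!r}")
            mean, amp, period = (
                float(spec["mean"]),
                float(spec["amplitude"]),
                float(spec["period"]),
            )
            if period <= 0:
                raise ScenarioError(f"seasonal scenario: channel {c!r} period must be positive")
            lo = mean - abs(amp)
            _check_level(c, lo)
            funcs[c] = (
                lambda m, a, p: lambda t: m + a * math.sin(2.0 * math.pi * t / p)
            )(mean, amp, period)
        else:
            level = float(spec)
            _check_level(c, level)
            funcs[c] = (lambda lv: lambda t: lv)(level)
    return funcs


def _check_level(channel: str, value: float) -> None:
    if not math.isfinite(value):
        raise ScenarioError(f"channel {channel!r}: level must be finite, got {value}")
    if channel == "temperature":
        if value <= 0:
            raise ScenarioError(f"channel 'temperature': must be > 0 K, got {value}")
    elif value < 0:
        raise ScenarioError(f"channel {channel!r}: level must be nonnegative, got {value}")


def _noisy(params: Mapping) -> tuple[dict[str, Callable[[float], float]], int]:
    if "base" not in params:
        raise ScenarioError("noisy scenario: missing 'base' scenario")
    if "seed" not in params:
        raise ScenarioError("noisy scenario: missing 'seed'")
    base = params["base"]
    if not isinstance(base, EnvironmentScenario):
        base = make_scenario(base.get("kind", "constant"), base)
    sd = float(params.get("noise_sd", 0.1))
    if sd < 0:
        raise ScenarioError(f"noisy scenario: noise_sd must be nonnegative, got {sd}")
    seed = int(params["seed"])
    dt = float(params.get("noise_dt", 1.0))
    if dt <= 0:
        raise ScenarioError(f"noisy scenario: noise_dt must be positive, got {dt}")

    # Multiplicative lognormal noise, piecewise constant on a grid of width
    # noise_dt so the channel stays a pure function of time: the factor at
    # bin i is drawn from a generator re-seeded with (seed, channel, i).
    def make_channel(name: str, base_func):
        def channel(t: float) -> float:
            i = int(math.floor(t / dt))
            rng = np.random.default_rng([seed, hash(name) % (2**31), i])
            factor = math.exp(rng.normal(0.0, sd) - 0.5 * sd * sd)
            return base_func(t) * factor

        return channel

    funcs = {}
    for c in CHANNELS:
        if c == "temperature":
            funcs[c] = getattr(base, c)  # temperature noise off: keep T > 0 trivially
        else:
            funcs[c] = make_channel(c, getattr(base, c))
    return funcs, seed


def make_scenario(kind: str, params: Mapping) -> EnvironmentScenario:
    """Build an :class:`EnvironmentScenario` of the given kind.

    Parameters
    ----------
    kind:
        One of ``constant``, ``step``, ``seasonal``, ``noisy``.
    params:
        Kind-specific keys.  ``constant``: one level per channel.  ``step``:
        per channel either a level or ``{before, after, t_switch}``.
        ``seasonal``: per channel either a level or ``{mean, amplitude,
        period}``.  ``noisy``: ``base`` (scenario or its config), ``seed``,
        optional ``noise_sd`` (lognormal sigma, default 0.1) and ``noise_dt``
        (bin width in days, default 1).
    """
    seed = None
    if kind == "constant":
        funcs = _constant(params)
    elif kind == "step":
        funcs = _step(params)
    elif kind == "seasonal":
        funcs = _seasonal(params)
    elif kind == "noisy":
        funcs, seed = _noisy(params)
    else:
        raise ScenarioError(
            f"unknown scenario kind {kind!r}; expected constant, step, seasonal or noisy"
        )
    return EnvironmentScenario(
        co2=funcs["co2"],
        light=funcs["light"],
        soil_n=funcs["soil_n"],
        temperature=funcs["temperature"],
        seed=seed,
        label=str(params.get("label", kind)),
    )
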