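"""Synthesizing-unit (SU) kinetics.

A synthesizing unit is a stylized representation of the biochemical machinery
that transforms one or more substrate fluxes into a product flux.  Two rules
are supported for complementary (all-required) substrates:

* ``MINIMUM`` -- the Liebig idealization: production is limited solely by the
  scarcest substrate and the SU is perfectly efficient with respect to it.
* ``PCSU`` -- the parallel complementary SU: substrates bind independently in
  parallel and production completes only once every binding site is occupied.
  For two substrates the mean rate is ``(1/rho1 + 1/rho2 - 1/(rho1+rho2))^-1``
  where ``rho_i`` are arrival rates scaled to product equivalents.  At equal
  balanced arrivals this is exactly 2/3 of the minimum-rule rate.

All rates here are continuous deterministic fluxes.  The discrete-event
binding-site interpretation is used only as a test oracle.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SURule",
    "SUSpec",
    "SUError",
    "scaled_arrivals",
    "production_rate",
    "rejected_fluxes",
    "saturating_uptake",
]

#: absolute tolerance below which a computed rejection flux is clipped to zero
_REJECT_TOL = 1e-12


class SURule(enum.Enum):
    """Synthesis rule of an SU with complementary substrates."""

    MINIMUM = "minimum"
    PCSU = "pcsu"


class SUError(ValueError):
    """Raised for invalid SU configuration or inconsistent flux wiring."""


@dataclass(frozen=True)
class SUSpec:
    """Stoichiometry and rule of one synthesizing unit.

    Parameters
    ----------
    rule:
        Synthesis rule (:class:`SURule` or its string value).
    yields:
        Per-substrate stoichiometric coefficients: substrate units required
        per unit of product.  Strictly positive and finite.
    label:
        Name used in error messages and ledgers.
    """

    rule: SURule
    yields: tuple[float, ...]
    label: str = "su"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rule", SURule(self.rule))
        y = tuple(float(v) for v in self.yields)
        if len(y) == 0:
            raise SUError(f"SU {self.label!r}: needs at least one substrate yield")
        if any(not math.isfinite(v) or v <= 0 for v in y):
            raise SUError(f"SU {self.label!r}: yields must be positive and finite, got {y}")
        object.__setattr__(self, "yields", y)


def scaled_arrivals(arrivals: Sequence[float], spec: SUSpec) -> np.ndarray:
    """Scale raw substrate arrival fluxes to product-equivalent rates.

    ``rho_i = arrival_i / yield_i`` puts every substrate stream in units of
    product per time, so synthesis rules can compare them directly.
    """
    arr = np.asarray(arrivals, dtype=float)
    if arr.shape != (len(spec.yields),):
        raise SUError(
            f"SU {spec.label!r}: expected {len(spec.yields)} arrival fluxes, "
            f"got shape {arr.shape}"
        )
    if np.any(arr < 0):
        raise SUError(f"SU {spec.label!r}: arrival fluxes must be nonnegative, got {arr}")
    return arr / np.asarray(spec.yields)


def production_rate(rho: Sequence[float], rule: SURule | str) -> float:
    """Product synthesis rate from scaled arrival rates.

    Parameters
    ----------
    rho:
        Scaled (product-equivalent) arrival rates, nonnegative.
    rule:
        ``MINIMUM`` for the Liebig rule, ``PCSU`` for the parallel
        complementary SU.

    Notes
    -----
    A single-substrate SU processes everything that arrives under either
    rule.  With ``k`` complementary substrates the PCSU rate is the inverse
    of the inclusion-exclusion sum

    ``1/j = sum_i 1/rho_i - sum_{i<j} 1/(rho_i + rho_j) + ...``

    which for ``k = 2`` reduces to the standard two-substrate closed form.
    If any required substrate is absent (``rho_i = 0``) the rate is 0.
    """
    rule = SURule(rule)
    r = np.asarray(rho, dtype=float)
    if np.any(r < 0) or not np.all(np.isfinite(r)):
        raise SUError(f"scaled arrival rates must be nonnegative and finite, got {r}")
    if r.size == 0:
        raise SUError("at least one scaled arrival rate is required")
    if np.any(r == 0.0):
        return 0.0
    if r.size == 1:
        return float(r[0])
    if rule is SURule.MINIMUM:
        return float(r.min())
    # PCSU: 1/j = E[max of independent exponentials with rates rho_i]
    inv = 0.0
    idx = range(r.size)
    for k in range(1, r.size + 1):
        sign = 1.0 if k % 2 == 1 else -1.0
        for combo in itertools.combinations(idx, k):
            inv += sign / r[list(combo)].sum()
    return 1.0 / inv


def rejected_fluxes(
    arrivals: Sequence[float], spec: SUSpec, j_prod: float
) -> np.ndarray:
    """Per-substrate rejected flux (raw substrate units per time).

    Conservation at the SU: ``arrival_i = yield_i * j_prod + rejected_i``.
    Tiny negative residuals (|.| <= 1e-12) from floating-point cancellation
    are clipped to zero; anything larger signals a wiring bug upstream.
    """
    arr = np.asarray(arrivals, dtype=float)
    if arr.shape != (len(spec.yields),):
        raise SUError(
            f"SU {spec.label!r}: expected {len(spec.yields)} arrival fluxes, "
            f"got shape {arr.shape}"
        )
    rej = arr - np.asarray(spec.yields) * float(j_prod)
    scale = max(1.0, float(np.max(np.abs(arr), initial=0.0)))
    if np.any(rej < -_REJECT_TOL * scale):
        raise SUError(
            f"SU {spec.label!r}: negative rejection flux {rej} for arrivals {arr} "
            f"and production {j_prod}; inconsistent wiring"
        )
    return np.clip(rej, 0.0, None)


def saturating_uptake(conc: float, j_max: float, K: float) -> float:
    """Hyperbolic single-substrate acquisition flux.

    ``j = j_max * conc / (conc + K)``: the standard saturating response of a
    single-substrate SU to environmental substrate concentration, with
    half-saturation constant ``K``.
    """
    if conc < 0:
        raise SUError(f"environmental concentration must be nonnegative, got {conc}")
    if j_max <= 0 or K <= 0:
        raise SUError(f"j_max and K must be positive, got j_max={j_max}, K={K}")
    return j_max * conc / (conc + K)
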