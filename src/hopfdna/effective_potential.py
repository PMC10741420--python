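"""Effective potential of the torque-driven B-Z transition.

The local interaction between successive base pairs is captured by a
chiral gauge potential rho, the rotational angle between neighbouring
base pairs (rad/bp): rho > 0 for a right-handed (B) helix, rho < 0 for
a left-handed (Z) helix.  Under an applied torque tau the effective
potential is the tilted double well

    Veff(rho) = V0 [ (rho/omega0)^2 - 1 ]^2 - (tau - tauc) * rho

with omega0 = 2pi/10.5 rad/bp the relaxed helix rotation, V0 the barrier
scale and tauc the critical torque.  At tau = tauc the well is symmetric
with minima at rho = +/- omega0; for tau > tauc the right-handed
minimum is favoured and the left-handed helix converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EffectivePotentialParams",
    "StationaryPoint",
    "veff",
    "veff_stationary_points",
]


@dataclass(frozen=True)
class EffectivePotentialParams:
    """Parameters of the B-Z effective potential.

    Defaults are the single-molecule magnetic-tweezer values:
    V0 = 6e-21 J, omega0 = 2pi/10.5 rad/bp, tauc = -7.9e-21 J.
    """

    v0: float = 6e-21
    omega0: float = 2.0 * math.pi / 10.5
    tau: float = -7.9e-21
    tau_c: float = -7.9e-21

    def __post_init__(self) -> None:
        if not self.v0 > 0:
            raise ValueError(f"v0 must be > 0, got {self.v0}")
        if self.omega0 == 0:
            raise ValueError("omega0 must be nonzero")


@dataclass(frozen=True)
class StationaryPoint:
    """A root of dVeff/drho with its second-derivative classification."""

    rho: float
    value: float
    kind: str  # "min" | "max" | "inflection"


def veff(rho, params: EffectivePotentialParams):
    """Effective potential Veff(rho) in joules; scalar or array ``rho``."""
    rho = np.asarray(rho, dtype=float)
    quartic = params.v0 * ((rho / params.omega0) ** 2 - 1.0) ** 2
    tilt = (params.tau - params.tau_c) * rho
    out = quartic - tilt
    return out if out.ndim else float(out)


def _veff_second(rho: float, params: EffectivePotentialParams) -> float:
    w2 = params.omega0**2
    return 4.0 * params.v0 * (3.0 * rho**2 / w2 - 1.0) / w2


def veff_stationary_points(params: EffectivePotentialParams) -> list[StationaryPoint]:
    """Real stationary points of Veff, sorted by rho and classified.

    dVeff/drho = 0 reduces to the depressed cubic

        rho^3 - omega0^2 rho - (tau - tauc) omega0^4 / (4 V0) = 0

    solved in closed form (trigonometric method for three real roots,
    Cardano for one), with ``numpy.roots`` as fallback on degenerate
    arithmetic.  At tau = tauc the roots are exactly {-omega0, 0,
    +omega0} with minima at +/- omega0.
    """
    w0 = params.omega0
    pcoef = -(w0**2)
    qcoef = -(params.tau - params.tau_c) * w0**4 / (4.0 * params.v0)
    roots = _solve_depressed_cubic(pcoef, qcoef)

    points = []
    for rho in sorted(roots):
        second = _veff_second(rho, params)
        if second > 0:
            kind = "min"
        elif second < 0:
            kind = "max"
        else:
            kind = "inflection"
        points.append(StationaryPoint(rho=rho, value=float(veff(rho, params)), kind=kind))
    return points


def _solve_depressed_cubic(p: float, q: float) -> list[float]:
    """Real roots of t^3 + p t + q = 0."""
    if p == 0 and q == 0:
        return [0.0]
    disc = -4.0 * p**3 - 27.0 * q**2
    try:
        if disc > 0:
            # three distinct real roots: trigonometric method (p < 0 here)
            mag = 2.0 * math.sqrt(-p / 3.0)
            arg = 3.0 * q / (p * mag)
            arg = min(1.0, max(-1.0, arg))
            base = math.acos(arg) / 3.0
            return [mag * math.cos(base - 2.0 * math.pi * k / 3.0) for k in range(3)]
        if disc == 0:
            # repeated roots
            if q == 0:
                r = math.sqrt(-p) if p < 0 else 0.0
                return sorted({-r, 0.0, r}) if p < 0 else [0.0]
            double = -3.0 * q / (2.0 * p)
            simple = 3.0 * q / p
            return sorted({double, simple})
        # one real root: Cardano
        half_q = q / 2.0
        shift = math.sqrt(half_q**2 + (p / 3.0) ** 3)
        return [math.cbrt(-half_q + shift) + math.cbrt(-half_q - shift)]
    except (ValueError, OverflowError):
        roots = np.roots([1.0, 0.0, p, q])
        return [float(r.real) for r in roots if abs(r.imag) < 1e-9 * max(1.0, abs(r))]
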