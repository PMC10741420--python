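"""Torus-knot (Hopfion) reduction of the DNA free energy.

A closed DNA knot with linking number Lk is mapped onto a torus knot —
a Hopfion with Hopf charge W = P*Q = Lk, toroidal winding P and poloidal
winding Q — through the angle map

    theta = 2R,   phi = P*varphi + Q*Theta,   chi = P*varphi - Q*Theta,

where varphi and Theta are the toroidal and poloidal angles on the torus
and R is the (constant) bending angle of the helix axis, 0 < R < 90 deg.
With constant rates m = d(varphi)/ds, n = d(Theta)/ds and dR/ds = 0 the
Landau density collapses to the closed form, in reduced units,

    F(P) = (B/2) (Pm + (W/P) n)^2 sin^2(2R)
         + 2C   (Pm cos^2 R - (W/P) n sin^2 R)^2

The torsion factor carries a minus sign: it follows from the
-2PQ (dvarphi/ds)(dTheta/ds) sin^2(2R) cross term of the torsional part
of the expanded density, and is the form that reproduces the known
nucleosome minima (~938 kBT/b at P = 1.9 for R = 18 deg, ~1071 at
P = 2.1 for R = 22 deg).  The total energy of a molecule of reduced
length b is simply E = F * b since F is s-independent.

P enters as a magnitude (the wrap number |Wr|); profiles use the
continuous relaxation Q = W/P, while :func:`integer_minimum` restricts
to the integer factorizations of W.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .elasticity import ElasticConstants
from .topology import hopf_factorizations

__all__ = [
    "HopfionConfig",
    "EnergyProfile",
    "map_angles",
    "map_angle_rates",
    "free_energy",
    "total_energy",
    "profile",
    "integer_minimum",
]

_PQ_TOL = 1e-9


@dataclass(frozen=True)
class HopfionConfig:
    """A torus-knot state of closed DNA.

    Parameters
    ----------
    w : float
        Hopf charge = linking number; positive, integer in canonical use.
    p : float
        Toroidal winding; positive, continuous in profile scans.
    q : float
        Poloidal winding; must satisfy p*q = w. Defaults to w/p.
    r_deg : float
        Bending angle R in degrees, open interval (0, 90).
    m, n : float
        Constant rates d(varphi)/ds and d(Theta)/ds in reduced units
        (default 1: toroidal and poloidal angles advance equally).
    """

    w: float
    p: float
    r_deg: float
    q: float = None
    m: float = 1.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError(f"w must be > 0, got {self.w}")
        if not self.p > 0:
            raise ValueError(f"p must be > 0, got {self.p}")
        if self.q is None:
            object.__setattr__(self, "q", self.w / self.p)
        elif abs(self.p * self.q - self.w) > _PQ_TOL:
            raise ValueError(f"p*q = {self.p * self.q} does not match w = {self.w}")
        if not (0.0 < self.r_deg < 90.0):
            raise ValueError(f"r_deg must be in (0, 90), got {self.r_deg}")
        for name in ("m", "n"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def r_rad(self) -> float:
        return math.radians(self.r_deg)


@dataclass(frozen=True)
class EnergyProfile:
    """Sampled free-energy curve F(P) with its (refined) minimum.

    ``p_grid``/``f_values`` hold the raw scan; ``p_min_grid``/``f_min_grid``
    the best grid point; ``p_min``/``f_min`` the bounded-minimization
    refinement around it.  Energies are reduced (kBT per unit arc length).
    """

    p_grid: np.ndarray
    f_values: np.ndarray
    p_min_grid: float
    f_min_grid: float
    p_min: float
    f_min: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.p_grid, dtype=float)
        f = np.asarray(self.f_values, dtype=float)
        if p.size == 0:
            raise ValueError("empty profile grid")
        if p.size != f.size:
            raise ValueError("p_grid and f_values must have equal length")
        if np.any(p <= 0) or np.any(np.diff(p) <= 0):
            raise ValueError("p_grid must be strictly increasing and positive")
        if np.any(f < 0):
            raise ValueError("free energies must be non-negative")
        if self.f_min > self.f_min_grid + 1e-9:
            raise ValueError("refined minimum exceeds grid minimum")
        object.__setattr__(self, "p_grid", p)
        object.__setattr__(self, "f_values", f)

    def __len__(self) -> int:
        return self.p_grid.size


def map_angles(r_rad: float, p: float, q: float,
               phi_coord: float, theta_coord: float) -> tuple[float, float, float]:
    """Euler angles (theta, phi, chi) of the torus-knot state.

    theta = 2R, phi = P*varphi + Q*Theta, chi = P*varphi - Q*Theta, where
    (varphi, Theta) are the toroidal/poloidal coordinates.
    """
    if not (0.0 < r_rad < math.pi / 2.0):
        raise ValueError(f"r_rad must be in (0, pi/2), got {r_rad}")
    theta = 2.0 * r_rad
    phi = p * phi_coord + q * theta_coord
    chi = p * phi_coord - q * theta_coord
    return theta, phi, chi


def map_angle_rates(p: float, q: float, m: float, n: float) -> tuple[float, float, float]:
    """Arc-length derivatives of the mapped Euler angles.

    With dR/ds = 0 and constant rates m, n:
    dtheta/ds = 0, dphi/ds = Pm + Qn, dchi/ds = Pm - Qn.
    """
    return 0.0, p * m + q * n, p * m - q * n


def free_energy(config: HopfionConfig, constants: ElasticConstants) -> float:
    """Closed-form reduced free energy per unit arc length of a Hopfion state.

    F = (B/2)(Pm + Qn)^2 sin^2(2R) + 2C (Pm cos^2 R - Qn sin^2 R)^2
    with Q = W/P and B, C the reduced rigidities. Always >= 0.
    """
    return _free_energy_raw(
        config.p, config.w, config.r_rad, config.m, config.n,
        constants.B_red, constants.C_red,
    )


def _free_energy_raw(p, w, r_rad, m, n, B, C):
    """Vectorized closed form; ``p`` may be an array."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("P must be strictly positive")
    q = w / p
    bend = 0.5 * B * (p * m + q * n) ** 2 * np.sin(2.0 * r_rad) ** 2
    tors = 2.0 * C * (p * m * np.cos(r_rad) ** 2 - q * n * np.sin(r_rad) ** 2) ** 2
    out = bend + tors
    return out if out.ndim else float(out)


def total_energy(f: float, b: float) -> float:
    """Total elastic energy E = F * b of a molecule of reduced length b.

    Valid because F is s-independent (constant R, m, n along the knot).
    """
    if b < 0:
        raise ValueError(f"b must be >= 0, got {b}")
    return f * b


def profile(
    w: float,
    r_deg: float,
    m: float = 1.0,
    n: float = 1.0,
    constants: ElasticConstants | None = None,
    p_start: float = 0.5,
    p_stop: float | None = None,
    p_step: float = 0.1,
) -> EnergyProfile:
    """Scan F(P) over a P grid and refine the minimum.

    The grid runs from ``p_start`` to ``p_stop`` (default: W) in steps of
    ``p_step``, endpoints included; Q = W/P is continuous.  The minimum
    is refined from the best grid point by bounded scalar minimization
    (Brent, xatol 1e-8) on the bracketing interval.
    """
    if constants is None:
        constants = ElasticConstants()
    if p_stop is None:
        p_stop = float(w)
    if not (0.0 < p_start < p_stop):
        raise ValueError(f"need 0 < p_start < p_stop, got {p_start}, {p_stop}")
    if not p_step > 0:
        raise ValueError(f"p_step must be > 0, got {p_step}")
    n_steps = int(round((p_stop - p_start) / p_step))
    grid = p_start + p_step * np.arange(n_steps + 1)
    grid = grid[grid <= p_stop + 1e-12]
    if grid.size == 0:
        raise ValueError("empty profile grid")
    r_rad = math.radians(r_deg)
    if not (0.0 < r_deg < 90.0):
        raise ValueError(f"r_deg must be in (0, 90), got {r_deg}")
    B, C = constants.B_red, constants.C_red
    f_values = _free_energy_raw(grid, w, r_rad, m, n, B, C)

    i = int(np.argmin(f_values))
    p_min_grid = float(grid[i])
    f_min_grid = float(f_values[i])

    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if lo == hi:
        p_min, f_min = p_min_grid, f_min_grid
    else:
        res = minimize_scalar(
            lambda p: _free_energy_raw(p, w, r_rad, m, n, B, C),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        p_min, f_min = float(res.x), float(res.fun)
        if f_min > f_min_grid:  # refinement must never lose to the grid
            p_min, f_min = p_min_grid, f_min_grid

    return EnergyProfile(
        p_grid=grid,
        f_values=f_values,
        p_min_grid=p_min_grid,
        f_min_grid=f_min_grid,
        p_min=p_min,
        f_min=f_min,
        metadata={
            "w": w, "r_deg": r_deg, "m": m, "n": n,
            "B_red": B, "C_red": C,
            "p_start": p_start, "p_stop": p_stop, "p_step": p_step,
        },
    )


def integer_minimum(
    w: int,
    r_deg: float,
    m: float = 1.0,
    n: float = 1.0,
    constants: ElasticConstants | None = None,
) -> tuple[int, float]:
    """Minimize F over the integer factorizations (P, Q) of W.

    Evaluates every ordered pair with P*Q = W and returns (P_best,
    F_best); ties break toward smaller P.  For the canonical nucleosome
    (W = 14, R = 20 deg, m = n = 1) the minimum is at P = 2.
    """
    if constants is None:
        constants = ElasticConstants()
    r_rad = math.radians(r_deg)
    if not (0.0 < r_deg < 90.0):
        raise ValueError(f"r_deg must be in (0, 90), got {r_deg}")
    best_p, best_f = None, math.inf
    for p, q in hopf_factorizations(w):
        f = _free_energy_raw(float(p), w, r_rad, m, n,
                             constants.B_red, constants.C_red)
        if f < best_f:
            best_p, best_f = p, f
    return best_p, best_f
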