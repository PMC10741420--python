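"""Euler-angle Landau free-energy density for DNA conformations.

The conformation of the double helix is encoded in a two-component
complex order parameter Psi built from the Euler angles (phi, theta,
chi) of the helix axis frame.  Substituting Psi into the gradient
Landau expansion with coefficients k1 = 4B, k1 + k2 = 4C yields the
density, per unit arc length s,

    F = (B/2) [ (dtheta/ds)^2 + (dphi/ds)^2 sin^2(theta) ]
      + (C/2) [ (dphi/ds) cos(theta) + dchi/ds ]^2

whose bending term is the squared curvature of the helix axis and whose
torsional term is the squared torsion tau = (dphi/ds) cos(theta) + dchi/ds.
Integrating tau/2pi along the molecule gives the twist number Tw.

This module is the ground truth that the torus-knot closed form in
:mod:`hopfdna.hopfion` is verified against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elasticity import ElasticConstants

__all__ = [
    "OrderParameter",
    "EulerPath",
    "order_parameter",
    "euler_rotation",
    "free_energy_density_euler",
    "torsion",
    "twist_number",
]

_NORM_TOL = 1e-12
_THETA_TOL = 1e-9


@dataclass(frozen=True)
class OrderParameter:
    """Two-component complex order parameter of a DNA conformation.

    c1 describes the superhelix (axis conformation); c2 the internal
    base-pair winding.  |c1|^2 + |c2|^2 = 1 by construction.
    """

    c1: complex
    c2: complex

    def __post_init__(self) -> None:
        norm = abs(self.c1) ** 2 + abs(self.c2) ** 2
        if abs(norm - 1.0) >= _NORM_TOL:
            raise ValueError(f"order parameter not normalised: |Psi|^2 = {norm}")


def order_parameter(phi: float, theta: float, chi: float) -> OrderParameter:
    """Order parameter from the Euler angles (radians).

    Psi = ( cos(theta/2) e^{-i(phi+chi)/2},  sin(theta/2) e^{i(phi-chi)/2} ),
    equivalently the Euler rotation applied to the reference state (1, 0).
    """
    half = theta / 2.0
    c1 = np.cos(half) * np.exp(-0.5j * (phi + chi))
    c2 = np.sin(half) * np.exp(0.5j * (phi - chi))
    return OrderParameter(complex(c1), complex(c2))


def euler_rotation(phi: float, theta: float, chi: float) -> np.ndarray:
    """SU(2) Euler rotation matrix T(phi, theta, chi).

    Applying T to the reference spinor (1, 0)^T reproduces
    :func:`order_parameter`; used as the independent construction in
    verification.
    """
    half = theta / 2.0
    c, s = np.cos(half), np.sin(half)
    return np.array(
        [
            [c * np.exp(-0.5j * (phi + chi)), s * np.exp(-0.5j * (phi - chi))],
            [s * np.exp(0.5j * (phi - chi)), c * np.exp(0.5j * (phi + chi))],
        ]
    )


@dataclass(frozen=True)
class EulerPath:
    """Sampled Euler-angle path along the DNA arc length.

    All arrays share one length (>= 2); ``s`` is strictly increasing in
    reduced arc-length units.  Derivatives may be supplied; missing ones
    are filled by second-order central differences (``numpy.gradient``).
    theta must stay inside the open interval (0, pi) (pole frames are
    degenerate), enforced to 1e-9 at the endpoints.
    """

    s: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    chi: np.ndarray
    dphi: np.ndarray = None
    dtheta: np.ndarray = None
    dchi: np.ndarray = None

    def __post_init__(self) -> None:
        arrays = {
            "s": np.asarray(self.s, dtype=float),
            "phi": np.asarray(self.phi, dtype=float),
            "theta": np.asarray(self.theta, dtype=float),
            "chi": np.asarray(self.chi, dtype=float),
        }
        n = arrays["s"].size
        if n < 2:
            raise ValueError("EulerPath needs at least 2 samples")
        for name, arr in arrays.items():
            if arr.ndim != 1 or arr.size != n:
                raise ValueError(f"{name} must be 1-D of length {n}")
        if np.any(np.diff(arrays["s"]) <= 0):
            raise ValueError("s must be strictly increasing")
        th = arrays["theta"]
        if np.any(th < _THETA_TOL) or np.any(th > np.pi - _THETA_TOL):
            raise ValueError("theta must lie in the open interval (0, pi)")
        for name in ("dphi", "dtheta", "dchi"):
            given = getattr(self, name)
            if given is None:
                d = np.gradient(arrays[name.lstrip("d")], arrays["s"])
            else:
                d = np.asarray(given, dtype=float)
                if d.shape != (n,):
                    raise ValueError(f"{name} must be 1-D of length {n}")
            object.__setattr__(self, name, d)
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.s.size


def free_energy_density_euler(
    theta,
    dtheta_ds,
    dphi_ds,
    dchi_ds,
    constants: ElasticConstants | None = None,
    *,
    B: float | None = None,
    C: float | None = None,
):
    """Landau free-energy density at one (or many) Euler-angle samples.

    Returns, per unit arc length and in the units of B and C
    (reduced kBT units when taken from ``constants``),

        (B/2) [ dtheta^2 + dphi^2 sin^2 theta ] + (C/2) [ dphi cos theta + dchi ]^2

    which is non-negative for positive rigidities.  Accepts scalars or
    equal-shaped arrays.
    """
    if constants is not None:
        B, C = constants.B_red, constants.C_red
    if B is None or C is None:
        raise ValueError("supply either constants or both B and C")
    theta = np.asarray(theta, dtype=float)
    dtheta = np.asarray(dtheta_ds, dtype=float)
    dphi = np.asarray(dphi_ds, dtype=float)
    dchi = np.asarray(dchi_ds, dtype=float)
    bend = dtheta**2 + dphi**2 * np.sin(theta) ** 2
    tors = torsion(dphi, theta, dchi)
    out = 0.5 * B * bend + 0.5 * C * tors**2
    return out if out.ndim else float(out)


def torsion(dphi_ds, theta, dchi_ds):
    """Torsion of the helix per unit arc length: tau = dphi cos(theta) + dchi."""
    return np.asarray(dphi_ds) * np.cos(np.asarray(theta)) + np.asarray(dchi_ds)


def twist_number(path: EulerPath) -> float:
    """Twist Tw = (1/2pi) * integral of the torsion along the path.

    Trapezoidal quadrature on the caller's grid; second-order accurate
    in the grid spacing for smooth paths.
    """
    tau = torsion(path.dphi, path.theta, path.dchi)
    return float(np.trapezoid(tau, path.s) / (2.0 * np.pi))
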