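"""Topological descriptors of closed circular (nucleosomal) DNA.

Nucleosomal DNA is treated as closed circular DNA (histone H1 locks the
entry/exit points), so its linking number Lk is a topological invariant
obeying White's formula Lk = Wr + Tw.  The writhe Wr measures the coiling
of the helix axis in space (negative for a left-handed superhelical wrap,
the sense found in nucleosome core particles); the twist Tw counts turns
of the double helix about its own axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DNAGeometry",
    "TopologyState",
    "linking_number",
    "writhe_from_wrap",
    "twist_from_white",
    "bend_angle_per_pitch",
    "hopf_factorizations",
]

#: Tolerance to which White's formula Lk = Wr + Tw must hold on construction.
WHITE_TOL = 1e-12

#: Residual allowed when rounding a real linking number to an integer.
INTEGER_LK_TOL = 1e-9


@dataclass(frozen=True)
class DNAGeometry:
    """Geometric parameters of B-DNA wrapped on a nucleosome core particle.

    Parameters
    ----------
    n_bp : int
        Number of base pairs of the (closed) nucleosomal DNA. Must be >= 1.
    bp_per_turn : float
        Base pairs per turn of the double helix (canonical B-DNA: 10.5).
    rise_per_bp : float
        Distance between adjacent base pairs, nm (B-DNA: 0.34).
    dna_diameter : float
        Diameter of the double-helix cross section, nm (B-DNA: 2.0).
    ncp_diameter : float
        Diameter of the nucleosome core particle, nm (canonical: 11.0).
    superhelix_pitch : float
        Pitch of the superhelical wrap, nm (canonical: 2.8).
    """

    n_bp: float
    bp_per_turn: float = 10.5
    rise_per_bp: float = 0.34
    dna_diameter: float = 2.0
    ncp_diameter: float = 11.0
    superhelix_pitch: float = 2.8

    def __post_init__(self) -> None:
        if self.n_bp < 1:
            raise ValueError(f"n_bp must be >= 1, got {self.n_bp}")
        for name in ("bp_per_turn", "rise_per_bp", "dna_diameter",
                     "ncp_diameter", "superhelix_pitch"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")

    @property
    def superhelix_radius(self) -> float:
        """Radius of the circle traced by the DNA helix axis, nm.

        The axis sits midway between the NCP surface and the particle
        centre: (ncp_diameter - dna_diameter) / 2, i.e. 4.5 nm for the
        canonical 11 nm particle wrapped by 2 nm DNA.
        """
        return (self.ncp_diameter - self.dna_diameter) / 2.0

    @property
    def contour_length(self) -> float:
        """Contour length of the DNA, nm."""
        return self.n_bp * self.rise_per_bp


@dataclass(frozen=True)
class TopologyState:
    """(Lk, Wr, Tw) triple of a closed DNA, validated against White's formula.

    Attributes
    ----------
    lk : float
        Linking number. Real in general; integer when n_bp/bp_per_turn
        is exact.
    wr : float
        Writhe; signed, negative for a left-handed superhelical wrap.
    tw : float
        Twist.
    bend_angle_deg : float
        Average bending angle per unit arc length (one superhelical
        pitch), degrees; in (0, 360].
    """

    lk: float
    wr: float
    tw: float
    bend_angle_deg: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if abs(self.lk - (self.wr + self.tw)) >= WHITE_TOL:
            raise ValueError(
                "White's formula violated: "
                f"Lk={self.lk} != Wr+Tw={self.wr + self.tw}"
            )
        if not math.isnan(self.bend_angle_deg):
            if not (0.0 < self.bend_angle_deg <= 360.0):
                raise ValueError(
                    f"bend_angle_deg must lie in (0, 360], got {self.bend_angle_deg}"
                )

    @property
    def lk_int(self) -> int:
        """Linking number as an exact integer.

        Raises
        ------
        ValueError
            If lk is farther than 1e-9 from the nearest integer.
        """
        nearest = round(self.lk)
        if abs(self.lk - nearest) > INTEGER_LK_TOL:
            raise ValueError(f"linking number {self.lk} is not integral")
        return int(nearest)

    @classmethod
    def from_wrap(cls, geometry: DNAGeometry, turns: float,
                  handedness: str = "left") -> "TopologyState":
        """Build the topology of a wrapped DNA from its geometry and wrap.

        Lk comes from the base-pair count, Wr from the signed wrap turns,
        Tw from White's formula, and the bend angle from |Wr| and Tw.
        """
        lk = linking_number(geometry)
        wr = writhe_from_wrap(turns, handedness)
        tw = twist_from_white(lk, wr)
        bend = bend_angle_per_pitch(abs(wr), tw) if turns > 0 else float("nan")
        return cls(lk=lk, wr=wr, tw=tw, bend_angle_deg=bend)


def linking_number(geometry: DNAGeometry) -> float:
    """Linking number Lk = N / n_i of closed circular DNA.

    N is the total number of base pairs and n_i the base pairs per
    double-helix turn.  Returned exactly, without rounding: 147 bp of
    B-DNA at 10.5 bp/turn gives Lk = 14; 63 bp gives Lk = 6.
    """
    return geometry.n_bp / geometry.bp_per_turn


def writhe_from_wrap(turns: float, handedness: str) -> float:
    """Signed writhe of a superhelical wrap of ``turns`` turns.

    Left-handed wraps (the nucleosomal sense) are negative: 1.75 turns
    left-handed gives Wr = -1.75.
    """
    if turns < 0:
        raise ValueError(f"turns must be >= 0, got {turns}")
    if handedness not in ("left", "right"):
        raise ValueError(f"handedness must be 'left' or 'right', got {handedness!r}")
    return -turns if handedness == "left" else turns


def twist_from_white(lk: float, wr: float) -> float:
    """Twist from White's formula: Tw = Lk - Wr.

    For the canonical nucleosome, Tw = 14 - (-1.75) = 15.75.
    """
    return lk - wr


def bend_angle_per_pitch(wr_magnitude: float, tw: float) -> float:
    """Average bending angle per superhelical pitch, degrees.

    theta = |Wr| * 360 / Tw.  The magnitude of the writhe is used: the
    canonical 40 degrees comes from 1.75, not -1.75.
    """
    if not wr_magnitude > 0:
        raise ValueError(f"wr_magnitude must be > 0, got {wr_magnitude}")
    if not tw > 0:
        raise ValueError(f"tw must be > 0, got {tw}")
    return wr_magnitude * 360.0 / tw


def hopf_factorizations(w: int) -> list[tuple[int, int]]:
    """All ordered positive-integer pairs (P, Q) with P * Q = w, sorted by P.

    These are the integer torus-knot windings compatible with Hopf
    charge w: e.g. w = 14 admits (1,14), (2,7), (7,2), (14,1).
    """
    if isinstance(w, float) and not w.is_integer():
        raise ValueError(f"w must be an integer, got {w}")
    w = int(w)
    if w < 1:
        raise ValueError(f"w must be >= 1, got {w}")
    pairs = []
    for p in range(1, w + 1):
        if w % p == 0:
            pairs.append((p, w // p))
    return pairs
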