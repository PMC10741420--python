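"""Preset nucleosome scenarios.

Each scenario fixes the geometry and wrap of a nucleosomal DNA together
with the torus-knot bending angle R and rates m, n, so that one call
reproduces a complete set of inputs: the canonical 147-bp nucleosome
(1.75 left-handed wrap turns, Lk = 14, R = 20 deg), the short 63-bp
construct (0.75 turns, Lk = 6), the 168-bp (2 turns, Lk = 16) and
189-bp (2.25 turns, Lk = 18) variants, plus R-variants of the canonical
particle at 5/12/18/22/30 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .elasticity import ElasticConstants
from .hopfion import EnergyProfile, integer_minimum, profile
from .topology import DNAGeometry, TopologyState

__all__ = ["Scenario", "PRESETS", "get_preset", "run_scenario"]


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified nucleosomal-DNA input set."""

    name: str
    geometry: DNAGeometry
    wrap_turns: float
    handedness: str = "left"
    r_deg: float = 20.0
    m: float = 1.0
    n: float = 1.0
    description: str = ""

    def topology(self) -> TopologyState:
        return TopologyState.from_wrap(self.geometry, self.wrap_turns, self.handedness)


def _scenario(name, n_bp, turns, r_deg, description):
    return Scenario(
        name=name,
        geometry=DNAGeometry(n_bp=n_bp),
        wrap_turns=turns,
        r_deg=r_deg,
        description=description,
    )


PRESETS: dict[str, Scenario] = {
    s.name: s
    for s in [
        _scenario("nucleosome147", 147, 1.75, 20.0,
                  "Canonical nucleosome: 147 bp, 1.75 left-handed turns, Lk=14, R=20 deg"),
        _scenario("short63", 63, 0.75, 20.0,
                  "Short construct: 63 bp, 0.75 turns, Lk=6"),
        _scenario("long168", 168, 2.0, 20.0,
                  "Long construct: 168 bp, 2 turns, Lk=16"),
        _scenario("long189", 189, 2.25, 20.0,
                  "Long construct: 189 bp, 2.25 turns, Lk=18"),
    ]
    + [
        _scenario(f"nucleosome147-r{r:g}", 147, 1.75, float(r),
                  f"Canonical nucleosome at bending angle R={r} deg")
        for r in (5, 12, 18, 22, 30)
    ]
}


def get_preset(name: str) -> Scenario:
    """Look up a preset scenario by name."""
    try:
        return PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; available presets: {known}") from None


def run_scenario(
    scenario: Scenario,
    constants: ElasticConstants | None = None,
    p_step: float = 0.1,
) -> dict:
    """Topology summary, F(P) profile and integer-P minimum for one scenario.

    Deterministic: identical inputs give identical reports.
    """
    if constants is None:
        constants = ElasticConstants()
    topo = scenario.topology()
    w = topo.lk_int
    prof = profile(w=w, r_deg=scenario.r_deg, m=scenario.m, n=scenario.n,
                   constants=constants, p_step=p_step)
    p_best, f_best = integer_minimum(w, scenario.r_deg, scenario.m,
                                     scenario.n, constants)
    return {
        "scenario": scenario.name,
        "description": scenario.description,
        "topology": {
            "lk": topo.lk,
            "wr": topo.wr,
            "tw": topo.tw,
            "bend_angle_deg": topo.bend_angle_deg,
            "superhelix_radius_nm": scenario.geometry.superhelix_radius,
        },
        "profile": {
            "p_min": prof.p_min,
            "f_min": prof.f_min,
            "p_min_grid": prof.p_min_grid,
            "f_min_grid": prof.f_min_grid,
            "params": prof.metadata,
        },
        "integer_minimum": {"p": p_best, "f": f_best},
        "_profile_object": prof,
    }
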