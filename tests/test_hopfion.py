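"""Torus-knot closed form: mapping, energies, profiles, integer minima."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hopfdna import (
    ElasticConstants,
    HopfionConfig,
    free_energy,
    free_energy_density_euler,
    integer_minimum,
    map_angle_rates,
    map_angles,
    profile,
    total_energy,
)
from hopfdna.hopfion import _free_energy_raw

configs = st.tuples(
    st.floats(0.2, 20),        # p
    st.floats(0.2, 30),        # w
    st.floats(1.0, 89.0),      # r_deg
    st.floats(-3, 3),          # m
    st.floats(-3, 3),          # n
)


def test_map_angles_examples():
    R = 0.4
    assert map_angles(R, 3, 5, 0.0, 0.0) == (2 * R, 0.0, 0.0)
    theta, phi, chi = map_angles(R, 1, 1, 0.7, 0.2)
    assert (theta, phi, chi) == (2 * R, pytest.approx(0.9), pytest.approx(0.5))
    with pytest.raises(ValueError):
        map_angles(math.pi / 2, 1, 1, 0, 0)


def test_map_angle_rates_linearity():
    dtheta, dphi, dchi = map_angle_rates(p=2, q=7, m=1.5, n=0.5)
    assert dtheta == 0.0
    assert dphi == pytest.approx(2 * 1.5 + 7 * 0.5)
    assert dchi == pytest.approx(2 * 1.5 - 7 * 0.5)


@pytest.mark.parametrize(
    "p, r_deg, expected",
    [(2.1, 22.0, 1071), (1.9, 18.0, 938)],
)
def test_free_energy_nucleosome_minima(p, r_deg, expected, constants):
    """The closed form reproduces the canonical nucleosome energies (W=14)."""
    cfg = HopfionConfig(w=14, p=p, r_deg=r_deg)
    assert round(free_energy(cfg, constants)) == expected


@given(configs)
def test_closed_form_matches_euler_density(params):
    """Central correctness property: the closed form equals the Landau
    density evaluated on the mapped Euler-angle derivatives."""
    p, w, r_deg, m, n = params
    q = w / p
    r_rad = math.radians(r_deg)
    dtheta, dphi, dchi = map_angle_rates(p, q, m, n)
    theta = 2 * r_rad
    via_landau = free_energy_density_euler(theta, dtheta, dphi, dchi, B=50, C=95)
    closed = _free_energy_raw(p, w, r_rad, m, n, 50, 95)
    assert closed == pytest.approx(via_landau, rel=1e-9, abs=1e-9)


@given(configs)
def test_duality_swap(params):
    """F is invariant under (P, m) <-> (Q, n) with R -> 90 deg - R."""
    p, w, r_deg, m, n = params
    q = w / p
    f1 = _free_energy_raw(p, w, math.radians(r_deg), m, n, 50, 95)
    f2 = _free_energy_raw(q, w, math.radians(90 - r_deg), n, m, 50, 95)
    assert f2 == pytest.approx(f1, rel=1e-9, abs=1e-9)


def test_limits_at_r_extremes(constants):
    """R -> 0 gives pure toroidal torsion 2C(Pm)^2; R -> 90 gives 2C(Qn)^2."""
    p, w, m, n = 3.0, 12.0, 1.3, 0.7
    q = w / p
    C = constants.C_red
    f0 = _free_energy_raw(p, w, math.radians(1e-6), m, n, 50, C)
    f90 = _free_energy_raw(p, w, math.radians(90 - 1e-6), m, n, 50, C)
    assert f0 == pytest.approx(2 * C * (p * m) ** 2, rel=1e-6)
    assert f90 == pytest.approx(2 * C * (q * n) ** 2, rel=1e-6)


def test_total_energy():
    assert total_energy(1071.0, 1.0) == 1071.0
    assert total_energy(500.0, 0.0) == 0.0
    assert total_energy(500.0, 2.0) == 2 * total_energy(500.0, 1.0)
    with pytest.raises(ValueError):
        total_energy(500.0, -1.0)


@pytest.mark.parametrize(
    "r_deg, p_expect, f_expect",
    [(22.0, 2.1, 1071), (18.0, 1.9, 938)],
)
def test_profile_grid_minima(r_deg, p_expect, f_expect, constants):
    """Grid scan at step 0.1 recovers the published argmin and minimum."""
    prof = profile(w=14, r_deg=r_deg, constants=constants)
    assert prof.p_min_grid == pytest.approx(p_expect, abs=1e-9)
    assert round(prof.f_min_grid) == f_expect
    assert len(prof) == 136  # [0.5, 14] at step 0.1


def test_profile_refinement_vs_brute_force(constants):
    """The refined argmin matches a dense step-1e-4 brute-force scan."""
    prof = profile(w=14, r_deg=20.0, constants=constants)
    dense = np.arange(0.5, 14.0, 1e-4)
    f = _free_energy_raw(dense, 14, math.radians(20.0), 1, 1, 50, 95)
    p_brute = dense[np.argmin(f)]
    assert prof.p_min == pytest.approx(p_brute, abs=1e-3)
    assert prof.f_min <= prof.f_min_grid + 1e-9
    assert prof.f_min <= f.min() + 1e-6


def test_integer_minimum_canonical(constants):
    """Among P in {1, 2, 7, 14} at R = 20 deg the minimum is P = 2."""
    p_best, f_best = integer_minimum(14, 20.0, constants=constants)
    assert p_best == 2
    assert f_best == pytest.approx(1007.146907565359, rel=1e-12)


def test_integer_minimum_single_candidate(constants):
    assert integer_minimum(1, 30.0, constants=constants)[0] == 1


def test_integer_minimum_vs_exhaustive(constants):
    """W = 12: the reported argmin equals brute-force over all 6 divisor pairs."""
    values = {
        p: _free_energy_raw(float(p), 12, math.radians(20.0), 1, 1, 50, 95)
        for p in (1, 2, 3, 4, 6, 12)
    }
    expect = min(values, key=values.get)
    assert integer_minimum(12, 20.0, constants=constants)[0] == expect


def test_minimum_increases_with_bend_angle(constants):
    """Steeper wrapping costs more: f_min grows with R, and so does argmin P."""
    mins = [profile(w=14, r_deg=r, constants=constants) for r in (18.0, 20.0, 22.0)]
    f = [m.f_min for m in mins]
    p = [m.p_min for m in mins]
    assert f == sorted(f) and len(set(f)) == 3
    assert p == sorted(p) and len(set(p)) == 3


def test_minimum_increases_with_linking_number(constants):
    """Longer wrapped DNA (larger Lk) raises the minimum free energy."""
    f = [profile(w=w, r_deg=20.0, constants=constants).f_min
         for w in (6, 14, 16, 18)]
    assert f == sorted(f) and len(set(f)) == 4


def test_config_validation():
    with pytest.raises(ValueError):
        HopfionConfig(w=14, p=0, r_deg=20)
    with pytest.raises(ValueError):
        HopfionConfig(w=14, p=2, r_deg=95)
    with pytest.raises(ValueError):
        HopfionConfig(w=14, p=2, q=3, r_deg=20)  # p*q != w
    cfg = HopfionConfig(w=14, p=2, r_deg=20)
    assert cfg.q == 7.0


def test_profile_validation(constants):
    with pytest.raises(ValueError):
        profile(w=14, r_deg=20, p_start=5, p_stop=1, constants=constants)
    with pytest.raises(ValueError):
        profile(w=14, r_deg=20, p_step=-0.1, constants=constants)
    with pytest.raises(ValueError):
        _free_energy_raw(-1.0, 14, 0.3, 1, 1, 50, 95)
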