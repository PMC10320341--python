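"""Network thermodynamics and the homogeneous fixed point."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from turingtherm.model import (
    DiffusionConstants,
    IrreversibleLimitError,
    RateConstants,
    all_fixed_points,
    build_network,
    compute_thermo,
    effective_rates,
    homogeneous_fixed_point,
)
from turingtherm.presets import GAMMA_ROBUSTNESS


def test_equilibrium_rates_have_unit_cycle_parameters(equilibrium_rates):
    th = compute_thermo(equilibrium_rates)
    assert th.Gamma == pytest.approx(1.0)
    assert th.GammaPrime == pytest.approx(1.0)
    assert th.W == pytest.approx(0.0, abs=1e-12)


def test_gamma_prime_matches_hand_arithmetic(accuracy):
    # k13*k32*k21 / (k12*k23*k31) with the reference parameter values
    r = accuracy.rates
    expected = (0.0139 * 1.39e-5 * 3.6) / (0.5 * 0.0139 * 0.0416)
    assert compute_thermo(r).GammaPrime == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(2.40577e-3, rel=1e-4)


def test_robustness_preset_kt12_round_trips_gamma(robustness):
    # kt12 is derived from the declared Gamma; the round trip must close
    th = compute_thermo(robustness.rates)
    assert th.Gamma == pytest.approx(GAMMA_ROBUSTNESS, rel=1e-12)


def test_irreversible_limit_refused():
    r = RateConstants(k12=0.5, k21=3.6, k23=0.01, k32=1e-5, k31=0.04,
                      k13=0.01, kt12=1e-5, kt21=0.0)
    with pytest.raises(IrreversibleLimitError):
        compute_thermo(r)


@given(scale=st_h.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_gamma_invariant_under_uniform_rate_rescaling(scale):
    r = RateConstants(k12=0.5, k21=3.6, k23=0.0139, k32=1.39e-5,
                      k31=0.0416, k13=0.0139, kt12=1.67e-5, kt21=1e-6)
    r2 = RateConstants(**{f: getattr(r, f) * scale for f in
                          ("k12", "k21", "k23", "k32", "k31", "k13", "kt12", "kt21")})
    t1, t2 = compute_thermo(r), compute_thermo(r2)
    assert t1.Gamma == pytest.approx(t2.Gamma, rel=1e-9)
    assert t1.GammaPrime == pytest.approx(t2.GammaPrime, rel=1e-9)


def test_W_strictly_decreasing_in_kt21(accuracy):
    kts = [1e-7, 1e-6, 1e-5]
    Ws = [compute_thermo(accuracy.rates.with_(kt21=k)).W for k in kts]
    assert Ws[0] > Ws[1] > Ws[2]


def test_effective_rates():
    r = RateConstants(k12=0.5, k21=3.6, k23=0.0139, k32=1.39e-5,
                      k31=0.0416, k13=0.0139, kt12=1.67e-5, kt21=1.67e-5)
    assert effective_rates(r, 0.0) == (0.0, 0.0)
    b12, b21 = effective_rates(r, 7200 / 6.0)
    assert b12 == pytest.approx(1.67e-5 * 1200**2, rel=1e-12)
    # doubling N quadruples beta
    b12_2, _ = effective_rates(r, 2 * 1200.0)
    assert b12_2 == pytest.approx(4 * b12, rel=1e-12)


def test_equilibrium_fixed_point_satisfies_detailed_balance(equilibrium_rates):
    fp = homogeneous_fixed_point(equilibrium_rates, 1200.0)
    net = build_network(equilibrium_rates, DiffusionConstants(D1=0.3, D2=0.012))
    jf, jb = net.fluxes(fp.as_array())
    # every reaction individually balanced at equilibrium
    assert np.allclose(jf, jb, rtol=1e-8)


def test_fixed_point_agrees_with_ode_relaxation(accuracy):
    from scipy.integrate import solve_ivp

    from turingtherm.model import _wellmixed_rhs

    rng = np.random.default_rng(7)
    c_tot = 1200.0
    fp = homogeneous_fixed_point(accuracy.rates, c_tot)
    for _ in range(3):
        w = rng.dirichlet([1.0, 1.0, 1.0]) * c_tot
        sol = solve_ivp(_wellmixed_rhs(accuracy.rates), (0, 2e5), w,
                        method="LSODA", rtol=1e-10, atol=1e-8)
        end = sol.y[:, -1]
        roots = all_fixed_points(accuracy.rates, c_tot)
        dists = [np.linalg.norm(end - r.as_array()) for r in roots]
        assert min(dists) < 1e-4 * c_tot
        # the relaxed-from-equal-partition convention picks one of them
        assert any(np.allclose(fp.as_array(), r.as_array()) for r in roots)


def test_v2_increases_with_N_for_robustness_rates(robustness):
    v2s = [homogeneous_fixed_point(robustness.rates, N / 6.0).v2
           for N in (1500, 2500, 4000, 7000)]
    assert all(a < b for a, b in zip(v2s, v2s[1:]))


def test_linear_network_limit_scales_with_ctot():
    r = RateConstants(k12=0.5, k21=3.6, k23=0.0139, k32=1.39e-5,
                      k31=0.0416, k13=0.0139, kt12=1e-300, kt21=0.0)
    f1 = homogeneous_fixed_point(r, 100.0)
    f2 = homogeneous_fixed_point(r, 200.0)
    assert np.allclose(2 * f1.as_array(), f2.as_array(), rtol=1e-8)


def test_mass_conservation_of_fixed_points(robustness):
    for N in (1500, 3000, 7200):
        fp = homogeneous_fixed_point(robustness.rates, N / 6.0)
        assert fp.u1 + fp.u2 + fp.u3 == pytest.approx(N / 6.0, rel=1e-9)
        assert min(fp.u1, fp.u2, fp.u3) >= 0
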