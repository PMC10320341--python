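"""Entropy-production accounting: densities, identities, estimators."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from turingtherm.dynamics import ConcentrationField, patterned_steady_state
from turingtherm.model import (
    DiffusionConstants,
    Geometry,
    IrreversibleLimitError,
    homogeneous_fixed_point,
)
from turingtherm.thermo import (
    chem_dissipation,
    cycle_fluxes,
    diff_dissipation,
    diffusive_fraction_estimate,
    dissipation_breakdown,
    total_dissipation_cycleform,
)


def _uniform_field(u_vec, geometry):
    return ConcentrationField(geometry.x, np.outer(u_vec, np.ones(geometry.n_box)))


def test_equilibrium_state_dissipates_nothing(equilibrium_rates, small_geometry):
    fp = homogeneous_fixed_point(equilibrium_rates, 600.0)
    fld = _uniform_field(fp.as_array(), small_geometry)
    assert chem_dissipation(fld, equilibrium_rates).max() < 1e-10
    D = DiffusionConstants(D1=0.3, D2=0.012)
    assert diff_dissipation(fld, D, small_geometry).max() == 0.0
    assert total_dissipation_cycleform(fld, equilibrium_rates) == pytest.approx(0.0)


@given(seed=st_h.integers(min_value=0, max_value=10_000))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_dissipation_densities_nonnegative_on_random_fields(seed):
    from turingtherm.presets import get_preset

    p = get_preset("accuracy")
    rng = np.random.default_rng(seed)
    g = Geometry(L=6.0, n_box=20)
    u = rng.uniform(1.0, 500.0, size=(3, 20))
    fld = ConcentrationField(g.x, u)
    assert chem_dissipation(fld, p.rates).min() >= 0
    assert diff_dissipation(fld, p.diffusion, g, mode="discrete").min() >= 0
    assert diff_dissipation(fld, p.diffusion, g, mode="continuum").min() >= 0


def test_irreversible_flux_refused(accuracy, small_geometry):
    rates = accuracy.rates.with_(kt21=0.0)
    fld = _uniform_field([100.0, 100.0, 100.0], small_geometry)
    with pytest.raises(IrreversibleLimitError):
        chem_dissipation(fld, rates)


def test_discrete_matches_continuum_under_refinement(accuracy):
    """Hop-flux dissipation converges to D (du/dx)^2/u as dx -> 0."""
    gaps = []
    for nbox in (60, 240):
        g = Geometry(L=6.0, n_box=nbox)
        u2 = 300 - 250 * np.cos(2 * np.pi * 3 * g.x / 6.0)
        u = np.vstack([400 + 0 * g.x, u2, 200 + 0 * g.x])
        fld = ConcentrationField(g.x, u)
        tot_d = diff_dissipation(fld, accuracy.diffusion, g, "discrete").sum() * g.dx
        tot_c = diff_dissipation(fld, accuracy.diffusion, g, "continuum").sum() * g.dx
        gaps.append(abs(tot_d - tot_c) / tot_c)
    assert gaps[1] < gaps[0]
    assert gaps[1] < 0.01


def test_cycle_identity_at_patterned_steady_state(robustness):
    """The spatial integral of w_chem + w_diff equals the cycle-flux
    formula at the striped steady state (the central identity)."""
    fld = patterned_steady_state(robustness.rates, robustness.diffusion,
                                 robustness.geometry, 2300 / 6.0, n_stripes=3)
    bd = dissipation_breakdown(fld, robustness.rates, robustness.diffusion,
                               robustness.geometry)
    assert bd.Wdot_total == pytest.approx(bd.Wdot_cycle, rel=1e-3)
    assert bd.r_diff > 0
    # the autocatalytic cycle dominates the dissipation
    assert bd.J1c > 10 * abs(bd.J2c)
    # and the cycle flux equals the integrated autocatalytic net flux
    jf_auto = (robustness.rates.kt12 * fld.u[0] * fld.u[1] ** 2
               - robustness.rates.kt21 * fld.u[1] ** 3)
    assert bd.J1c == pytest.approx(jf_auto.sum() * fld.dx, rel=1e-6)


def test_homogeneous_state_has_zero_diffusive_fraction(robustness):
    fp = homogeneous_fixed_point(robustness.rates, 2300 / 6.0)
    g = robustness.geometry
    fld = _uniform_field(fp.as_array(), g)
    bd = dissipation_breakdown(fld, robustness.rates, robustness.diffusion, g)
    assert bd.r_diff == pytest.approx(0.0, abs=1e-12)
    assert bd.Wdot_chem > 0  # driven chemistry still dissipates


def test_cycleform_warns_off_steady_state(robustness, small_geometry):
    fld = _uniform_field([500.0, 10.0, 10.0], small_geometry)
    with pytest.warns(UserWarning, match="far from steady state"):
        total_dissipation_cycleform(fld, robustness.rates)


def test_diffusive_fraction_estimate_trends(accuracy, small_geometry):
    flat = _uniform_field([100, 100, 100], small_geometry)
    assert diffusive_fraction_estimate(flat, accuracy.rates) == 0.0
    g = small_geometry
    u2 = 120 - 80 * np.cos(2 * np.pi * g.x / 6.0)
    fld = ConcentrationField(g.x, np.vstack([150 + 0 * g.x, u2, 90 + 0 * g.x]))
    e1 = diffusive_fraction_estimate(fld, accuracy.rates.with_(kt21=1e-6))
    e2 = diffusive_fraction_estimate(fld, accuracy.rates.with_(kt21=1e-7))
    assert e2 < e1  # larger W (smaller kt21) -> smaller estimate
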