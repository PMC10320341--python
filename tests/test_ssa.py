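"""Exactness and plumbing of the lattice Gillespie simulator."""
import numpy as np
import pytest

from turingtherm.model import DiffusionConstants, Geometry, RateConstants
from turingtherm.ssa import (
    LatticeState,
    propensities,
    run_ensemble,
    run_ssa,
    uniform_counts,
)
from turingtherm.model import build_network


ZERO_RATES = RateConstants(k12=0, k21=0, k23=0, k32=0, k31=0, k13=0,
                           kt12=1e-300, kt21=0)


def test_propensity_no_flux_boundaries(accuracy):
    g = Geometry(L=6.0, n_box=6)
    counts = np.zeros((3, 6), dtype=np.int64)
    counts[0, 0] = 1   # end box
    counts[1, 3] = 1   # interior box
    chans = propensities(LatticeState(counts), ZERO_RATES,
                         DiffusionConstants(D1=0.3, D2=0.012), g)
    hop = lambda s, b: sum(c.propensity for c in chans
                           if c.kind == "hop" and c.index == s and c.box == b)
    dx2 = g.dx**2
    assert hop(0, 0) == pytest.approx(0.3 / dx2)        # end: inward only
    assert hop(1, 3) == pytest.approx(2 * 0.012 / dx2)  # interior: both ways


def test_backward_autocatalysis_needs_three_molecules(accuracy):
    g = Geometry(L=6.0, n_box=3)
    counts = np.zeros((3, 3), dtype=np.int64)
    counts[1, 1] = 2  # only two X2
    chans = propensities(LatticeState(counts), accuracy.rates,
                         accuracy.diffusion, g)
    back_auto = [c for c in chans if c.kind == "reaction" and c.index == 3
                 and c.direction == -1 and c.box == 1]
    assert back_auto[0].propensity == 0.0
    # forward autocatalysis also zero (no X1 present)
    fwd = [c for c in chans if c.kind == "reaction" and c.index == 3
           and c.direction == 1 and c.box == 1]
    assert fwd[0].propensity == 0.0


def test_identical_seeds_reproduce_bitwise(accuracy, small_geometry):
    init = uniform_counts(600, [1, 1, 1], small_geometry, seed=5)
    k1 = run_ssa(init, accuracy.rates, accuracy.diffusion, small_geometry,
                 5.0, 0.5, seed=42)
    init2 = uniform_counts(600, [1, 1, 1], small_geometry, seed=5)
    k2 = run_ssa(init2, accuracy.rates, accuracy.diffusion, small_geometry,
                 5.0, 0.5, seed=42)
    assert np.array_equal(k1.meta["counts"], k2.meta["counts"])
    k3 = run_ssa(uniform_counts(600, [1, 1, 1], small_geometry, seed=5),
                 accuracy.rates, accuracy.diffusion, small_geometry,
                 5.0, 0.5, seed=43)
    assert not np.array_equal(k1.meta["counts"], k3.meta["counts"])


def test_exact_molecule_conservation(accuracy, small_geometry):
    init = uniform_counts(900, [2, 1, 1], small_geometry, seed=1)
    kym = run_ssa(init, accuracy.rates, accuracy.diffusion, small_geometry,
                  20.0, 1.0, seed=9)
    totals = kym.meta["counts"].sum(axis=(1, 2))
    assert np.all(totals == 900)
    assert np.all(kym.meta["counts"] >= 0)


def test_pure_diffusion_spreads_and_uniformizes():
    g = Geometry(L=6.0, n_box=60)
    D = DiffusionConstants(D1=0.3, D2=0.3, D3=0.3)
    N = 400
    var_t, t_probe = [], 1.0
    n_rep = 24
    for rep in range(n_rep):
        counts = np.zeros((3, 60), dtype=np.int64)
        counts[0, 30] = N
        kym = run_ssa(LatticeState(counts), ZERO_RATES, D, g, 2.0, t_probe,
                      seed=100 + rep)
        c = kym.meta["counts"][:, 0, :]
        x = g.x
        mean = (c[1] * x).sum() / N
        var_t.append(((c[1] * (x - mean) ** 2).sum() / N))
    # variance after t_probe approximately 2 D t (before boundary contact)
    expected = 2 * 0.3 * t_probe
    assert np.mean(var_t) == pytest.approx(expected, rel=0.15)
    # long-time occupancy approaches uniform
    counts = np.zeros((3, 60), dtype=np.int64)
    counts[0, 30] = 6000
    kym = run_ssa(LatticeState(counts), ZERO_RATES, D, g, 100.0, 100.0, seed=7)
    occ = kym.meta["counts"][-1, 0, :]
    assert occ.std() / occ.mean() < 0.25


def test_ensemble_seeding_and_order_independence(accuracy, small_geometry):
    net = build_network(accuracy.rates, accuracy.diffusion)
    make = lambda i: uniform_counts(300, [1, 1, 1], small_geometry, seed=1000 + i)
    ens = run_ensemble(make, net, small_geometry, 3.0, 1.0,
                       n_replicates=3, seed_base=50)
    assert len(ens) == 3
    seeds = [k.meta["seed"] for k in ens]
    assert seeds == [50, 51, 52]
    # replicate 1 alone reproduces the ensemble's replicate 1
    solo = run_ensemble(lambda i: make(1), net, small_geometry, 3.0, 1.0,
                        n_replicates=1, seed_base=51)[0]
    assert np.array_equal(solo.meta["counts"], ens[1].meta["counts"])
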