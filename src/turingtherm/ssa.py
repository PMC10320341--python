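"""Exact stochastic simulation of the reaction-diffusion master equation.

Space is a row of boxes of width dx; molecules hop to nearest
neighbours at rate D/dx^2 (inward only at the closed ends) and react
within a box with combinatorial mass-action propensities (falling
factorials, e.g. the backward autocatalytic channel needs three
distinct X2: kt21/dx^2 * n2 (n2-1)(n2-2)).  Events are drawn with the
direct Gillespie method; per-box propensity subtotals are updated
incrementally so each event costs O(n_box + channels).

Trajectories are statistically exact samples of the RDME.  Snapshots
store integer counts (lossless); concentrations u = n/dx are formed in
analysis.  An optional per-event entropy tally accumulates
ln(a_forward/a_reverse) over executed events, the trajectory-level
dissipation of the medium (zero-mean at equilibrium).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numba import njit

from .dynamics import Kymograph
from .model import DiffusionConstants, Geometry, RateConstants, build_network
from .network import ReactionNetwork

__all__ = [
    "LatticeState",
    "EventChannel",
    "propensities",
    "run_ssa",
    "run_network_ssa",
    "run_ensemble",
    "uniform_counts",
]


@dataclass
class LatticeState:
    """Integer molecule counts per species and box at time t."""

    counts: np.ndarray  # (S, n_box) int64
    t: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative molecule count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def weighted_total(self, weights: np.ndarray) -> float:
        return float(np.asarray(weights) @ self.counts.sum(axis=1))


@dataclass(frozen=True)
class EventChannel:
    kind: str          # "reaction" | "hop"
    box: int
    index: int         # directed reaction index, or species for hops
    direction: int     # +1 right / -1 left for hops; +1 fwd / -1 bwd for reactions
    propensity: float


def _directed_arrays(net: ReactionNetwork, dx: float):
    """Expand reversible reactions into directed channels.

    Returns (stoich_in, stoich_out, k_scaled) with shapes (2R, S) and
    per-box propensity prefactors k/dx^(order_in - 1).
    """
    sub, prod = net.stoich_arrays()
    kf, kb = net.rate_vectors()
    stoich_in = np.vstack([sub, prod]).astype(np.int64)
    stoich_out = np.vstack([prod, sub]).astype(np.int64)
    k = np.concatenate([kf, kb]).astype(np.float64)
    order = stoich_in.sum(axis=1)
    k_scaled = k / dx ** (order - 1)
    # reorder so channel 2i / 2i+1 are the forward/backward pair
    R = net.n_reactions
    idx = np.empty(2 * R, dtype=np.int64)
    idx[0::2] = np.arange(R)
    idx[1::2] = np.arange(R) + R
    return stoich_in[idx], stoich_out[idx], k_scaled[idx]


@njit(cache=True, inline="always", fastmath=True)
def _ffact(n: np.int64, m: np.int64) -> float:
    out = 1.0
    for j in range(m):
        out *= n - j
    return out if out > 0 else 0.0


@njit(cache=True, fastmath=True, inline="always")
def _chan_prop(counts, b, c, k_scaled, chan_sp, chan_m, chan_ns):
    """Propensity of directed channel c in box b (involved species only)."""
    a = k_scaled[c]
    for j in range(chan_ns[c]):
        a *= _ffact(counts[chan_sp[c, j], b], chan_m[c, j])
        if a == 0.0:
            return 0.0
    return a


@njit(cache=True, fastmath=True)
def _box_propensity(counts, b, k_scaled, chan_sp, chan_m, chan_ns, hop, nx):
    """Total propensity of box b (reactions + outgoing hops)."""
    C = k_scaled.shape[0]
    S = hop.shape[0]
    tot = 0.0
    for c in range(C):
        tot += _chan_prop(counts, b, c, k_scaled, chan_sp, chan_m, chan_ns)
    ends = 1.0 if (b == 0 or b == nx - 1) else 2.0
    for s in range(S):
        tot += ends * hop[s] * counts[s, b]
    return tot


@njit(cache=True, fastmath=True)
def _ssa_core(counts, stoich_in, stoich_out, k_scaled, hop, t0, t_end,
              sample_times, out, seed, tally_entropy,
              chan_sp, chan_m, chan_ns, delta):
    np.random.seed(seed)
    S, nx = counts.shape
    C = stoich_in.shape[0]
    box_a = np.empty(nx)
    for b in range(nx):
        box_a[b] = _box_propensity(counts, b, k_scaled, chan_sp, chan_m,
                                   chan_ns, hop, nx)
    total = box_a.sum()
    t = t0
    isamp = 0
    nsamp = sample_times.shape[0]
    entropy = 0.0
    events = 0
    while isamp < nsamp:
        if total <= 0.0:
            # frozen state: emit remaining samples unchanged
            while isamp < nsamp:
                out[isamp] = counts
                isamp += 1
            break
        r1 = np.random.random()
        dt = -np.log(r1 if r1 > 0 else 1e-300) / total
        t_next = t + dt
        while isamp < nsamp and sample_times[isamp] <= t_next:
            out[isamp] = counts
            isamp += 1
        if isamp >= nsamp:
            break
        t = t_next
        # pick box
        r2 = np.random.random() * total
        b = 0
        acc = 0.0
        for bb in range(nx):
            acc += box_a[bb]
            if r2 < acc or bb == nx - 1:
                b = bb
                break
        # pick channel within box
        r3 = r2 - (acc - box_a[b])
        if r3 < 0.0:
            r3 = 0.0
        chosen = -1
        acc2 = 0.0
        a_event = 0.0
        for c in range(C):
            a = _chan_prop(counts, b, c, k_scaled, chan_sp, chan_m, chan_ns)
            acc2 += a
            if r3 < acc2:
                chosen = c
                a_event = a
                break
        hop_species = -1
        hop_dir = 0
        if chosen < 0:
            # a hop channel
            ends = 1.0 if (b == 0 or b == nx - 1) else 2.0
            for s in range(S):
                a1 = ends * hop[s] * counts[s, b]
                if a1 <= 0.0:
                    continue
                acc2 += a1
                hop_species = s  # remember last occupied species (float-overshoot guard)
                a_event = hop[s] * counts[s, b]
                if b == 0:
                    hop_dir = 1
                elif b == nx - 1:
                    hop_dir = -1
                else:
                    hop_dir = 1 if (r3 - (acc2 - a1)) < a1 / 2.0 else -1
                if r3 < acc2:
                    break
            if hop_species < 0:
                continue  # empty box selected by float drift; redraw
        # execute
        if chosen >= 0:
            for s in range(S):
                counts[s, b] += delta[chosen, s]
            if tally_entropy:
                rev = chosen + 1 if chosen % 2 == 0 else chosen - 1
                a_rev = _chan_prop(counts, b, rev, k_scaled, chan_sp, chan_m, chan_ns)
                if a_rev > 0.0:
                    entropy += np.log(a_event / a_rev)
            new_a = _box_propensity(counts, b, k_scaled, chan_sp, chan_m,
                                    chan_ns, hop, nx)
            total += new_a - box_a[b]
            box_a[b] = new_a
        else:
            b2 = b + hop_dir
            counts[hop_species, b] -= 1
            counts[hop_species, b2] += 1
            if tally_entropy:
                a_rev = hop[hop_species] * counts[hop_species, b2]
                entropy += np.log(a_event / a_rev)
            na = _box_propensity(counts, b, k_scaled, chan_sp, chan_m,
                                 chan_ns, hop, nx)
            nb = _box_propensity(counts, b2, k_scaled, chan_sp, chan_m,
                                 chan_ns, hop, nx)
            total += (na - box_a[b]) + (nb - box_a[b2])
            box_a[b] = na
            box_a[b2] = nb
        events += 1
        if events % 4194304 == 0:
            # refresh running sums against float drift
            for bb in range(nx):
                box_a[bb] = _box_propensity(counts, bb, k_scaled, chan_sp,
                                            chan_m, chan_ns, hop, nx)
            total = box_a.sum()
    return t, entropy, events


def propensities(
    state: LatticeState,
    rates: RateConstants,
    diffusion: DiffusionConstants,
    geometry: Geometry,
) -> list[EventChannel]:
    """Explicit channel list for the three-species model (diagnostics)."""
    net = build_network(rates, diffusion)
    return network_propensities(state, net, geometry)


def network_propensities(
    state: LatticeState, net: ReactionNetwork, geometry: Geometry
) -> list[EventChannel]:
    dx = geometry.dx
    nx = geometry.n_box
    stoich_in, stoich_out, k_scaled = _directed_arrays(net, dx)
    hop = net.diffusion / dx**2
    counts = state.counts
    out: list[EventChannel] = []
    for b in range(nx):
        for c in range(stoich_in.shape[0]):
            a = k_scaled[c]
            for s in range(net.n_species):
                m = stoich_in[c, s]
                if m > 0:
                    a *= np.prod([counts[s, b] - j for j in range(m)])
            a = max(a, 0.0)
            out.append(
                EventChannel("reaction", b, c // 2, +1 if c % 2 == 0 else -1, float(a))
            )
        for s in range(net.n_species):
            for dd in (-1, +1):
                if 0 <= b + dd < nx:
                    out.append(
                        EventChannel("hop", b, s, dd, float(hop[s] * counts[s, b]))
                    )
    return out


def run_network_ssa(
    initial: LatticeState,
    net: ReactionNetwork,
    geometry: Geometry,
    t_end: float,
    sample_dt: float,
    seed: int,
    tally_entropy: bool = False,
    meta: dict | None = None,
) -> Kymograph:
    """Exact SSA trajectory for an arbitrary network; counts stored."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    counts = initial.counts.copy()
    S, nx = counts.shape
    if (S, nx) != (net.n_species, geometry.n_box):
        raise ValueError("state shape does not match network/geometry")
    stoich_in, stoich_out, k_scaled = _directed_arrays(net, geometry.dx)
    hop = net.diffusion / geometry.dx**2
    if nx == 1:
        hop = np.zeros_like(hop)  # well-mixed limit: no hop channels
    # flattened involved-species views for the kernel
    C = stoich_in.shape[0]
    max_sp = max(1, int((stoich_in > 0).sum(axis=1).max()) if C else 1)
    chan_sp = np.zeros((C, max_sp), dtype=np.int64)
    chan_m = np.zeros((C, max_sp), dtype=np.int64)
    chan_ns = np.zeros(C, dtype=np.int64)
    for c in range(C):
        j = 0
        for s in range(S):
            if stoich_in[c, s] > 0:
                chan_sp[c, j] = s
                chan_m[c, j] = stoich_in[c, s]
                j += 1
        chan_ns[c] = j
    delta = (stoich_out - stoich_in).astype(np.int64)
    sample_times = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    out = np.empty((len(sample_times), S, nx), dtype=np.int64)
    t_final, entropy, events = _ssa_core(
        counts, stoich_in, stoich_out, k_scaled, hop,
        initial.t, t_end, sample_times, out, np.uint32(seed), tally_entropy,
        chan_sp, chan_m, chan_ns, delta,
    )
    if not np.isfinite(t_final):
        raise RuntimeError(f"propensity overflow/NaN; state dump: {counts!r}")
    u = out.astype(float) / geometry.dx
    m = dict(meta or {})
    m.update(seed=seed, sample_dt=sample_dt, counts=out,
             entropy=entropy if tally_entropy else None, n_events=events)
    return Kymograph(sample_times, geometry.x, u, meta=m)


def run_ssa(
    initial: LatticeState,
    rates: RateConstants,
    diffusion: DiffusionConstants,
    geometry: Geometry,
    t_end: float,
    sample_dt: float,
    seed: int,
    tally_entropy: bool = False,
) -> Kymograph:
    """Exact three-species RDME trajectory (counts in meta, u = n/dx)."""
    net = build_network(rates, diffusion)
    return run_network_ssa(
        initial, net, geometry, t_end, sample_dt, seed,
        tally_entropy=tally_entropy,
        meta={"rates": rates, "diffusion": diffusion},
    )


def uniform_counts(
    N: int, n_species_fracs: np.ndarray, geometry: Geometry, seed: int
) -> LatticeState:
    """Multinomial placement of N molecules over species (given
    fractions) and uniformly over boxes."""
    rng = np.random.default_rng(seed)
    fracs = np.asarray(n_species_fracs, dtype=float)
    fracs = fracs / fracs.sum()
    S = len(fracs)
    probs = np.repeat(fracs / geometry.n_box, geometry.n_box)
    flat = rng.multinomial(N, probs)
    return LatticeState(flat.reshape(S, geometry.n_box))


def run_ensemble(
    make_initial,
    net: ReactionNetwork,
    geometry: Geometry,
    t_end: float,
    sample_dt: float,
    n_replicates: int,
    seed_base: int,
    tally_entropy: bool = False,
) -> list[Kymograph]:
    """Independent replicate trajectories, seeded seed_base + index.

    ``make_initial(replicate_index) -> LatticeState`` builds each
    initial condition (it may itself use the replicate index for an
    independent random placement).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for i in range(n_replicates):
        out.append(
            run_network_ssa(
                make_initial(i), net, geometry, t_end, sample_dt,
                seed=seed_base + i, tally_entropy=tally_entropy,
                meta={"replicate": i},
            )
        )
    return out
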