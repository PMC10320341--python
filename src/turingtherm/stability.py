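"""Linear stability of the homogeneous state and pattern onsets.

The homogeneous steady state of the reaction-diffusion system loses
stability to a finite-wavelength (Turing) mode when the reverse
autocatalytic rate kt21 drops below a critical value.  This module
computes

* the dispersion relation rho(q): largest real part of the eigenvalues
  of J - q^2 diag(D) at the homogeneous fixed point;
* the infinite-system onset kt0 (max_q rho = 0, q unconstrained);
* the finite-system onset ktc for a given stripe mode n, from the
  phase-diffusion criterion ktc = kt0 (1 - 3 xi^2 dq^2) with
  dq = q_n - q0;
* the minimum diffusion ratio d_min below which no instability exists
  even at infinite driving (kt21 -> 0);
* the closed-form critical effective rate beta0 and Gamma0 in the
  fast-inhibitor (d >> 1) limit, and the molecule-number window
  [N_min, N_max] where a target pattern is phase-stable at a given
  operating Gamma.

Wavevectors follow the periodic convention q_n = 2 pi n / L (wavelength
L/n); the Neumann-cosine alternative q_n = pi n / L can be selected
per call but is off by default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import (
    DiffusionConstants,
    Geometry,
    HomogeneousFixedPoint,
    RateConstants,
    build_network,
    compute_thermo,
    effective_rates,
    homogeneous_fixed_point,
)

__all__ = [
    "DispersionResult",
    "CriticalScan",
    "NRangeResult",
    "dispersion",
    "onset_kt0",
    "onset_ktc_finite",
    "find_dmin",
    "beta0_and_Gamma0",
    "gamma_c_curve",
    "n_range",
]

# The q -> 0 growth rate is exactly zero along the conservation
# direction; bisections on max_q rho therefore exclude a neighbourhood
# of q = 0 so its numerical zero cannot flip signs.
Q_GUARD = 0.3


@dataclass(frozen=True)
class DispersionResult:
    q: np.ndarray          # um^-1
    rho: np.ndarray        # s^-1, largest real eigenvalue part per q
    q0: float              # maximizing wavevector
    rho_max: float
    xi2: float | None = None   # um^2, curvature length^2 (onset scans only)
    tau: float | None = None   # s, characteristic time (onset scans only)


@dataclass(frozen=True)
class CriticalScan:
    kt0: float
    ktc: float
    zeta: float
    Gamma0: float
    Gammac: float
    W0: float
    Wc: float
    q0: float
    qn: float
    dq: float
    xi2: float
    tau: float


@dataclass(frozen=True)
class NRangeResult:
    N_min: float
    N_max: float
    N_star: float
    Gamma_c_peak: float
    N_grid: np.ndarray
    Gamma_c: np.ndarray


def _rho_at(rates: RateConstants, diffusion: DiffusionConstants,
            fp: HomogeneousFixedPoint, q: np.ndarray) -> np.ndarray:
    net = build_network(rates, diffusion)
    J = net.jacobian(fp.as_array())
    D = diffusion.as_array()
    out = np.empty(len(q))
    for i, qq in enumerate(np.asarray(q, dtype=float)):
        ev = np.linalg.eigvals(J - qq**2 * np.diag(D))
        out[i] = ev.real.max()
    return out


def dispersion(
    rates: RateConstants,
    diffusion: DiffusionConstants,
    c_tot: float,
    q_grid: np.ndarray | None = None,
) -> DispersionResult:
    """Growth rate of spatial mode q about the homogeneous fixed point."""
    fp = homogeneous_fixed_point(rates, c_tot)
    if q_grid is None:
        q_grid = np.linspace(0.0, 60.0, 1200)
    q_grid = np.asarray(q_grid, dtype=float)
    rho = _rho_at(rates, diffusion, fp, q_grid)
    interior = q_grid >= Q_GUARD
    if interior.any():
        i = np.argmax(np.where(interior, rho, -np.inf))
    else:
        i = int(np.argmax(rho))
    return DispersionResult(q_grid, rho, float(q_grid[i]), float(rho[i]))


def _max_rho(rates: RateConstants, diffusion: DiffusionConstants, c_tot: float,
             q_hi: float = 80.0, n_q: int = 800) -> tuple[float, float]:
    fp = homogeneous_fixed_point(rates, c_tot)
    qs = np.linspace(Q_GUARD, q_hi, n_q)
    rho = _rho_at(rates, diffusion, fp, qs)
    i = int(np.argmax(rho))
    # parabolic refinement of the peak
    if 0 < i < n_q - 1:
        r0, r1, r2 = rho[i - 1], rho[i], rho[i + 1]
        denom = r0 - 2 * r1 + r2
        if denom < 0:
            dq = 0.5 * (r0 - r2) / denom
            qstar = qs[i] + dq * (qs[1] - qs[0])
            rstar = _rho_at(rates, diffusion, fp, np.array([qstar]))[0]
            if rstar > r1:
                return rstar, qstar
    return float(rho[i]), float(qs[i])


def onset_kt0(
    rates: RateConstants,
    diffusion: DiffusionConstants,
    c_tot: float,
    kt21_hi: float = 1e-2,
    rtol: float = 1e-6,
) -> float:
    """Critical kt21 below which the homogeneous state is Turing unstable
    in an infinite system (bisection on max_q rho)."""

    def g(kt21: float) -> float:
        return _max_rho(rates.with_(kt21=kt21), diffusion, c_tot)[0]

    lo = 1e-14
    if g(lo) <= 0:
        raise ValueError("no onset in range: homogeneous state stable even as kt21 -> 0")
    if g(kt21_hi) >= 0:
        raise ValueError("no onset in range: still unstable at kt21_hi")
    return brentq(g, lo, kt21_hi, rtol=rtol)


def _onset_curvature(
    rates: RateConstants, diffusion: DiffusionConstants, c_tot: float, kt0: float
) -> tuple[float, float, float]:
    """(q0, xi2, tau) at the onset point kt21 = kt0.

    xi^2 = -(tau/2) d^2 rho/dq^2 at q0, with tau the reciprocal of
    kt0 |d rho(q0)/d kt21| so that rho ~ (eps0 - xi^2 (q-q0)^2)/tau
    near onset (eps0 = 1 - kt21/kt0).
    """
    r = rates.with_(kt21=kt0)
    _, q0 = _max_rho(r, diffusion, c_tot)
    fp = homogeneous_fixed_point(r, c_tot)
    h = 1e-3 * q0
    rm, r0_, rp = _rho_at(r, diffusion, fp, np.array([q0 - h, q0, q0 + h]))
    d2 = (rp - 2 * r0_ + rm) / h**2
    dk = 1e-4 * kt0
    ra = _rho_at(
        rates.with_(kt21=kt0 + dk), diffusion,
        homogeneous_fixed_point(rates.with_(kt21=kt0 + dk), c_tot), np.array([q0])
    )[0]
    rb = _rho_at(
        rates.with_(kt21=kt0 - dk), diffusion,
        homogeneous_fixed_point(rates.with_(kt21=kt0 - dk), c_tot), np.array([q0])
    )[0]
    drho_dkt = (ra - rb) / (2 * dk)
    tau = 1.0 / (abs(drho_dkt) * kt0)
    xi2 = -0.5 * tau * d2
    return q0, xi2, tau


def onset_ktc_finite(
    rates: RateConstants,
    diffusion: DiffusionConstants,
    geometry: Geometry,
    n: int,
    c_tot: float | None = None,
    N: float | None = None,
    neumann: bool = False,
) -> CriticalScan:
    """Finite-system onset for the n-stripe mode.

    The phase diffusion constant of the n-stripe pattern vanishes at
    ktc = kt0 (1 - 3 xi^2 dq^2), dq = q_n - q0, giving the stricter
    finite-system threshold (ktc <= kt0, hence Wc >= W0).
    """
    if c_tot is None:
        if N is None:
            raise ValueError("give c_tot or N")
        c_tot = N / geometry.L
    kt0 = onset_kt0(rates, diffusion, c_tot)
    q0, xi2, tau = _onset_curvature(rates, diffusion, c_tot, kt0)
    qn = (math.pi if neumann else 2 * math.pi) * n / geometry.L
    dq = qn - q0
    zeta = 1.0 - 3.0 * xi2 * dq**2
    if zeta <= 0:
        raise ValueError("mode outside phase-stable band (zeta <= 0)")
    ktc = kt0 * zeta
    Gamma0 = compute_thermo(rates.with_(kt21=kt0)).Gamma
    Gammac = compute_thermo(rates.with_(kt21=ktc)).Gamma
    return CriticalScan(
        kt0=kt0, ktc=ktc, zeta=zeta, Gamma0=Gamma0, Gammac=Gammac,
        W0=-math.log(Gamma0), Wc=-math.log(Gammac),
        q0=q0, qn=qn, dq=dq, xi2=xi2, tau=tau,
    )


def find_dmin(
    rates: RateConstants,
    diffusion_template: DiffusionConstants,
    c_tot: float,
    d_lo: float = 1.01,
    d_hi: float = 100.0,
    xtol: float = 1e-3,
) -> float:
    """Smallest diffusion ratio d = D1/D2 with a Turing band at infinite
    driving (kt21 = 0).  D2 is held at the template value, D1 = D3 vary."""
    r0 = rates.with_(kt21=0.0)
    D2 = diffusion_template.D2

    def g(d: float) -> float:
        dif = DiffusionConstants(D1=d * D2, D2=D2)
        return _max_rho(r0, dif, c_tot)[0]

    glo, ghi = g(d_lo), g(d_hi)
    if ghi < 0:
        return math.inf  # never unstable, no finite d_min in bracket
    if glo > 0:
        return d_lo
    return brentq(g, d_lo, d_hi, xtol=xtol)


# ----------------------------------------------------------------------
# closed-form onset in the fast-inhibitor limit and the N-window
# ----------------------------------------------------------------------
def beta0_and_Gamma0(
    rates: RateConstants, c_tot: float, max_iter: int = 80, tol: float = 1e-12
) -> tuple[float, float]:
    """Critical effective autocatalytic rate beta0 = kt_c * c_tot^2 and
    the corresponding Gamma0, in the d >> 1 limit.

    Derivation: for d -> infinity the inhibitor fields are spatially
    pinned, and the band-opening condition reduces to the vanishing of
    the activator self-coupling, which combined with the steady-state
    balances gives

        beta0 = (k21 + k23)/v2*^2 - 2 (k12 v1* + k32 v3*) / v2*^3,

    with v1* = (1 - R2 v2*)/R1, R1 = (k31+k32+k13)/(k31+k32),
    R2 = (k31+k32+k23)/(k31+k32).  v2* is the relative concentration of
    the homogeneous fixed point evaluated self-consistently at
    beta21 = beta0 (fixed-point iteration).
    """
    beta12, _ = effective_rates(rates, c_tot)
    kt21 = 0.0
    beta0 = 0.0
    v2 = math.nan
    prev_u2: float | None = None
    for _ in range(max_iter):
        fp = homogeneous_fixed_point(rates.with_(kt21=kt21), c_tot, near=prev_u2)
        prev_u2 = fp.u2
        v1, v2, v3 = fp.as_array() / c_tot
        if v2 <= 0:
            raise ZeroDivisionError("v2* = 0: no activator at the fixed point")
        new = (rates.k21 + rates.k23) / v2**2 - 2 * (
            rates.k12 * v1 + rates.k32 * v3
        ) / v2**3
        if new <= 0:
            return math.nan, math.nan
        kt21 = new / c_tot**2
        if abs(new - beta0) <= tol * max(1.0, abs(new)):
            beta0 = new
            break
        beta0 = new
    Gamma0 = beta0 * rates.k12 / (beta12 * rates.k21)
    return beta0, Gamma0


def R_constants(rates: RateConstants) -> tuple[float, float]:
    den = rates.k31 + rates.k32
    return (den + rates.k13) / den, (den + rates.k23) / den


def gamma_c_curve(
    rates: RateConstants,
    geometry: Geometry,
    N_grid: np.ndarray,
    zeta: float = 1.0,
) -> np.ndarray:
    """Gamma_c(N) = zeta * Gamma0(N) over a molecule-number grid."""
    out = np.empty(len(N_grid))
    for i, N in enumerate(np.asarray(N_grid, dtype=float)):
        _, g0 = beta0_and_Gamma0(rates, N / geometry.L)
        out[i] = zeta * g0
    return out


def n_range(
    rates: RateConstants,
    diffusion: DiffusionConstants,
    geometry: Geometry,
    Gamma_operating: float,
    n_mode: int = 3,
    N_grid: np.ndarray | None = None,
    zeta: float | None = None,
) -> NRangeResult:
    """Molecule-number window [N_min, N_max] where the n-stripe pattern
    is phase-stable at the operating Gamma, from Gamma_c(N) = Gamma.

    zeta is evaluated once at the peak of Gamma0(N) (the natural centre
    of the window) and treated as constant across N.
    """
    if N_grid is None:
        N_grid = np.geomspace(200, 60000, 240)
    N_grid = np.asarray(N_grid, dtype=float)
    g0 = gamma_c_curve(rates, geometry, N_grid, zeta=1.0)
    ok = np.isfinite(g0)
    if not ok.any():
        raise ValueError("no stable-N window: Gamma0 undefined on grid")
    istar = int(np.nanargmax(np.where(ok, g0, -np.inf)))
    N_star = float(N_grid[istar])
    if zeta is None:
        scan = onset_ktc_finite(rates, diffusion, geometry, n_mode, N=N_star)
        zeta = scan.zeta
    gc = zeta * g0
    peak = float(gc[istar])
    if Gamma_operating >= peak:
        raise ValueError("no stable-N window: operating Gamma above the Gamma_c peak")

    def flank_root(lo_side: bool) -> float:
        if lo_side:
            idx = np.arange(0, istar + 1)
        else:
            idx = np.arange(istar, len(N_grid))
        Ns, gs = N_grid[idx], gc[idx]
        good = np.isfinite(gs)
        Ns, gs = Ns[good], gs[good]
        diff = gs - Gamma_operating
        sgn = np.sign(diff)
        cross = np.where(sgn[:-1] * sgn[1:] <= 0)[0]
        if len(cross) == 0:
            # window edge beyond the grid flank
            return float(Ns[0] if lo_side else Ns[-1])
        j = cross[0] if lo_side else cross[-1]
        # log-linear interpolation
        x0, x1 = math.log(Ns[j]), math.log(Ns[j + 1])
        y0, y1 = diff[j], diff[j + 1]
        return math.exp(x0 - y0 * (x1 - x0) / (y1 - y0))

    return NRangeResult(
        N_min=flank_root(True),
        N_max=flank_root(False),
        N_star=N_star,
        Gamma_c_peak=peak,
        N_grid=N_grid,
        Gamma_c=gc,
    )
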