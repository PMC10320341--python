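"""Positional accuracy of striped patterns and the phase-diffusion theory.

The translational phase of a stripe pattern is a soft mode; in a small
stochastic system the tracked position x_p(t) of the central stripe
wanders, and its standard deviation sigma over time is the positional
error.  The long-wavelength theory treats the phase phi(x, t) as
governed by

    dphi/dt = D2 d2phi/dx2 - D4 d4phi/dx4 + dx(eta),

with conserved noise of strength Delta0, giving a positional variance

    sigma^2 = (lambda/2pi)^2 int_{pi/L}^inf dq int dw
              Delta0 q^2 / (w^2 + (D2 q^2 + D4 q^4)^2)
            = sigma0^2 / S(eps),

where with D2 = d2*eps and constant D4 the variance-reduction factor is
S(eps) = a sqrt(eps) / arctan(a sqrt(eps)), a = (L/pi) sqrt(d2/D4),
and sigma0^2 = (lambda/2pi)^2 Delta0 L / D4 at eps = 0.  Expanding the
error-reduction function around strong driving yields the error-energy
relation sigma = sigma_min / (1 - c1 exp(-dW) + h.o.t.).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import curve_fit

from .dynamics import Kymograph
from .model import Geometry

__all__ = [
    "PeakTrack",
    "track_peak",
    "stripe_counts",
    "S_of_eps",
    "sigma_squared_integral",
    "fit_error_energy",
    "synthetic_kymograph",
]


@dataclass
class PeakTrack:
    """Tracked central-peak positions and their spread."""

    times: np.ndarray
    x_p: np.ndarray
    valid: np.ndarray           # stripe count equals the target count
    sigma: float                # std of x_p over valid samples after burn-in
    n_stripes: int              # target (modal) stripe count
    frac_invalid: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.x_p[self.valid]))


def _local_maxima(profile: np.ndarray, prominence_frac: float = 0.2) -> list[int]:
    """Indices of stripe maxima: interior peaks with prominence of at
    least ``prominence_frac`` of the profile range, plus boundary boxes
    that rise comparably above the minimum (half-stripes at the closed
    ends); low-amplitude tail upticks are not stripes."""
    from scipy.signal import find_peaks

    rng = float(profile.max() - profile.min())
    if rng <= 0:
        return []
    prom = prominence_frac * rng
    idx = list(find_peaks(profile, prominence=prom)[0])
    thr = profile.min() + prom
    n = len(profile)
    if profile[0] > profile[1] and profile[0] >= thr:
        idx.insert(0, 0)
    if profile[-1] > profile[-2] and profile[-1] >= thr:
        idx.append(n - 1)
    return idx


def _subgrid_peak(profile: np.ndarray, i: int, x: np.ndarray) -> float:
    """Parabolic interpolation through box i and its neighbours."""
    if i == 0 or i == len(profile) - 1:
        return float(x[i])
    y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(x[i])
    shift = 0.5 * (y0 - y2) / denom
    return float(x[i] + shift * (x[1] - x[0]))


def _smooth_space(u: np.ndarray, window: int) -> np.ndarray:
    """Box-car smoothing along x with reflecting ends; u is (T, nx)."""
    if window <= 1:
        return u
    pad = window // 2
    up = np.pad(u, ((0, 0), (pad, pad)), mode="reflect")
    kernel = np.ones(window) / window
    out = np.empty_like(u)
    for t in range(u.shape[0]):
        out[t] = np.convolve(up[t], kernel, mode="valid")[: u.shape[1]]
    return out


def _smooth_time(u: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return u
    kernel = np.ones(window) / window
    out = np.empty_like(u)
    for j in range(u.shape[1]):
        out[:, j] = np.convolve(u[:, j], kernel, mode="same")
    # repair the edge bias of 'same' convolution
    for t in range(u.shape[0]):
        lo = max(0, t - window // 2)
        hi = min(u.shape[0], t + (window + 1) // 2)
        out[t] = u[lo:hi].mean(axis=0)
    return out


def stripe_counts(
    kym: Kymograph, species: int = 1, smoothing: int = 1, space_smoothing: int = 1
) -> np.ndarray:
    u = _smooth_space(_smooth_time(kym.u[:, species, :], smoothing), space_smoothing)
    return np.array([len(_local_maxima(u[t])) for t in range(u.shape[0])])


def track_peak(
    kym: Kymograph,
    species: int = 1,
    smoothing: int = 10,
    space_smoothing: int = 1,
    target_stripes: int | None = None,
    burn_frac: float = 0.2,
    stable_run: int = 100,
    max_invalid_frac: float = 0.5,
) -> PeakTrack:
    """Track the central stripe of a kymograph.

    The species field is smoothed over ``smoothing`` consecutive
    samples, local maxima are located per snapshot, and the peak whose
    position is nearest the domain centre is followed with sub-grid
    (parabolic) resolution.  Samples whose stripe count differs from
    the target count are flagged invalid.  Burn-in removes the leading
    ``burn_frac`` of the trajectory and everything before the stripe
    count has remained at the target for ``stable_run`` consecutive
    samples.
    """
    L = kym.x[-1] + (kym.x[1] - kym.x[0]) / 2
    u = _smooth_space(_smooth_time(kym.u[:, species, :], smoothing), space_smoothing)
    T = u.shape[0]
    counts = np.array([len(_local_maxima(u[t])) for t in range(T)])
    if target_stripes is None:
        target_stripes = int(np.bincount(counts).argmax())
    # burn-in: first index from which the count stays on target for stable_run
    start = None
    run = 0
    for t in range(T):
        run = run + 1 if counts[t] == target_stripes else 0
        if run >= min(stable_run, T):
            start = t - run + 1
            break
    if start is None:
        raise ValueError("pattern lost: stripe count never stabilized at target")
    start = max(start, int(burn_frac * T))
    x_p = np.full(T, np.nan)
    valid = np.zeros(T, dtype=bool)
    centre = L / 2
    lam = L / max(target_stripes, 1)
    ref = centre  # stripe identity: seeded at the centre, then followed
    for t in range(start, T):
        maxima = _local_maxima(u[t])
        if not maxima:
            continue
        i = min(maxima, key=lambda j: abs(kym.x[j] - ref))
        pos = _subgrid_peak(u[t], i, kym.x)
        if abs(pos - ref) > lam / 2:
            # lost the stripe identity this sample; do not move the reference
            continue
        x_p[t] = pos
        ref = pos
        valid[t] = counts[t] == target_stripes
    sel = valid & np.isfinite(x_p)
    n_window = T - start
    frac_invalid = 1.0 - sel[start:].sum() / max(n_window, 1)
    if frac_invalid > max_invalid_frac:
        raise ValueError(
            f"pattern lost: {frac_invalid:.0%} of samples without the target stripe count"
        )
    sigma = float(np.std(x_p[sel], ddof=1)) if sel.sum() > 1 else 0.0
    return PeakTrack(
        times=kym.times, x_p=x_p, valid=sel, sigma=sigma,
        n_stripes=target_stripes, frac_invalid=float(frac_invalid),
    )


# ----------------------------------------------------------------------
# phase-diffusion theory
# ----------------------------------------------------------------------
def S_of_eps(eps: float | np.ndarray, a: float) -> float | np.ndarray:
    """Variance-reduction factor a sqrt(eps)/arctan(a sqrt(eps)); S(0)=1."""
    if a <= 0:
        raise ValueError("a must be > 0")
    eps_arr = np.asarray(eps, dtype=float)
    if np.any((eps_arr < 0) | (eps_arr > 1)):
        raise ValueError("eps must lie in [0, 1]")
    x = a * np.sqrt(eps_arr)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(x > 0, x / np.arctan(x), 1.0)
    return float(out) if np.isscalar(eps) else out


def sigma_squared_integral(
    D2: float, D4: float, Delta0: float, L: float, lam: float
) -> float:
    """Positional variance from the (q, w) spectrum of the phase field.

    The frequency integral is analytic, int dw/(w^2 + A^2) = pi/A with
    A = D2 q^2 + D4 q^4; the remaining q integral from pi/L to infinity
    is evaluated numerically.
    """
    if D4 <= 0:
        raise ValueError("D4 must be > 0")
    if D2 < 0 and -D2 >= D4 * (math.pi / L) ** 2:
        # pole of the relaxation spectrum inside the integration range
        raise ValueError("phase-unstable regime: D2 q^2 + D4 q^4 vanishes for q >= pi/L")

    def integrand(q: float) -> float:
        return math.pi * Delta0 / (D2 + D4 * q**2)

    val, _ = quad(integrand, math.pi / L, math.inf, limit=200)
    return (lam / (2 * math.pi)) ** 2 * val


def fit_error_energy(
    sigmas: Sequence[float],
    dWs: Sequence[float],
    sigma_errs: Sequence[float] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Least-squares fit of sigma = sigma_min / (1 - c1 exp(-dW)).

    Returns (sigma_min, c1, covariance).  Needs at least four points
    with dW >= 0.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    dWs = np.asarray(dWs, dtype=float)
    if len(sigmas) < 4:
        raise ValueError("need at least 4 (dW, sigma) points")
    if np.any(dWs < 0):
        raise ValueError("dW must be >= 0")

    def model(dw, sigma_min, c1):
        return sigma_min / (1.0 - c1 * np.exp(-dw))

    p0 = (float(sigmas.min()), 0.5)
    popt, pcov = curve_fit(
        model, dWs, sigmas, p0=p0, sigma=sigma_errs,
        bounds=([0.0, 0.0], [np.inf, 0.999]), maxfev=20000,
    )
    resid = sigmas - model(dWs, *popt)
    if not np.all(np.isfinite(pcov)):
        raise RuntimeError(f"non-convergent fit; residuals: {resid!r}")
    return float(popt[0]), float(popt[1]), pcov


# ----------------------------------------------------------------------
# synthetic fixture kymographs
# ----------------------------------------------------------------------
def synthetic_kymograph(
    geometry: Geometry,
    n_samples: int,
    jitter_std: float,
    seed: int,
    n_stripes: int = 3,
    amplitude: float = 100.0,
    baseline: float = 120.0,
    sample_dt: float = 1.0,
    noise: float = 0.0,
) -> Kymograph:
    """Striped activator kymograph with known Gaussian peak jitter.

    Emulates a stochastic kymograph as a row of ``n_stripes`` localized
    stripes (Gaussian bumps of width lambda/4 centred at
    x = L(2j-1)/(2n)) whose centres are displaced by i.i.d. Gaussian
    offsets of std ``jitter_std`` per snapshot, for calibrating the
    peak tracker.  It does not emulate stripe-count changes, correlated
    phase dynamics or amplitude fluctuations.
    """
    rng = np.random.default_rng(seed)
    x = geometry.x
    times = np.arange(n_samples) * sample_dt
    u = np.zeros((n_samples, 3, geometry.n_box))
    lam = geometry.L / n_stripes
    width = lam / 4
    centres = (2 * np.arange(n_stripes) + 1) * lam / 2
    for t in range(n_samples):
        profile = np.full(geometry.n_box, float(baseline) - amplitude * 0.0)
        profile[:] = baseline - amplitude
        for c in centres:
            cj = c + rng.normal(0.0, jitter_std)
            profile = profile + 2 * amplitude * np.exp(-((x - cj) ** 2) / (2 * width**2))
        if noise > 0:
            profile = profile + rng.normal(0.0, noise, size=profile.shape)
        u[t, 1] = np.clip(profile, 0.0, None)
        u[t, 0] = baseline
        u[t, 2] = baseline
    return Kymograph(times, x, u, meta={"jitter_std": jitter_std, "seed": seed})


def __getattr__(name):
    # scan_sigma_vs_N lives with the other sweep drivers; re-exported
    # here because it is part of the pattern-metrics surface
    if name == "scan_sigma_vs_N":
        from .experiments import scan_sigma_vs_N

        return scan_sigma_vs_N
    raise AttributeError(name)
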