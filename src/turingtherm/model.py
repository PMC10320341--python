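"""The reversible three-species self-positioning network.

Three interconverting forms X1, X2, X3 of one protein complex (in the
MukBEF picture: DNA-free complex, DNA-bound complex, dissociated
subunits) react through three linear conversions and one cubic
autocatalytic step,

    X1 <-> X2 (k12/k21),  X2 <-> X3 (k23/k32),  X3 <-> X1 (k31/k13),
    X1 + 2 X2 <-> 3 X2 (kt12/kt21),

and diffuse with constants D1, D2, D3 (the DNA-bound activator X2 is
slow, D2 << D1 = D3).  The two independent reaction cycles carry
irreversibility parameters

    Gamma  = kt21 k12 / (kt12 k21),
    Gamma' = k13 k32 k21 / (k12 k23 k31),

both equal to 1 at thermodynamic equilibrium.  The chemical driving per
completion of the dominant (autocatalytic) cycle is W = -ln Gamma in
units of kT.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .network import Reaction, ReactionNetwork

__all__ = [
    "RateConstants",
    "DiffusionConstants",
    "Geometry",
    "ThermoState",
    "HomogeneousFixedPoint",
    "IrreversibleLimitError",
    "compute_thermo",
    "homogeneous_fixed_point",
    "all_fixed_points",
    "effective_rates",
    "build_network",
]


class IrreversibleLimitError(ValueError):
    """Raised when a thermodynamic quantity is requested at a zero
    backward rate (the dissipation per event diverges there)."""


@dataclass(frozen=True)
class RateConstants:
    """First-order conversion rates (s^-1) and autocatalytic rates
    (s^-1 um^2 in 1-D concentration units)."""

    k12: float
    k21: float
    k23: float
    k32: float
    k31: float
    k13: float
    kt12: float
    kt21: float

    def __post_init__(self) -> None:
        for name in ("k12", "k21", "k23", "k32", "k31", "k13", "kt12", "kt21"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kt12 <= 0:
            raise ValueError("kt12 must be > 0 (no autocatalysis, no pattern)")

    def with_(self, **kw) -> "RateConstants":
        return replace(self, **kw)

    @property
    def reversible(self) -> bool:
        return min(self.k21, self.k32, self.k13, self.kt21) > 0


@dataclass(frozen=True)
class DiffusionConstants:
    """Diffusion constants in um^2/s.  By default the two DNA-free
    conformations share one value (D3 = D1)."""

    D1: float
    D2: float
    D3: float | None = None

    def __post_init__(self) -> None:
        if self.D3 is None:
            object.__setattr__(self, "D3", self.D1)
        if min(self.D1, self.D2, self.D3) <= 0:
            raise ValueError("diffusion constants must be > 0")

    @property
    def d(self) -> float:
        """Inhibitor/activator diffusion ratio D1/D2."""
        return self.D1 / self.D2

    def as_array(self) -> np.ndarray:
        return np.array([self.D1, self.D2, self.D3])


@dataclass(frozen=True)
class Geometry:
    """Closed (no-flux) 1-D domain of length L split into n_box boxes."""

    L: float
    n_box: int

    def __post_init__(self) -> None:
        # n_box = 1 is the well-mixed limit; spatial work uses >= 3
        if self.n_box < 1:
            raise ValueError("need at least one box")
        if self.L <= 0:
            raise ValueError("L must be > 0")

    @property
    def dx(self) -> float:
        return self.L / self.n_box

    @property
    def x(self) -> np.ndarray:
        """Box-centre coordinates."""
        return (np.arange(self.n_box) + 0.5) * self.dx


@dataclass(frozen=True)
class ThermoState:
    """Cycle irreversibility parameters and drivings (kT per cycle)."""

    Gamma: float
    GammaPrime: float
    W: float
    Wprime: float


@dataclass(frozen=True)
class HomogeneousFixedPoint:
    """Well-mixed steady state at total concentration c_tot = N/L."""

    u1: float
    u2: float
    u3: float
    c_tot: float

    @property
    def v2(self) -> float:
        """Relative activator concentration u2/c_tot."""
        return self.u2 / self.c_tot

    def as_array(self) -> np.ndarray:
        return np.array([self.u1, self.u2, self.u3])


def compute_thermo(rates: RateConstants) -> ThermoState:
    """Cycle irreversibility parameters Gamma, Gamma' and drivings.

    Gamma multiplies reverse over forward rate constants around the
    autocatalytic cycle, Gamma' around the three-state loop; W = -ln
    Gamma is the free energy dissipated per completed cycle (kT).
    """
    if not rates.reversible:
        raise IrreversibleLimitError(
            "zero backward rate: irreversible limit, dissipation undefined"
        )
    Gamma = rates.kt21 * rates.k12 / (rates.kt12 * rates.k21)
    GammaPrime = (
        rates.k13 * rates.k32 * rates.k21 / (rates.k12 * rates.k23 * rates.k31)
    )
    return ThermoState(Gamma, GammaPrime, -math.log(Gamma), -math.log(GammaPrime))


def effective_rates(rates: RateConstants, c_tot: float) -> tuple[float, float]:
    """Autocatalytic rates in relative-concentration units,
    beta = kt * c_tot^2 (s^-1)."""
    if c_tot < 0:
        raise ValueError("c_tot must be >= 0")
    return rates.kt12 * c_tot**2, rates.kt21 * c_tot**2


def build_network(rates: RateConstants, diffusion: DiffusionConstants) -> ReactionNetwork:
    """Assemble the three-species model as a generic ReactionNetwork."""
    rx = [
        Reaction({0: 1}, {1: 1}, rates.k12, rates.k21, "X1<->X2"),
        Reaction({1: 1}, {2: 1}, rates.k23, rates.k32, "X2<->X3"),
        Reaction({2: 1}, {0: 1}, rates.k31, rates.k13, "X3<->X1"),
        Reaction({0: 1, 1: 2}, {1: 3}, rates.kt12, rates.kt21, "X1+2X2<->3X2"),
    ]
    return ReactionNetwork(["X1", "X2", "X3"], rx, diffusion.as_array())


# ----------------------------------------------------------------------
# homogeneous fixed point
# ----------------------------------------------------------------------
def all_fixed_points(rates: RateConstants, c_tot: float) -> list[HomogeneousFixedPoint]:
    """All nonnegative well-mixed steady states at this c_tot.

    Via the X3 balance and the conservation constraint, u1 and u3 are
    linear in u2, and the remaining X2 balance is a cubic polynomial in
    u2 solved exactly.
    """
    if c_tot <= 0:
        raise ValueError("c_tot must be > 0")
    ksum = rates.k13 + rates.k31 + rates.k32
    # u1 = a1 + b1 u2 ; u3 = c_tot - u2 - u1
    a1 = (rates.k31 + rates.k32) * c_tot / ksum
    b1 = -((rates.k31 + rates.k32) + rates.k23) / ksum
    # X2 balance: k12 u1 + k32 u3 - (k21 + k23) u2 + kt12 u1 u2^2 - kt21 u2^3 = 0
    # u3 = c_tot - u2 - u1
    # constant and linear parts:
    c0 = rates.k12 * a1 + rates.k32 * (c_tot - a1)
    c1 = rates.k12 * b1 + rates.k32 * (-1.0 - b1) - (rates.k21 + rates.k23)
    # cubic coefficients (descending powers of u2)
    coeffs = [
        -rates.kt21 + rates.kt12 * b1,
        rates.kt12 * a1,
        c1,
        c0,
    ]
    roots = np.roots(coeffs)  # np.roots trims leading zeros (linear limit)
    out: list[HomogeneousFixedPoint] = []
    tol = 1e-9 * c_tot
    for r in np.atleast_1d(roots):
        if abs(np.imag(r)) > 1e-9 * max(1.0, abs(r)):
            continue
        u2 = float(np.real(r))
        if u2 < -tol or u2 > c_tot + tol:
            continue
        u1 = a1 + b1 * u2
        u3 = c_tot - u2 - u1
        if u1 >= -tol and u3 >= -tol:
            out.append(
                HomogeneousFixedPoint(max(u1, 0.0), max(u2, 0.0), max(u3, 0.0), c_tot)
            )
    out.sort(key=lambda f: f.u2)
    if not out:
        raise ValueError("invalid parameter regime: no nonnegative fixed point")
    return out


def _wellmixed_rhs(rates: RateConstants):
    def f(t, u):
        u1, u2, u3 = u
        r12 = rates.k12 * u1 - rates.k21 * u2
        rt = rates.kt12 * u1 * u2**2 - rates.kt21 * u2**3
        r23 = rates.k23 * u2 - rates.k32 * u3
        r31 = rates.k31 * u3 - rates.k13 * u1
        return [-r12 - rt + r31, r12 + rt - r23, r23 - r31]

    return f


def homogeneous_fixed_point(
    rates: RateConstants,
    c_tot: float,
    t_relax: float = 1e6,
    near: float | None = None,
) -> HomogeneousFixedPoint:
    """The relevant well-mixed steady state at total concentration c_tot.

    When the cubic steady-state system has several nonnegative roots,
    the one reached by relaxation of the well-mixed rate equations from
    the uniform equal-partition state is returned (use
    :func:`all_fixed_points` for the full set).  ``near`` short-circuits
    the relaxation by picking the root with u2 closest to the given
    value (continuity tracking in parameter scans).
    """
    roots = all_fixed_points(rates, c_tot)
    if near is not None:
        return min(roots, key=lambda r: abs(r.u2 - near))
    if len(roots) == 1:
        return roots[0]
    sol = solve_ivp(
        _wellmixed_rhs(rates),
        (0.0, t_relax),
        [c_tot / 3] * 3,
        method="LSODA",
        rtol=1e-10,
        atol=1e-10 * c_tot,
    )
    u_end = sol.y[:, -1]
    best = min(roots, key=lambda r: np.linalg.norm(r.as_array() - u_end))
    return best
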