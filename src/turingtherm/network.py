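"""Generic reversible reaction networks on a 1-D diffusive lattice.

A :class:`ReactionNetwork` collects species (with diffusion constants and
conservation weights) and reversible mass-action reactions.  The same
object backs the deterministic method-of-lines integrator, the linear
stability analysis and the exact stochastic simulator, so the three
routes share one definition of the kinetics.

Units: 1-D concentrations are in molecules per micron (u = n/dx).  A
reaction of molecularity ``m`` carries a rate constant with units
s^-1 um^(m-1), so that mass-action rate densities are s^-1 um^-1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Reaction", "ReactionNetwork"]


@dataclass(frozen=True)
class Reaction:
    """A reversible elementary reaction with mass-action kinetics.

    ``reactants`` and ``products`` map species index -> stoichiometric
    count.  ``kf``/``kb`` are the forward/backward rate constants.  A
    backward rate of zero marks an irreversible limit; dynamics are
    well defined there but entropy-production evaluations refuse it.
    ``n_driven`` counts fuel (e.g. ATP hydrolysis) events coupled to the
    forward direction; it is used by models whose driving is scaled by a
    fuel concentration ratio and is zero for passive steps.
    """

    reactants: dict[int, int]
    products: dict[int, int]
    kf: float
    kb: float
    label: str = ""
    n_driven: int = 0

    def __post_init__(self) -> None:
        if self.kf < 0 or self.kb < 0:
            raise ValueError(f"negative rate constant in reaction {self.label!r}")

    @property
    def order_f(self) -> int:
        return sum(self.reactants.values())

    @property
    def order_b(self) -> int:
        return sum(self.products.values())


@dataclass
class ReactionNetwork:
    """Species + reversible reactions + transport coefficients."""

    species: list[str]
    reactions: list[Reaction]
    diffusion: np.ndarray            # um^2/s, one per species
    weights: np.ndarray | None = None  # conservation weights (monomer equivalents)

    def __post_init__(self) -> None:
        self.diffusion = np.asarray(self.diffusion, dtype=float)
        if self.diffusion.shape != (self.n_species,):
            raise ValueError("diffusion must provide one constant per species")
        if np.any(self.diffusion <= 0):
            raise ValueError("diffusion constants must be positive")
        if self.weights is None:
            self.weights = np.ones(self.n_species)
        self.weights = np.asarray(self.weights, dtype=float)
        for r in self.reactions:
            wl = sum(self.weights[s] * m for s, m in r.reactants.items())
            wr = sum(self.weights[s] * m for s, m in r.products.items())
            if abs(wl - wr) > 1e-12:
                raise ValueError(
                    f"reaction {r.label!r} does not conserve weighted mass "
                    f"({wl} -> {wr})"
                )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    # ------------------------------------------------------------------
    # dense stoichiometry views used by the simulators
    # ------------------------------------------------------------------
    def stoich_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(reactant, product) stoichiometric count matrices, shape (R, S)."""
        S, R = self.n_species, self.n_reactions
        sub = np.zeros((R, S), dtype=np.int64)
        prod = np.zeros((R, S), dtype=np.int64)
        for i, r in enumerate(self.reactions):
            for s, m in r.reactants.items():
                sub[i, s] = m
            for s, m in r.products.items():
                prod[i, s] = m
        return sub, prod

    def rate_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        kf = np.array([r.kf for r in self.reactions])
        kb = np.array([r.kb for r in self.reactions])
        return kf, kb

    # ------------------------------------------------------------------
    # deterministic kinetics
    # ------------------------------------------------------------------
    def fluxes(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Forward/backward mass-action flux densities per reaction.

        ``u`` has shape (S,) or (S, nx); returns arrays shaped like
        (R,) or (R, nx).
        """
        u = np.asarray(u, dtype=float)
        sub, prod = self.stoich_arrays()
        kf, kb = self.rate_vectors()
        jf = kf.reshape(-1, *([1] * (u.ndim - 1))) * np.prod(
            u[None, ...] ** sub.reshape(*sub.shape, *([1] * (u.ndim - 1))), axis=1
        )
        jb = kb.reshape(-1, *([1] * (u.ndim - 1))) * np.prod(
            u[None, ...] ** prod.reshape(*prod.shape, *([1] * (u.ndim - 1))), axis=1
        )
        return jf, jb

    def reaction_rates(self, u: np.ndarray) -> np.ndarray:
        """Net species production rates du/dt from reactions only."""
        jf, jb = self.fluxes(u)
        sub, prod = self.stoich_arrays()
        nu = (prod - sub).astype(float)           # (R, S)
        return np.tensordot(nu.T, jf - jb, axes=([1], [0]))

    def jacobian(self, u: np.ndarray) -> np.ndarray:
        """Jacobian d(reaction_rates)/du at a well-mixed state u (S,)."""
        u = np.asarray(u, dtype=float)
        sub, prod = self.stoich_arrays()
        kf, kb = self.rate_vectors()
        nu = (prod - sub).astype(float)
        S = self.n_species
        J = np.zeros((S, S))
        for i in range(self.n_reactions):
            for s in range(S):
                # d(jf)/du_s and d(jb)/du_s via power rule
                if sub[i, s] > 0:
                    dj = kf[i] * sub[i, s] * u[s] ** (sub[i, s] - 1)
                    for t in range(S):
                        if t != s and sub[i, t] > 0:
                            dj *= u[t] ** sub[i, t]
                    J[:, s] += nu[i] * dj
                if prod[i, s] > 0:
                    dj = kb[i] * prod[i, s] * u[s] ** (prod[i, s] - 1)
                    for t in range(S):
                        if t != s and prod[i, t] > 0:
                            dj *= u[t] ** prod[i, t]
                    J[:, s] -= nu[i] * dj
        return J

    # ------------------------------------------------------------------
    # thermodynamic bookkeeping
    # ------------------------------------------------------------------
    def cycle_consistent(self, atol: float = 1e-9) -> bool:
        """True if every reaction cycle has zero affinity (ln kf/kb sums).

        Uses a spanning-tree test on the species graph: assign each
        species a potential from ln(kf/kb) along tree edges and check
        every off-tree reaction closes.  Multi-molecular reactions are
        handled through weighted potentials.
        """
        # potential phi_s such that for each reaction:
        #   sum_s nu_{rs} phi_s = ln(kf_r/kb_r)
        # solvable iff the affinity vector lies in the row space of nu.
        sub, prod = self.stoich_arrays()
        nu = (prod - sub).astype(float)
        kf, kb = self.rate_vectors()
        if np.any(kb == 0) or np.any(kf == 0):
            raise ValueError("cycle consistency needs strictly positive rates")
        A = np.log(kf / kb)
        sol, res, rank, _ = np.linalg.lstsq(nu, A, rcond=None)
        resid = nu @ sol - A
        return bool(np.max(np.abs(resid)) < atol)
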