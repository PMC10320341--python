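"""Reference parameter sets for the three-species model.

Two bundled presets cover the two study conditions the model is used
under:

``accuracy``
    The error-energy study set: slow activator (D2 = 0.012 um^2/s),
    moderate inhibitor diffusion (D1 = D3 = 0.3), X3 cycle much slower
    than the main cycle.  The driving is swept by varying kt21 (and
    k12); the bundled default kt21 = 1e-6 s^-1 um^2 sits well inside
    the patterned regime (W ~ 4.8 kT).

``robustness``
    The molecule-number robustness study set: fast inhibitor
    (D1 = D3 = 1.8 um^2/s), ten-fold faster X3 cycle, operating
    irreversibility Gamma = 0.011 with kt21 = 1.67e-5; kt12 is derived
    from Gamma (it is not independently specified for this set).

Both use a closed domain of L = 6 um in 60 boxes and a default total
molecule number N = 7200.
"""
from __future__ import annotations

from dataclasses import dataclass

from .model import DiffusionConstants, Geometry, RateConstants

__all__ = ["Preset", "get_preset", "PRESETS"]


@dataclass(frozen=True)
class Preset:
    name: str
    rates: RateConstants
    diffusion: DiffusionConstants
    geometry: Geometry
    N: int

    @property
    def c_tot(self) -> float:
        return self.N / self.geometry.L


_GEOM = Geometry(L=6.0, n_box=60)

_ACCURACY = Preset(
    name="accuracy",
    rates=RateConstants(
        k12=0.5, k21=3.6,
        k23=0.0139, k32=1.39e-5, k31=0.0416, k13=0.0139,
        kt12=1.67e-5, kt21=1.0e-6,
    ),
    diffusion=DiffusionConstants(D1=0.3, D2=0.012),
    geometry=_GEOM,
    N=7200,
)

# Operating irreversibility of the robustness set; kt12 follows from
# Gamma = kt21 k12 / (kt12 k21).
GAMMA_ROBUSTNESS = 0.011
_KT21_R = 1.67e-5
_K12_R, _K21_R = 0.5, 3.6
_KT12_R = _KT21_R * _K12_R / (GAMMA_ROBUSTNESS * _K21_R)

_ROBUSTNESS = Preset(
    name="robustness",
    rates=RateConstants(
        k12=_K12_R, k21=_K21_R,
        k23=0.139, k32=0.0139, k31=0.416, k13=0.139,
        kt12=_KT12_R, kt21=_KT21_R,
    ),
    diffusion=DiffusionConstants(D1=1.8, D2=0.012),
    geometry=_GEOM,
    N=7200,
)

PRESETS: dict[str, Preset] = {p.name: p for p in (_ACCURACY, _ROBUSTNESS)}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
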