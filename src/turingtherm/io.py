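"""Configuration files and tabular kymograph I/O.

Kymographs are written as plain delimited text, one row per
(time, box): columns t (s), x (um), then one concentration column per
species (um^-1).  A '#'-prefixed header block carries units and
provenance (parameters, seed) as YAML.  Configs are YAML with explicit
units; the bundled presets expand to the reference parameter sets.
"""
from __future__ import annotations

import io as _io
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import Kymograph
from .model import DiffusionConstants, Geometry, RateConstants
from .presets import PRESETS, Preset, get_preset

__all__ = [
    "ExperimentConfig",
    "load_config",
    "save_config",
    "write_kymograph",
    "read_kymograph",
]

_RATE_FIELDS = ("k12", "k21", "k23", "k32", "k31", "k13", "kt12", "kt21")


@dataclass
class ExperimentConfig:
    """Fully explicit description of one experiment run.

    Every run is determined by this object plus seed_base; it is
    serialized alongside outputs for provenance.
    """

    driver: str = "simulate"
    preset: str | None = None
    rates: dict | None = None            # overrides, units s^-1 / s^-1 um^2
    diffusion: dict | None = None        # um^2/s
    L: float | None = None               # um
    n_box: int | None = None
    N: int | None = None
    t_end: float = 100.0                 # s
    sample_dt: float = 1.0               # s
    n_replicates: int = 1
    seed_base: int = 0
    scale: float = 1.0                   # uniform desk-scale reduction factor
    sweep: dict = field(default_factory=dict)
    out_dir: str = "."

    def resolve(self) -> tuple[RateConstants, DiffusionConstants, Geometry, int]:
        if self.preset is not None:
            p = get_preset(self.preset)
            rates, diff, geom, N = p.rates, p.diffusion, p.geometry, p.N
        else:
            rates = diff = geom = None
            N = None
        if self.rates:
            base = {f: getattr(rates, f) for f in _RATE_FIELDS} if rates else {}
            base.update(self.rates)
            unknown = set(base) - set(_RATE_FIELDS)
            if unknown:
                raise ValueError(f"unknown rate field(s): {sorted(unknown)}")
            rates = RateConstants(**base)
        if self.diffusion:
            d = {"D1": None, "D2": None, "D3": None}
            if diff:
                d.update(D1=diff.D1, D2=diff.D2, D3=diff.D3)
            d.update(self.diffusion)
            unknown = set(self.diffusion) - {"D1", "D2", "D3"}
            if unknown:
                raise ValueError(f"unknown diffusion field(s): {sorted(unknown)}")
            diff = DiffusionConstants(**d)
        if self.L is not None or self.n_box is not None:
            geom = Geometry(
                L=self.L if self.L is not None else (geom.L if geom else 6.0),
                n_box=self.n_box if self.n_box is not None else (geom.n_box if geom else 60),
            )
        if self.N is not None:
            N = self.N
        if rates is None or diff is None or geom is None or N is None:
            raise ValueError("config incomplete: give a preset or explicit blocks")
        return rates, diff, geom, N


_CONFIG_FIELDS = set(ExperimentConfig.__dataclass_fields__)


def load_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = ExperimentConfig(**raw)
    cfg.resolve()  # validate eagerly
    return cfg


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def write_kymograph(kym: Kymograph, path: str | Path, species_names=None) -> None:
    S = kym.u.shape[1]
    names = list(species_names or [f"u{i+1}" for i in range(S)])
    meta = {
        "units": {"t": "s", "x": "um", **{n: "um^-1" for n in names}},
        "n_box": int(len(kym.x)),
        "seed": kym.meta.get("seed"),
        "sample_dt": kym.meta.get("sample_dt"),
    }
    buf = _io.StringIO()
    for line in yaml.safe_dump(meta, sort_keys=False).splitlines():
        buf.write(f"# {line}\n")
    T, _, nx = kym.u.shape
    tcol = np.repeat(kym.times, nx)
    xcol = np.tile(kym.x, T)
    cols = {"t": tcol, "x": xcol}
    for i, n in enumerate(names):
        cols[n] = kym.u[:, i, :].reshape(-1)
    pd.DataFrame(cols).to_csv(buf, sep="\t", index=False, float_format="%.8g")
    Path(path).write_text(buf.getvalue())


def read_kymograph(path: str | Path) -> Kymograph:
    text = Path(path).read_text().splitlines()
    meta_lines = [l[2:] for l in text if l.startswith("# ")]
    meta = yaml.safe_load("\n".join(meta_lines)) or {}
    body = "\n".join(l for l in text if not l.startswith("#"))
    df = pd.read_csv(_io.StringIO(body), sep="\t")
    times = np.unique(df["t"].to_numpy())
    x = np.unique(df["x"].to_numpy())
    species = [c for c in df.columns if c not in ("t", "x")]
    nx, T, S = len(x), len(times), len(species)
    u = np.empty((T, S, nx))
    for i, n in enumerate(species):
        u[:, i, :] = df[n].to_numpy().reshape(T, nx)
    return Kymograph(times, x, u, meta=meta)
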