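"""Packaged LET and reference CL-yield tables.

The LET table gives unrestricted LET in water versus (particle, specific
energy), derived from a Barkas effective-charge scaling of a power-law fit to
proton stopping powers; in production use these values would come from a
transport code, and the packaged CSV can be overridden by any file with the
same columns.

The reference yield table is a synthetic stand-in for in-vitro-fitted CL
yields of a reference rodent line: CL/um versus radiation quality.  Its
values are generated from a documented parametric form (see
:func:`reference_yield_parametric`) chosen so that ion effectiveness per
unit dose approaches the photon value at vanishing LET and rises with LET as
lesion clustering increases.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, MissingSpeciesError

__all__ = [
    "PARTICLES",
    "LETTable",
    "ReferenceYields",
    "ReferenceLineInfo",
    "let_parametric",
    "reference_yield_parametric",
    "default_let_table",
    "default_reference_yields",
    "default_energy_grid",
]

# (name, Z, A): primary and fragment species covered by the packaged tables
PARTICLES: list[tuple[str, int, int]] = [
    ("H", 1, 1),
    ("He", 2, 4),
    ("Li", 3, 7),
    ("Be", 4, 9),
    ("B", 5, 11),
    ("C", 6, 12),
]

_PROTON_MASS_MEV = 931.494  # per nucleon rest energy used for beta(E)


def _beta2(energy_mev_u: np.ndarray | float) -> np.ndarray | float:
    gamma = 1.0 + np.asarray(energy_mev_u, dtype=float) / _PROTON_MASS_MEV
    return 1.0 - 1.0 / (gamma * gamma)


def let_parametric(z: int, energy_mev_u) -> np.ndarray | float:
    """Unrestricted LET in water, keV/um.

    Proton LET is approximated by 26 * E^-0.75 (E in MeV/u, valid ~1-400
    MeV/u); heavier ions scale with the Barkas effective charge
    Z_eff = Z (1 - exp(-125 beta Z^(-2/3))).
    """
    e = np.asarray(energy_mev_u, dtype=float)
    if np.any(e <= 0):
        raise ConfigurationError("energy must be positive")
    beta = np.sqrt(_beta2(e))
    z_eff = z * (1.0 - np.exp(-125.0 * beta * z ** (-2.0 / 3.0)))
    let_p = 26.0 * e**-0.75
    out = (z_eff / (1.0 * (1.0 - np.exp(-125.0 * beta)))) ** 2 * let_p
    return out if out.ndim else float(out)


# enhancement of the CL yield per unit dose with LET: unity at vanishing LET
# (photon-like sparse lesions), rising as intra-track clustering makes
# chromatin breaks increasingly likely per unit deposited energy
_ETA_LIN = 0.10
_ETA_LIN_POW = 0.8
_ETA_L0 = 45.0
_ETA_POW = 2.0


def clustering_enhancement(let_kev_um) -> np.ndarray | float:
    L = np.asarray(let_kev_um, dtype=float)
    return 1.0 + _ETA_LIN * L**_ETA_LIN_POW + (L / _ETA_L0) ** _ETA_POW


def reference_yield_parametric(
    let_kev_um,
    photon_yield_per_gy: float,
    nucleus_volume_um3: float,
) -> np.ndarray | float:
    """Reference-line ion CL yield in CL/um at the given LET.

    Constructed as (photon CL density per Gy) x (dose per unit track length)
    x (clustering enhancement): 0.1602*LET/V is the dose rate per um of
    track, so the enhancement factor alone carries the radiation-quality
    dependence beyond energy bookkeeping.
    """
    L = np.asarray(let_kev_um, dtype=float)
    base = photon_yield_per_gy * 0.1602 * L / nucleus_volume_um3
    return base * clustering_enhancement(L)


def default_energy_grid(n: int = 16) -> np.ndarray:
    """Log-spaced specific energies, 1-400 MeV/u."""
    return np.geomspace(1.0, 400.0, n)


def _packaged(name: str):
    return importlib.resources.files("ionrbe.data").joinpath(name)


class LETTable:
    """LET lookup by (particle, energy) with log-log interpolation."""

    def __init__(self, df: pd.DataFrame) -> None:
        need = {"particle", "Z", "A", "energy_mev_u", "let_kev_um"}
        if not need <= set(df.columns):
            raise ConfigurationError(f"LET table needs columns {sorted(need)}")
        self.df = df.sort_values(["particle", "energy_mev_u"]).reset_index(drop=True)
        self._by_particle = {
            p: (g["energy_mev_u"].to_numpy(), g["let_kev_um"].to_numpy())
            for p, g in self.df.groupby("particle")
        }

    @classmethod
    def from_csv(cls, path) -> "LETTable":
        return cls(pd.read_csv(path, comment="#"))

    def __call__(self, particle: str, energy_mev_u: float) -> float:
        if particle not in self._by_particle:
            raise MissingSpeciesError(f"particle {particle!r} not in LET table")
        e, let = self._by_particle[particle]
        x = np.log(np.clip(energy_mev_u, e[0], e[-1]))
        return float(np.exp(np.interp(x, np.log(e), np.log(let))))

    def energy_for_let(self, particle: str, let_kev_um: float) -> float:
        """Invert the (monotone decreasing) LET-energy relation."""
        if particle not in self._by_particle:
            raise MissingSpeciesError(f"particle {particle!r} not in LET table")
        e, let = self._by_particle[particle]
        if not (let[-1] <= let_kev_um <= let[0]):
            raise ConfigurationError(
                f"LET {let_kev_um} keV/um outside tabulated range "
                f"[{let[-1]:.3g}, {let[0]:.3g}] for {particle}"
            )
        y = np.log(let[::-1])
        x = np.log(e[::-1])
        return float(np.exp(np.interp(np.log(let_kev_um), y, x)))

    def zA(self, particle: str) -> tuple[int, int]:
        row = self.df[self.df["particle"] == particle].iloc[0]
        return int(row["Z"]), int(row["A"])


@dataclass(frozen=True)
class ReferenceLineInfo:
    """Photon yield and nucleus volume of the reference cell line."""

    photon_yield_per_gy: float
    nucleus_volume_um3: float


class ReferenceYields:
    """Reference-line ion CL yields (CL/um) by (particle, energy)."""

    def __init__(self, df: pd.DataFrame, line: ReferenceLineInfo) -> None:
        need = {"particle", "energy_mev_u", "let_kev_um", "cl_per_um"}
        if not need <= set(df.columns):
            raise ConfigurationError(f"yield table needs columns {sorted(need)}")
        self.df = df.sort_values(["particle", "energy_mev_u"]).reset_index(drop=True)
        self.line = line
        self._by_particle = {
            p: (g["energy_mev_u"].to_numpy(), g["cl_per_um"].to_numpy())
            for p, g in self.df.groupby("particle")
        }

    @classmethod
    def from_csv(cls, path, line: ReferenceLineInfo) -> "ReferenceYields":
        return cls(pd.read_csv(path, comment="#"), line)

    def __call__(self, particle: str, energy_mev_u: float) -> float:
        if particle not in self._by_particle:
            raise ConfigurationError(
                f"no reference CL yield for ({particle!r}, {energy_mev_u} MeV/u)"
            )
        e, y = self._by_particle[particle]
        x = np.log(np.clip(energy_mev_u, e[0], e[-1]))
        return float(np.exp(np.interp(x, np.log(e), np.log(y))))


def default_let_table() -> LETTable:
    return LETTable.from_csv(_packaged("let_table.csv"))


def default_reference_yields() -> ReferenceYields:
    with _packaged("reference_line.yaml").open() as fh:
        meta = yaml.safe_load(fh)
    line = ReferenceLineInfo(
        photon_yield_per_gy=float(meta["photon_yield_per_gy"]),
        nucleus_volume_um3=float(meta["nucleus_volume_um3"]),
    )
    return ReferenceYields.from_csv(_packaged("reference_yields.csv"), line)


def generate_let_frame(
    particles=PARTICLES, energies: np.ndarray | None = None
) -> pd.DataFrame:
    if energies is None:
        energies = default_energy_grid(25)
    rows = []
    for name, z, a in particles:
        for e in energies:
            rows.append(
                {
                    "particle": name,
                    "Z": z,
                    "A": a,
                    "energy_mev_u": round(float(e), 6),
                    "let_kev_um": round(float(let_parametric(z, e)), 6),
                }
            )
    return pd.DataFrame(rows)


def generate_reference_yield_frame(
    line: ReferenceLineInfo,
    particles=PARTICLES,
    energies: np.ndarray | None = None,
) -> pd.DataFrame:
    if energies is None:
        energies = default_energy_grid(25)
    rows = []
    for name, z, a in particles:
        for e in energies:
            let = float(let_parametric(z, e))
            y = float(
                reference_yield_parametric(
                    let, line.photon_yield_per_gy, line.nucleus_volume_um3
                )
            )
            rows.append(
                {
                    "particle": name,
                    "Z": z,
                    "A": a,
                    "energy_mev_u": round(float(e), 6),
                    "let_kev_um": round(let, 6),
                    "cl_per_um": round(y, 8),
                }
            )
    return pd.DataFrame(rows)
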