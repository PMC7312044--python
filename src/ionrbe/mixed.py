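"""Mixed-field radiosensitivity, survival, RBE-weighted dose, and RBE.

Per voxel of a treatment field, the particle spectrum (dose contributions by
particle type and energy) is folded with the radiobiological table using the
dose-weighted mixing rules of the theory of dual radiation action (TDRA):

    alpha = sum(alpha_i D_i) / sum(D_i)
    sqrt(beta) = sum(sqrt(beta_i) D_i) / sum(D_i)   (default; a linear
                 beta-weighting variant is available)

Survival follows the LQ model applied per fraction with full inter-fraction
repair; the RBE-weighted dose is the photon dose producing the same survival
under the same fractionation, and RBE = D_RBE / D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingSpeciesError
from .survival import LQParameters, RadiobiologicalTable

__all__ = [
    "SpectrumEntry",
    "VoxelSpectrum",
    "FractionationScheme",
    "RBEProfile",
    "lookup_LQ",
    "mix_alpha_beta",
    "survival_mixed",
    "rbe_weighted_dose",
    "rbe",
    "rbe_monochromatic",
    "lq_isoeffect_dose",
    "profile",
    "read_spectra_csv",
    "write_spectra_csv",
]

SPECTRUM_COLUMNS = [
    "voxel_id",
    "depth_mm",
    "particle",
    "Z",
    "A",
    "energy_mev_u",
    "let_kev_um",
    "dose_gy",
]


@dataclass(frozen=True)
class SpectrumEntry:
    particle: str
    z: int
    a: int
    energy_mev_u: float
    let_kev_um: float
    dose_gy: float

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ConfigurationError("component dose must be non-negative")


@dataclass(frozen=True)
class VoxelSpectrum:
    """Per-voxel list of (particle, energy, LET, dose) contributions."""

    voxel_id: int
    depth_mm: float
    entries: tuple[SpectrumEntry, ...]

    @property
    def total_dose_gy(self) -> float:
        return float(sum(e.dose_gy for e in self.entries))

    @property
    def dose_averaged_let(self) -> float:
        D = self.total_dose_gy
        if D == 0:
            return float("nan")
        return float(sum(e.let_kev_um * e.dose_gy for e in self.entries) / D)


@dataclass(frozen=True)
class FractionationScheme:
    """Equal fractions with full inter-fraction repair."""

    n_fractions: int = 1

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ConfigurationError("need at least one fraction")


@dataclass
class RBEProfile:
    """Voxel-wise mixed-field quantities along the depth axis."""

    df: pd.DataFrame  # voxel_id, depth_mm, dose_gy, alpha, beta, survival, d_rbe_gy, rbe

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def lookup_LQ(
    table: RadiobiologicalTable, particle: str, energy_mev_u: float
) -> tuple[float, float]:
    """(alpha_i, beta_i) at the given energy, log-energy interpolated.

    Queries outside the tabulated grid clamp to the edge rows.
    """
    sub = table.df[table.df["particle"] == particle]
    if sub.empty:
        raise MissingSpeciesError(f"particle {particle!r} not in radiobiological table")
    e = sub["energy_mev_u"].to_numpy()
    x = np.log(np.clip(energy_mev_u, e[0], e[-1]))
    alpha = float(np.interp(x, np.log(e), sub["alpha"].to_numpy()))
    beta = float(np.interp(x, np.log(e), sub["beta"].to_numpy()))
    return alpha, beta


def mix_alpha_beta(
    spectrum: VoxelSpectrum,
    table: RadiobiologicalTable,
    beta_mixing: str = "sqrt",
) -> tuple[float, float]:
    """TDRA dose-weighted mixed (alpha, beta) for one voxel spectrum."""
    if beta_mixing not in ("sqrt", "linear"):
        raise ConfigurationError("beta_mixing must be 'sqrt' or 'linear'")
    D = spectrum.total_dose_gy
    if D <= 0:
        raise ConfigurationError("mixed-field parameters undefined at zero dose")
    num_a = 0.0
    num_b = 0.0
    for e in spectrum.entries:
        ai, bi = lookup_LQ(table, e.particle, e.energy_mev_u)
        num_a += ai * e.dose_gy
        num_b += (np.sqrt(bi) if beta_mixing == "sqrt" else bi) * e.dose_gy
    alpha = num_a / D
    beta = (num_b / D) ** 2 if beta_mixing == "sqrt" else num_b / D
    return float(alpha), float(beta)


def survival_mixed(
    alpha: float,
    beta: float,
    scheme: FractionationScheme,
    total_dose_gy: float,
) -> float:
    """LQ survival of the full schedule: -ln S = n (alpha d + beta d^2), d = D/n."""
    if alpha < 0 or beta < 0 or total_dose_gy < 0:
        raise ConfigurationError("alpha, beta and dose must be non-negative")
    d = total_dose_gy / scheme.n_fractions
    return float(np.exp(-scheme.n_fractions * (alpha * d + beta * d * d)))


def lq_isoeffect_dose(alpha: float, beta: float, neg_log_s: float) -> float:
    """Dose D solving alpha*D + beta*D^2 = -ln S (non-negative root)."""
    if neg_log_s < 0:
        raise ConfigurationError("-ln S must be non-negative")
    if beta > 0:
        return float((-alpha + np.sqrt(alpha * alpha + 4 * beta * neg_log_s)) / (2 * beta))
    if alpha <= 0:
        raise ConfigurationError("degenerate LQ parameters (alpha = beta = 0)")
    return float(neg_log_s / alpha)


def rbe_weighted_dose(
    survival: float,
    photon: LQParameters,
    scheme: FractionationScheme = FractionationScheme(1),
) -> float:
    """Photon dose iso-effective to the given survival under the same schedule.

    The per-fraction photon dose d_X solves
    alpha_X d + beta_X d^2 = -ln(S)/n; D_RBE = n d_X.
    """
    if not (0 < survival <= 1):
        raise ConfigurationError("survival must lie in (0, 1]")
    neg_log_s_fx = -np.log(survival) / scheme.n_fractions
    return scheme.n_fractions * lq_isoeffect_dose(photon.alpha, photon.beta, neg_log_s_fx)


def rbe(d_rbe_gy: float, dose_gy: float) -> float:
    """RBE = RBE-weighted dose / physical dose."""
    if dose_gy <= 0:
        raise ConfigurationError("RBE undefined at zero physical dose")
    return d_rbe_gy / dose_gy


def rbe_monochromatic(
    ion: LQParameters,
    photon: LQParameters,
    survival_level: Optional[float] = None,
    ion_dose_gy: Optional[float] = None,
) -> float:
    """RBE of a monochromatic ion beam at a survival level or an ion dose.

    RBE = D_X(S) / D_i(S) with D(S) the LQ iso-effect dose.  When an ion
    dose is given, S is first evaluated from the ion LQ parameters.
    """
    if (survival_level is None) == (ion_dose_gy is None):
        raise ConfigurationError("give exactly one of survival_level or ion_dose_gy")
    if ion_dose_gy is not None:
        if ion_dose_gy <= 0:
            raise ConfigurationError("ion dose must be positive")
        neg_log_s = ion.alpha * ion_dose_gy + ion.beta * ion_dose_gy**2
        d_i = ion_dose_gy
    else:
        if not (0 < survival_level < 1):
            raise ConfigurationError("survival level must lie in (0, 1)")
        neg_log_s = -np.log(survival_level)
        d_i = lq_isoeffect_dose(ion.alpha, ion.beta, neg_log_s)
    d_x = lq_isoeffect_dose(photon.alpha, photon.beta, neg_log_s)
    return d_x / d_i


def profile(
    spectra: Sequence[VoxelSpectrum],
    table: RadiobiologicalTable,
    photon: LQParameters,
    scheme: FractionationScheme = FractionationScheme(1),
    beta_mixing: str = "sqrt",
) -> RBEProfile:
    """Voxel-by-voxel mix -> survival -> D_RBE -> RBE along the field.

    Zero-dose voxels are reported with null biological quantities rather
    than raising.
    """
    if not spectra:
        raise ConfigurationError("profile requires at least one voxel spectrum")
    rows = []
    for sp in spectra:
        D = sp.total_dose_gy
        if D == 0:
            rows.append(
                {
                    "voxel_id": sp.voxel_id,
                    "depth_mm": sp.depth_mm,
                    "dose_gy": 0.0,
                    "alpha": np.nan,
                    "beta": np.nan,
                    "survival": 1.0,
                    "d_rbe_gy": 0.0,
                    "rbe": np.nan,
                }
            )
            continue
        try:
            a, b = mix_alpha_beta(sp, table, beta_mixing=beta_mixing)
        except MissingSpeciesError as err:
            raise MissingSpeciesError(f"voxel {sp.voxel_id}: {err}") from err
        s = survival_mixed(a, b, scheme, D)
        d_rbe = rbe_weighted_dose(s, photon, scheme)
        rows.append(
            {
                "voxel_id": sp.voxel_id,
                "depth_mm": sp.depth_mm,
                "dose_gy": D,
                "alpha": a,
                "beta": b,
                "survival": s,
                "d_rbe_gy": d_rbe,
                "rbe": d_rbe / D,
            }
        )
    return RBEProfile(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# spectrum CSV dialect
# ---------------------------------------------------------------------------

def spectra_to_frame(spectra: Sequence[VoxelSpectrum]) -> pd.DataFrame:
    rows = []
    for sp in spectra:
        for e in sp.entries:
            rows.append(
                {
                    "voxel_id": sp.voxel_id,
                    "depth_mm": sp.depth_mm,
                    "particle": e.particle,
                    "Z": e.z,
                    "A": e.a,
                    "energy_mev_u": e.energy_mev_u,
                    "let_kev_um": e.let_kev_um,
                    "dose_gy": e.dose_gy,
                }
            )
    return pd.DataFrame(rows, columns=SPECTRUM_COLUMNS)


def write_spectra_csv(spectra: Sequence[VoxelSpectrum], path) -> None:
    spectra_to_frame(spectra).to_csv(path, index=False)


def read_spectra_csv(path) -> list[VoxelSpectrum]:
    df = pd.read_csv(path, comment="#")
    out = []
    for (vid, depth), g in df.groupby(["voxel_id", "depth_mm"], sort=True):
        entries = tuple(
            SpectrumEntry(
                particle=str(r["particle"]),
                z=int(r["Z"]),
                a=int(r["A"]),
                energy_mev_u=float(r["energy_mev_u"]),
                let_kev_um=float(r["let_kev_um"]),
                dose_gy=float(r["dose_gy"]),
            )
            for _, r in g.iterrows()
        )
        out.append(VoxelSpectrum(voxel_id=int(vid), depth_mm=float(depth), entries=entries))
    out.sort(key=lambda s: (s.depth_mm, s.voxel_id))
    return out
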