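"""Induction of critical lesions (CLs) in the nucleus.

A critical lesion is the model's elementary DNA damage: a chromatin break
that severs a chromosome into two independent fragments.  Photon-induced CLs
are distributed uniformly over the nucleus volume.  Ion-induced CLs are
placed along straight primary tracks parallel to the beam (cylinder) axis;
for heavy ions (Z >= 3) each CL is placed on the track core with probability
0.5 and in the delta-ray penumbra, at a 1/r radial distance, with probability
0.5 - reflecting the roughly equal partition of deposited energy between
track core and penumbra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, WrongRadiationKindError
from .karyo import NucleusGeometry, TerritoryConfiguration

__all__ = [
    "RadiationQuality",
    "CLYieldPhoton",
    "CLYieldIon",
    "CriticalLesion",
    "mean_track_count",
    "induce_photon",
    "induce_ion",
    "sample_penumbra_radius",
    "penumbra_radius_max",
    "PENUMBRA_CORE_UM",
]

# 1 Gy deposited by N tracks of LET L (keV/um) over chord h in a nucleus of
# cross-section A (um^2) and density rho (g/cm^3):
#   dose = N * L * KEV_UM_TO_GY_UM2 / (rho * A)
KEV_UM_TO_GY_UM2 = 0.1602

PENUMBRA_CORE_UM = 0.01  # inner radius of the 1/r penumbra sampling


@dataclass(frozen=True)
class RadiationQuality:
    """Radiation type: photon, or an ion identified by (Z, A) and energy.

    Ions carry a specific energy (MeV/u) and an unrestricted LET in water
    (keV/um).  Ions with Z <= 2 (protons, alphas) are 'light': all their CLs
    sit on the track core.  Ions with Z >= 3 (carbon and heavier, plus Li/Be/B
    fragments) are 'heavy' and get the 0.5/0.5 core/penumbra split.
    """

    kind: str  # "photon" | "light_ion" | "heavy_ion"
    z: int = 0
    a: int = 0
    energy_mev_u: float = 0.0
    let_kev_um: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "photon":
            return
        if self.kind not in ("light_ion", "heavy_ion"):
            raise ConfigurationError(f"unknown radiation kind {self.kind!r}")
        if self.let_kev_um <= 0:
            raise ConfigurationError("ion LET must be positive")
        if self.kind == "light_ion" and self.z > 2:
            raise ConfigurationError("light ions must have Z <= 2")
        if self.kind == "heavy_ion" and self.z < 3:
            raise ConfigurationError("heavy ions must have Z >= 3")

    @classmethod
    def photon(cls) -> "RadiationQuality":
        return cls(kind="photon")

    @classmethod
    def ion(cls, z: int, a: int, energy_mev_u: float, let_kev_um: float) -> "RadiationQuality":
        kind = "light_ion" if z <= 2 else "heavy_ion"
        return cls(kind=kind, z=z, a=a, energy_mev_u=energy_mev_u, let_kev_um=let_kev_um)

    @property
    def is_ion(self) -> bool:
        return self.kind != "photon"


@dataclass(frozen=True)
class CLYieldPhoton:
    """Mean number of CLs per Gy per cell for photon irradiation."""

    value: float  # CL / Gy / cell

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ConfigurationError("photon CL yield must be positive")


@dataclass(frozen=True)
class CLYieldIon:
    """Mean number of CLs per um of primary-ion path."""

    value: float  # CL / um

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ConfigurationError("ion CL yield must be non-negative")


@dataclass(frozen=True)
class CriticalLesion:
    """A chromatin break with its spatial and genomic coordinates."""

    position: tuple[float, float, float]  # um
    copy: int
    arm: str  # 'p' | 'q'
    genomic_mbp: float


def mean_track_count(
    dose_gy: float,
    let_kev_um: float,
    geometry: NucleusGeometry,
    density_g_cm3: float = 1.0,
) -> float:
    """Expected number of primary tracks through the nucleus at a given dose.

    Tracks run parallel to the cylinder axis, so each deposits
    LET x height keV; fluence-dose bookkeeping then gives
    N = dose * A * rho / (0.1602 * LET) with A the beam-facing area in um^2.
    """
    if let_kev_um <= 0:
        raise ConfigurationError("LET must be positive")
    if dose_gy < 0:
        raise ConfigurationError("dose must be non-negative")
    return dose_gy * geometry.cross_section_um2 * density_g_cm3 / (
        KEV_UM_TO_GY_UM2 * let_kev_um
    )


def _annotate(positions: np.ndarray, config: TerritoryConfiguration) -> list[CriticalLesion]:
    if len(positions) == 0:
        return []
    cid, arm, genomic = config.locate_arrays(positions)
    return [
        CriticalLesion(tuple(map(float, p)), int(c), "pq"[int(a)], float(g))
        for p, c, a, g in zip(positions, cid, arm, genomic)
    ]


def induce_photon(
    yield_photon: CLYieldPhoton,
    dose_gy: float,
    config: TerritoryConfiguration,
    rng: np.random.Generator,
) -> list[CriticalLesion]:
    """Poisson(yield x dose) CLs, uniform over the nucleus volume."""
    if dose_gy < 0:
        raise ConfigurationError("dose must be non-negative")
    positions = sample_photon_positions(yield_photon.value, dose_gy, config.geometry, rng)
    return _annotate(positions, config)


def sample_photon_positions(
    yield_per_gy: float,
    dose_gy: float,
    geometry: NucleusGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    n = int(rng.poisson(yield_per_gy * dose_gy))
    return geometry.sample_uniform(n, rng)


def penumbra_radius_max(quality: RadiationQuality) -> float:
    """Outer penumbra radius in um: 0.062 * E^1.7 (E in MeV/u).

    Kiefer-type scaling of the maximum delta-ray range with specific energy;
    floored just above the core radius so the sampling interval stays valid.
    """
    if quality.energy_mev_u <= 0:
        raise ConfigurationError("penumbra radius requires energy > 0")
    return max(0.062 * quality.energy_mev_u**1.7, PENUMBRA_CORE_UM * (1 + 1e-9))


def sample_penumbra_radius(
    quality: RadiationQuality,
    rng: np.random.Generator,
    size: Optional[int] = None,
) -> np.ndarray | float:
    """Radial displacement of a penumbra CL from its track core.

    Sampled with density proportional to 1/r on [r_core, r_max] (inverse-CDF:
    r = r_core * (r_max/r_core)**u), the amorphous-track convention for the
    radial spread of delta-ray energy deposition.
    """
    if quality.kind != "heavy_ion":
        raise WrongRadiationKindError("penumbra sampling applies to heavy ions only")
    r_max = penumbra_radius_max(quality)
    u = rng.random(size if size is not None else 1)
    r = PENUMBRA_CORE_UM * (r_max / PENUMBRA_CORE_UM) ** u
    return r if size is not None else float(r[0])


def sample_ion_positions(
    yield_ion_um: float,
    quality: RadiationQuality,
    dose_gy: float,
    geometry: NucleusGeometry,
    rng: np.random.Generator,
    density_g_cm3: float = 1.0,
):
    """CL positions for ion irradiation of one cell.

    Returns (positions (k,3), on_track (k,) bool, n_tracks).  Track entry
    points are uniform over the beam-facing disc; per-track CL counts are
    Poisson(yield x chord).  Heavy-ion penumbra CLs are displaced radially
    (1/r law, uniform azimuth) and re-sampled until they land inside the
    nucleus, so the 0.5/0.5 core/penumbra partition is preserved exactly.
    """
    if not quality.is_ion:
        raise WrongRadiationKindError("ion induction requires an ion quality")
    if dose_gy < 0:
        raise ConfigurationError("dose must be non-negative")
    n_tracks = int(rng.poisson(mean_track_count(dose_gy, quality.let_kev_um, geometry, density_g_cm3)))
    h = geometry.height
    R = geometry.radius_um
    if n_tracks == 0:
        return np.empty((0, 3)), np.empty(0, dtype=bool), 0
    r = R * np.sqrt(rng.random(n_tracks))
    th = rng.random(n_tracks) * 2 * np.pi
    ex, ey = r * np.cos(th), r * np.sin(th)
    counts = rng.poisson(yield_ion_um * h, size=n_tracks)
    k = int(counts.sum())
    if k == 0:
        return np.empty((0, 3)), np.empty(0, dtype=bool), n_tracks
    track = np.repeat(np.arange(n_tracks), counts)
    x = ex[track].copy()
    y = ey[track].copy()
    z = rng.random(k) * h
    if quality.kind == "heavy_ion":
        on_track = rng.random(k) < 0.5
        pen = np.nonzero(~on_track)[0]
        r_max = penumbra_radius_max(quality)
        todo = pen
        while todo.size:
            u = rng.random(todo.size)
            rr = PENUMBRA_CORE_UM * (r_max / PENUMBRA_CORE_UM) ** u
            phi = rng.random(todo.size) * 2 * np.pi
            px = ex[track[todo]] + rr * np.cos(phi)
            py = ey[track[todo]] + rr * np.sin(phi)
            ok = px**2 + py**2 <= R**2
            x[todo[ok]] = px[ok]
            y[todo[ok]] = py[ok]
            todo = todo[~ok]
    else:
        on_track = np.ones(k, dtype=bool)
    # clamp z of points exactly at the top face into the interior
    z = np.minimum(z, h * (1 - 1e-12))
    return np.column_stack([x, y, z]), on_track, n_tracks


def induce_ion(
    yield_ion: CLYieldIon,
    quality: RadiationQuality,
    dose_gy: float,
    config: TerritoryConfiguration,
    rng: np.random.Generator,
    return_details: bool = False,
):
    """Ion-induced CLs for one cell, annotated with chromosome coordinates."""
    positions, on_track, n_tracks = sample_ion_positions(
        yield_ion.value, quality, dose_gy, config.geometry, rng
    )
    cls_ = _annotate(positions, config)
    if return_details:
        return cls_, on_track, n_tracks
    return cls_
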