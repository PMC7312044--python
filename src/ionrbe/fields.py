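"""Synthetic voxel spectra emulating monochromatic and SOBP-like fields.

These fixtures stand in for a particle-transport calculation: instead of
modelling Bragg-curve physics, each recipe prescribes the *dose-averaged LET*
at a set of depth positions (the quantity through which the experiments are
reported) and the generator solves for component energies, from the packaged
LET table, that realise those values exactly.  Physical dose is flat across
the SOBP window; heavy-ion recipes include lighter fragment species at fixed
dose fractions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional

import yaml

from .errors import ConfigurationError
from .mixed import SpectrumEntry, VoxelSpectrum
from .tables import LETTable, default_let_table

__all__ = [
    "FragmentSpec",
    "SOBPRecipe",
    "make_monochromatic",
    "make_sobp",
    "load_recipe",
    "packaged_recipe",
    "PACKAGED_RECIPES",
]

PACKAGED_RECIPES = ("carbon_1cm_sobp", "carbon_6cm_sobp", "proton_6cm_sobp")

# relative half-spread of the primary's two-component energy mix per voxel;
# the pair brackets the target LET symmetrically, leaving the dose-averaged
# LET exactly on target
_PRIMARY_LET_SPREAD = 0.10


@dataclass(frozen=True)
class FragmentSpec:
    name: str
    z: int
    a: int
    dose_fraction: float
    energy_mev_u: float  # fixed fragment energy (fragments are fast and sparse)


@dataclass(frozen=True)
class SOBPRecipe:
    """Prescription for a synthetic SOBP-like field.

    ``window_positions_mm`` / ``window_let_kev_um`` give the evaluation
    depths inside the SOBP window and the dose-averaged LET to realise at
    each; ``plateau_positions_mm`` get the entrance-energy primary only.
    """

    name: str
    species: str
    species_z: int
    species_a: int
    entrance_energy_mev_u: float
    window_mm: tuple[float, float]
    window_positions_mm: tuple[float, ...]
    window_let_kev_um: tuple[float, ...]
    peak_dose_gy: float
    plateau_dose_gy: float = 0.0
    plateau_positions_mm: tuple[float, ...] = ()
    fragments: tuple[FragmentSpec, ...] = ()
    # relative half-spread of the primary two-component energy mix; 0 gives a
    # single monochromatic primary component per voxel
    primary_let_spread: float = _PRIMARY_LET_SPREAD

    def __post_init__(self) -> None:
        if not (0 <= self.primary_let_spread < 1):
            raise ConfigurationError("primary_let_spread must lie in [0, 1)")
        if len(self.window_positions_mm) != len(self.window_let_kev_um):
            raise ConfigurationError("positions and LET targets must align")
        lo, hi = self.window_mm
        if not all(lo <= p <= hi for p in self.window_positions_mm):
            raise ConfigurationError("window positions must lie inside the window")
        if self.peak_dose_gy < 0 or self.plateau_dose_gy < 0:
            raise ConfigurationError("dose levels must be non-negative")
        frac = sum(f.dose_fraction for f in self.fragments)
        if not (0 <= frac < 1):
            raise ConfigurationError("fragment dose fractions must sum to < 1")


def make_monochromatic(
    particle: str,
    z: int,
    a: int,
    energy_mev_u: float,
    let_kev_um: float,
    dose_gy: float,
    voxel_id: int = 0,
    depth_mm: float = 0.0,
) -> VoxelSpectrum:
    """Single-component spectrum (empty at zero dose)."""
    if dose_gy < 0:
        raise ConfigurationError("dose must be non-negative")
    entries = ()
    if dose_gy > 0:
        entries = (
            SpectrumEntry(
                particle=particle,
                z=z,
                a=a,
                energy_mev_u=energy_mev_u,
                let_kev_um=let_kev_um,
                dose_gy=dose_gy,
            ),
        )
    return VoxelSpectrum(voxel_id=voxel_id, depth_mm=depth_mm, entries=entries)


def _primary_pair(
    recipe: SOBPRecipe,
    let_table: LETTable,
    target_let: float,
    dose: float,
) -> list[SpectrumEntry]:
    """Primary component(s) whose dose-averaged LET equals target_let."""
    spread = recipe.primary_let_spread
    if spread == 0:
        e = let_table.energy_for_let(recipe.species, target_let)
        return [
            SpectrumEntry(
                particle=recipe.species,
                z=recipe.species_z,
                a=recipe.species_a,
                energy_mev_u=e,
                let_kev_um=target_let,
                dose_gy=dose,
            )
        ]
    lo = target_let * (1 - spread)
    hi = target_let * (1 + spread)
    out = []
    for l in (lo, hi):
        e = let_table.energy_for_let(recipe.species, l)
        out.append(
            SpectrumEntry(
                particle=recipe.species,
                z=recipe.species_z,
                a=recipe.species_a,
                energy_mev_u=e,
                let_kev_um=l,
                dose_gy=dose / 2,
            )
        )
    return out


def make_sobp(
    recipe: SOBPRecipe,
    seed: int = 0,
    let_table: Optional[LETTable] = None,
) -> list[VoxelSpectrum]:
    """Generate the voxel spectra of an SOBP-like field.

    Deterministic for a given recipe (the seed is accepted for interface
    uniformity).  In window voxels the primary contributes 1 - sum(fragment
    fractions) of the dose as two components bracketing the LET needed to
    land the *dose-averaged* LET exactly on the recipe target.
    """
    if let_table is None:
        let_table = default_let_table()
    frag_entries_unit = []
    frag_let_sum = 0.0
    for f in recipe.fragments:
        let = let_table(f.name, f.energy_mev_u)
        frag_let_sum += f.dose_fraction * let
        frag_entries_unit.append((f, let))
    phi_primary = 1.0 - sum(f.dose_fraction for f in recipe.fragments)

    spectra: list[VoxelSpectrum] = []
    vid = 0
    for depth in recipe.plateau_positions_mm:
        let = let_table(recipe.species, recipe.entrance_energy_mev_u)
        entries = [
            SpectrumEntry(
                recipe.species,
                recipe.species_z,
                recipe.species_a,
                recipe.entrance_energy_mev_u,
                let,
                recipe.plateau_dose_gy,
            )
        ]
        spectra.append(VoxelSpectrum(vid, float(depth), tuple(entries)))
        vid += 1

    for depth, l_star in zip(recipe.window_positions_mm, recipe.window_let_kev_um):
        dose = recipe.peak_dose_gy
        # dose-averaged LET constraint: phi_p * L_p + sum(phi_j * L_j) = L*
        l_primary = (l_star - frag_let_sum) / phi_primary
        if l_primary <= 0:
            raise ConfigurationError(
                f"fragment LET contributions exceed target {l_star} keV/um"
            )
        entries = _primary_pair(recipe, let_table, l_primary, dose * phi_primary)
        for f, let in frag_entries_unit:
            entries.append(
                SpectrumEntry(
                    f.name, f.z, f.a, f.energy_mev_u, let, dose * f.dose_fraction
                )
            )
        spectra.append(VoxelSpectrum(vid, float(depth), tuple(entries)))
        vid += 1
    return spectra


# ---------------------------------------------------------------------------
# recipe YAML
# ---------------------------------------------------------------------------

def _recipe_from_dict(d: dict) -> SOBPRecipe:
    frags = tuple(
        FragmentSpec(
            name=f["name"],
            z=int(f["Z"]),
            a=int(f["A"]),
            dose_fraction=float(f["dose_fraction"]),
            energy_mev_u=float(f["energy_mev_u"]),
        )
        for f in d.get("fragments", [])
    )
    sp = d["species"]
    return SOBPRecipe(
        name=d["name"],
        species=sp["name"],
        species_z=int(sp["Z"]),
        species_a=int(sp["A"]),
        entrance_energy_mev_u=float(d["entrance_energy_mev_u"]),
        window_mm=tuple(float(x) for x in d["window_mm"]),
        window_positions_mm=tuple(float(x) for x in d["window_positions_mm"]),
        window_let_kev_um=tuple(float(x) for x in d["window_let_kev_um"]),
        peak_dose_gy=float(d["peak_dose_gy"]),
        plateau_dose_gy=float(d.get("plateau_dose_gy", 0.0)),
        plateau_positions_mm=tuple(float(x) for x in d.get("plateau_positions_mm", ())),
        fragments=frags,
        primary_let_spread=float(d.get("primary_let_spread", _PRIMARY_LET_SPREAD)),
    )


def load_recipe(path) -> SOBPRecipe:
    with open(path) as fh:
        return _recipe_from_dict(yaml.safe_load(fh))


def packaged_recipe(name: str) -> SOBPRecipe:
    if name not in PACKAGED_RECIPES:
        raise ConfigurationError(f"unknown recipe {name!r}; have {PACKAGED_RECIPES}")
    res = importlib.resources.files("ionrbe.data.recipes").joinpath(f"{name}.yaml")
    with res.open() as fh:
        return _recipe_from_dict(yaml.safe_load(fh))
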