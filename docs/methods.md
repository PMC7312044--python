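# Methods

`ionrbe` simulates how ionizing radiation kills clonogenic cells through
chromosome aberrations, and turns those simulations into the quantities a
particle-therapy physicist needs: linear-quadratic (LQ) radiosensitivity
tables per radiation quality, and voxel-wise RBE-weighted dose profiles for
mixed fields. This note records the model, its assumptions, the parameters
that matter, and the places where the design was genuinely open.

## The biophysical model

**Critical lesions.** The elementary event is a *critical lesion* (CL): a
chromatin break that severs a chromosome into two independent fragments.
CL yields are the model's first adjustable parameter — expressed per Gy and
per cell for photons, and per µm of primary track for ions — because the
molecular identity of the lesions that matter for aberration formation is
not settled; the yield absorbs it.

**Geometry of energy deposition.**

- *Photons*: CLs are Poisson in number (yield × dose) and uniform over the
  nucleus volume.
- *Ions*: primary particles cross the nucleus as straight parallel tracks
  along the cylinder axis. Track number is Poisson with mean
  `N = D·A·ρ / (0.1602·LET)` (A the beam-facing area in µm², LET in keV/µm),
  which is exact fluence–dose bookkeeping for constant LET across the 6-µm
  chord. Per-track CL counts are Poisson(yield × chord length).
- *Light ions* (Z ≤ 2): all CLs lie on the track line.
- *Heavy ions* (Z ≥ 3): each CL independently sits on the track core with
  probability 0.5, otherwise in the delta-ray penumbra — reflecting the
  roughly equal split of deposited energy between core and penumbra. The
  penumbra radius is sampled with density ∝ 1/r on [0.01 µm, r_max] with
  r_max = 0.062·E^1.7 µm (E in MeV/u), a Kiefer-type maximum delta-ray
  range; the 1/r density corresponds to the 1/r² radial dose of amorphous
  track models integrated over cylindrical shells. Penumbra positions are
  re-sampled until they fall inside the nucleus, so the 0.5/0.5 partition is
  preserved exactly among deposited CLs. The radial law is isolated in one
  function and can be swapped.

**Chromosome territories.** The nucleus (default: upright cylinder, radius
6 µm, height 6 µm — the geometry used for the radiosensitivity database) is
voxelized at 0.25 µm and partitioned into one compact territory per
chromosome copy, with volume proportional to Mbp content. Construction:
seed voxels are placed with a spacing heuristic proportional to equivalent
territory radii; territories grow by synchronized accretion (always the
territory with the smallest fractional progress claims the next voxel of
its frontier); a boundary-diffusion sweep then repairs enclosure losses
until every territory is within a few percent of its Mbp-proportional
volume. Each territory's voxels are ordered by a greedy nearest-neighbour
walk (face > edge > corner preference), and that order is mapped linearly
onto the genomic coordinate, giving every point in the nucleus a
(chromosome copy, arm, Mbp position). In the packaged human karyotype this
walk keeps ~98 % of consecutive genomic steps spatially adjacent.

**Aberration formation.** Each CL's two flanking fragments acquire a free
end at the CL position. Rejoining follows a step function of initial
end-to-end distance: only ends closer than a threshold may join, where the
threshold is the mean centre-to-centre distance between face-adjacent
territories (≈3.3 µm for the human karyotype in the default nucleus). Each
end is first marked un-rejoinable with probability *f* — the model's second
adjustable parameter. Matching among the remaining ends is a random maximal
matching of the proximity graph: repeatedly, a uniformly random end with at
least one available partner within the threshold joins a uniformly random
such partner. Rearranged elements (chains or cycles of fragments) are then
scored: an element with k ≥ 2 centromeres counts k−1 dicentrics; a closed
element with exactly one centromere is a centric ring; any acentric element
with ≥ 3 Mbp of content is a *large deletion* (3 Mbp being the conventional
Giemsa visibility scale; configurable). One or more of these lethal
aberrations kills the clonogenic cell.

Two scoring conventions to keep in mind when reading aberration tallies:
acentric partners of exchanges are still scored as large deletions (this
inflates tallies but never changes the live/die decision, which only asks
for ≥ 1 lethal aberration), and multicentrics count centromeres−1
dicentrics. A consequence: −ln S is bounded above by the mean number of
scored lethal aberrations per cell rather than equal to it.

## Survival curves and the radiobiological database

Survival at a dose is the fraction of simulated cells with zero lethal
aberrations; S(0) = 1 exactly. Cells cycle through a small pool of
territory realisations (default 4) rather than rebuilding territories per
cell — a territory build costs ~0.5 s, the rest of a cell ~0.1–1 ms, and
the pool captures the territory-to-territory variability that matters at
far lower cost. Pool size is a parameter; a frozen single configuration is
also supported.

LQ fitting is weighted least squares of −ln S on (D, D²) through the
origin, weights from the binomial error of S propagated to the log scale,
with α, β clamped non-negative (iso-effect doses downstream take square
roots). The simulated response becomes visibly super-quadratic below
S ≈ 5 % (multiple lethal events per cell), so curves are fitted over the
range −ln S ≲ 3: the database uses an adaptive dose grid (a 400-cell probe
at 1 Gy sets the top dose near −ln S = 3, clamped to [0.8, 8] Gy, six
points), and photon calibration fits 1–6 Gy. Per dose, cells are simulated
until the binomial standard error of S falls below a target (default 0.01
for the database; tighter in the acceptance runs) or a cell cap is reached.

The database sweeps particle type and specific energy; each row records
(particle, Z, A, E, LET, α, β). Downstream lookups interpolate α and β
linearly in log energy, clamped at the grid edges.

## Calibration chain

1. **Photon anchor.** The photon pair (α_X, β_X) for the chordoma-like
   target tissue comes from inverting the Poisson TCP model
   `TCP = exp[−N·exp(−α_X D − β_X D d)]` with the published schedule
   (TCP = 0.60 at D = 35 Gy in d = 7 Gy fractions, N = 10⁷ cells/cm³ ×
   100 cm³) under the constraint α_X/β_X = 2.45 Gy. On the double-log scale
   the model is linear in β_X, so the bracketed root solve is exact:
   α_X = 0.1585 Gy⁻¹, β_X = 0.0647 Gy⁻². (Note 2.45 × the rounded
   β_X = 0.065 gives the commonly quoted 0.159.)
2. **Photon CL yield.** Bisection on the yield (log scale, common random
   numbers across evaluations) until the fitted α of the simulated photon
   curve matches α_X within tolerance (default 5 %). The default
   f = 0.022 was chosen once so that this calibrated curve reproduces not
   only α_X but also β_X — i.e. the simulated photon α/β ratio lands near
   2.45 Gy; with the calibrated yield (≈2.4 CL/Gy/cell) the fitted photon
   pair is (≈0.158, ≈0.065). f and the yield are the model's only two
   adjustable parameters, and this is exactly the degree of freedom they
   are meant to absorb.
3. **Ion yields.** For each (particle, energy), the reference-line ion
   yield is transferred to the target line by
   `(CL/µm) = (CL/µm)_ref · [(CL/Gy/cell)/(CL/Gy/cell)_ref] · V_ref/V`.

**Reference yields are synthetic placeholders.** The in-vitro-fitted
reference yields that a production database would use live in external
experimental fits and are not re-derived here. The packaged table is
generated from a documented parametric stand-in:
`(CL/µm)(LET) = y_ph_ref · 0.1602·LET/V_ref · η(LET)` with the clustering
enhancement `η(L) = 1 + 0.1·L^0.8 + (L/45)²`. The first factor makes ion
effectiveness per unit dose equal to the photon value as LET → 0 (so
proton RBE → ~1 from above); η carries the radiation-quality dependence —
the growing probability that deposited energy produces chromatin breaks as
ionization clusters densify. Its constants were fixed once, during design,
so that the chain lands in the radiobiologically expected ranges (proton
RBE ≈ 1.1–1.4 at 1.4–5.5 keV/µm; carbon α(LET) peaking near 150–200 keV/µm
with overkill beyond; SOBP-level RBE ≈ 3–5 at 2 Gy). The file is an
editable CSV: swapping in experimentally fitted yields requires no code
change.

The packaged LET table is likewise a stand-in for transport-code output: a
power-law fit to proton stopping power (26·E^−0.75 keV/µm, valid ~1–400
MeV/u) scaled by the Barkas effective charge for heavier species. It
reproduces, e.g., carbon LET ≈ 13.5 keV/µm at 280 MeV/u and ≈ 165 at
10 MeV/u.

## Mixed fields

Per voxel, dose contributions (particle, energy, LET, dose) are folded with
the table using dose-weighted mixing: α is the dose-weighted mean of α_i;
for β the dose-weighted mean of √β_i is squared (the dual-radiation-action
convention for the quadratic term; a linear β-weighting variant is
available behind `beta_mixing="linear"` — the difference is second-order
for the packaged fields). Survival applies the LQ form per fraction with
full inter-fraction repair: −ln S = n(αd + βd²), d = D/n. The RBE-weighted
dose is the photon dose iso-effective under the *same* fractionation,
obtained per fraction from the non-negative root of
α_X d_X + β_X d_X² = −ln S / n, and RBE = D_RBE/D. Two defining properties
are enforced by tests to 10⁻⁹–10⁻¹⁰: a field whose components all carry
(α_X, β_X) has RBE ≡ 1, and photon survival at D_RBE reproduces the
mixed-field survival exactly.

## Synthetic SOBP fields

The field generator stands in for particle transport and makes no attempt
at Bragg-curve physics. Each recipe prescribes evaluation depths and the
*dose-averaged LET* to realise at each — the quantity through which the
underlying experiments are reported — plus fixed fragment dose fractions
for heavy-ion beams (H and He at ~150 MeV/u, ~6 % and ~4.5 % of dose).
The generator solves for the primary energy that lands the dose-averaged
LET exactly on target (two components bracketing the target LET ±10 % give
the voxel an energy spread without moving the average), taking energies
from the packaged LET table. Physical dose is exactly flat across the
window. What this emulates: the monotone LET climb through an SOBP window,
fragment dilution, realistic dose-averaged LET values (16–99 keV/µm for
the 6-cm carbon field, 125 for the 1-cm field, 1.4–5.5 for the proton
field). What it does not: lateral scattering, the depth dependence of
fragment build-up, dose falloff, energy-spectrum tails. Passing tests on
these fixtures therefore validate the *biological* chain against
controlled spectra, not transport physics.

## Numerical choices and degenerate inputs

- All randomness flows from explicit `numpy` Generators seeded from the
  caller; identical seeds give bit-identical territory assignments, CL
  sets, and survival curves.
- Sub-voxel genomic positions use a deterministic low-discrepancy
  projection of the in-voxel offset, so `locate` is a pure function and
  CL annotations always agree with it; two CLs in one voxel still get
  distinct genomic coordinates.
- A CL falling exactly on a centromere position assigns the centromere to
  the p-side fragment (measure-zero tie).
- β is clamped at 0 by the non-negative fit; iso-effect doses then use the
  −ln S/α limit. An all-S = 1 curve returns a flagged degenerate fit
  rather than raising.
- Zero-dose voxels in a profile report null RBE rather than erroring;
  zero-dose spectra are invalid for mixing.
- Territory construction rejects voxelizations that would give any copy
  fewer than 8 voxels.

## Problem sizes

Default study sizes were chosen to resolve the quantities of interest with
Monte Carlo errors well below the effects being tested: survival points are
simulated to SE(S) ≤ 0.0075–0.01 (at most 10⁴ cells per dose), database
grids use 6 dose points per quality, ~10 energies for carbon and ~6 for
protons, and distributional checks use 10⁴–10⁵ samples. The acceptance
script re-runs the entire chain at these sizes in well under half an hour
on one core.

## Known limitations

- Aberration tallies (not the survival decision) double-count reciprocal
  products; dicentric yields are therefore upper-bound-flavoured.
- LET is constant across the nucleus chord; no energy loss, straggling, or
  angular divergence.
- The genomic embedding is a space-filling walk, not a polymer model;
  intra-arm contact statistics are only locality-faithful, not
  biophysically derived.
- The reference yield table and LET table are synthetic stand-ins (see
  above); absolute RBE values inherit their calibration, while the
  structural behaviours (LET peak, dose dependence, fractionation, mixing
  identities) are calibration-independent.
- Un-rejoined sub-threshold acentric pieces are non-lethal, following the
  metaphase-visibility qualifier; f is applied per end, not per fragment.
  Both readings of the convention are noted in the code where they apply.
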