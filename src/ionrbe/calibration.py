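"""Photon radiosensitivity from tumour-control data, and CL-yield calibration.

The photon (alpha_X, beta_X) pair of a cell line is anchored to clinical
outcome through the Poisson tumour-control-probability model

    TCP = exp[-N exp(-alpha_X D - beta_X D d)],

where N is the initial clonogen number (cell density x tumour volume), D the
total dose, and d the fractional dose.  Together with a known alpha/beta
ratio this fixes both parameters.  The photon CL yield of the simulator is
then tuned so that simulated photon survival reproduces alpha_X, and ion CL
yields for the cell line of interest are obtained from a reference line by
the scaling

    (CL/um) = (CL/um)_ref * [(CL/Gy/cell) / (CL/Gy/cell)_ref] * V_ref / V.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.optimize

from .errors import CalibrationError, ConfigurationError, DegenerateFitError
from .karyo import Karyotype, NucleusGeometry
from .damage import CLYieldIon, CLYieldPhoton, RadiationQuality
from .aberration import RejoiningParameters
from .survival import LQParameters, TerritoryPool, fit_LQ, simulate_survival

__all__ = [
    "TCPInputs",
    "CellLineContext",
    "solve_photon_LQ",
    "tcp",
    "calibrate_photon_yield",
    "scale_ion_yield",
    "CHORDOMA_TCP_INPUTS",
]


@dataclass(frozen=True)
class TCPInputs:
    """Clinical inputs closing the TCP equation for a photon schedule."""

    tcp: float
    total_dose_gy: float
    fractional_dose_gy: float
    tumor_volume_cm3: float
    cell_density_cm3: float
    alpha_beta_ratio_gy: float

    def __post_init__(self) -> None:
        if not (0 < self.tcp < 1):
            raise ConfigurationError("TCP must lie strictly in (0, 1)")
        if not (self.total_dose_gy >= self.fractional_dose_gy > 0):
            raise ConfigurationError("need D >= d > 0")
        if self.tumor_volume_cm3 <= 0 or self.cell_density_cm3 <= 0:
            raise ConfigurationError("volume and density must be positive")
        if self.alpha_beta_ratio_gy <= 0:
            raise ConfigurationError("alpha/beta ratio must be positive")

    @property
    def n_clonogens(self) -> float:
        return self.cell_density_cm3 * self.tumor_volume_cm3


# chordoma photon schedule (Henderson et al.): 35 Gy in 7-Gy fractions,
# TCP ~ 60%, 100 cm^3 tumour at 1e7 cells/cm^3, alpha/beta = 2.45 Gy
CHORDOMA_TCP_INPUTS = TCPInputs(
    tcp=0.60,
    total_dose_gy=35.0,
    fractional_dose_gy=7.0,
    tumor_volume_cm3=100.0,
    cell_density_cm3=1e7,
    alpha_beta_ratio_gy=2.45,
)


def tcp(alpha: float, beta: float, inputs: TCPInputs) -> float:
    """Poisson TCP for the given photon LQ parameters and schedule."""
    D = inputs.total_dose_gy
    d = inputs.fractional_dose_gy
    return float(np.exp(-inputs.n_clonogens * np.exp(-alpha * D - beta * D * d)))


def solve_photon_LQ(inputs: TCPInputs) -> LQParameters:
    """Invert the TCP model for (alpha_X, beta_X) at a fixed alpha/beta ratio.

    With alpha = ratio * beta, TCP is strictly increasing in beta, so a
    bracketed 1-D root solve is exact.  The root is found on the double-log
    scale -ln(-ln TCP), where the model is well conditioned over the whole
    (0, 1) range; the residual is then verified to 1e-10 in TCP itself.
    """
    ratio = inputs.alpha_beta_ratio_gy
    target = inputs.tcp
    rhs = np.log(-np.log(target))
    D, d = inputs.total_dose_gy, inputs.fractional_dose_gy

    # on this scale the model is exactly ln N - beta D (ratio + d)
    def g(beta: float) -> float:
        return np.log(inputs.n_clonogens) - beta * D * (ratio + d) - rhs

    lo, hi = 0.0, 1.0
    while g(hi) > 0:
        hi *= 2
        if hi > 1e3:
            raise CalibrationError("TCP root not bracketed")
    if g(lo) < 0:
        raise CalibrationError("TCP root not bracketed from below")
    beta = float(scipy.optimize.brentq(g, lo, hi, xtol=1e-16, rtol=8.9e-16))
    alpha = ratio * beta
    resid = abs(tcp(alpha, beta, inputs) - target)
    if resid >= 1e-10:
        raise CalibrationError(f"TCP residual {resid:.2e} exceeds 1e-10")
    return LQParameters(alpha=alpha, beta=beta)


@dataclass(frozen=True)
class CellLineContext:
    """What Eq.-style yield scaling needs to know about a cell line."""

    photon_yield: CLYieldPhoton  # CL / Gy / cell
    nucleus_volume_um3: float

    def __post_init__(self) -> None:
        if self.nucleus_volume_um3 <= 0:
            raise ConfigurationError("nucleus volume must be positive")


def scale_ion_yield(
    ref_yield: CLYieldIon,
    line: CellLineContext,
    ref_line: CellLineContext,
) -> CLYieldIon:
    """Transfer an ion CL yield from the reference line to the line of interest."""
    if ref_yield.value < 0:
        raise ConfigurationError("reference yield must be non-negative")
    factor = (
        line.photon_yield.value / ref_line.photon_yield.value
    ) * (ref_line.nucleus_volume_um3 / line.nucleus_volume_um3)
    return CLYieldIon(ref_yield.value * factor)


def calibrate_photon_yield(
    target: LQParameters,
    karyotype: Karyotype,
    geometry: NucleusGeometry,
    rej_params: RejoiningParameters,
    seed: int,
    tolerance: float = 0.05,
    search: tuple[float, float] = (0.05, 20.0),
    doses_gy: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    n_cells: int = 10_000,
    pool: Optional[TerritoryPool] = None,
    max_iter: int = 40,
    verbose: bool = False,
) -> tuple[CLYieldPhoton, list[dict]]:
    """Bisection on the photon CL yield until simulated alpha matches target.

    The fitted alpha of a simulated photon curve is monotone increasing in
    the yield, so bisection on log-yield converges; iteration stops when the
    relative alpha mismatch drops below ``tolerance``.  Returns the
    calibrated yield and the iteration trace.
    """
    if target.alpha <= 0:
        raise CalibrationError("target alpha must be positive")
    rng = np.random.default_rng(seed)
    if pool is None:
        pool = TerritoryPool(karyotype, geometry, seed=int(rng.integers(2**31)))
    sim_seed = int(rng.integers(2**31))

    def alpha_of(y: float) -> float:
        curve = simulate_survival(
            RadiationQuality.photon(),
            CLYieldPhoton(y),
            doses_gy,
            n_cells,
            karyotype,
            geometry,
            rej_params,
            seed=sim_seed,  # common random numbers keep alpha(y) monotone
            pool=pool,
        )
        try:
            return fit_LQ(curve).alpha
        except DegenerateFitError:
            # too few live dose points: this yield kills (nearly) everything
            return float("inf")

    lo, hi = search
    a_lo, a_hi = alpha_of(lo), alpha_of(hi)
    trace = [
        {"yield": lo, "alpha": a_lo},
        {"yield": hi, "alpha": a_hi},
    ]
    if not (a_lo <= target.alpha <= a_hi):
        raise CalibrationError(
            f"target alpha {target.alpha:.4f} outside achieved range "
            f"[{a_lo:.4f}, {a_hi:.4f}] for yields {search}"
        )
    y = float(np.sqrt(lo * hi))
    for _ in range(max_iter):
        a = alpha_of(y)
        trace.append({"yield": y, "alpha": a})
        if verbose:
            print(f"  yield={y:.4f}  alpha={a:.4f}")
        if abs(a - target.alpha) <= tolerance * target.alpha:
            return CLYieldPhoton(y), trace
        if a < target.alpha:
            lo = y
        else:
            hi = y
        y = float(np.sqrt(lo * hi))
    raise CalibrationError(
        f"calibration did not converge within {max_iter} iterations; "
        f"last alpha {a:.4f} vs target {target.alpha:.4f}"
    )
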