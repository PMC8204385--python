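"""Unit conversions and reach kernels shared by every stage of the pipeline.

The central dictionary of the package is the relation between the molecular
reach of a tethered reaction, ``L`` (nm), and the effective local
concentration experienced between two co-anchored sites,

    sigma* = 1 / L**3,

with the number density ``1/L**3`` (molecules per nm^3) expressed in
micromolar via Avogadro's number.  All lengths in the codebase are nm,
times are s and concentrations are uM; conversions happen only here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NM3_PER_UM",
    "SIGMA0_RATIO",
    "REACH_SHP1_CRYSTAL_NM",
    "REACH_SHP1_MAX_STRETCH_NM",
    "TetherSpec",
    "sigma_star_from_reach",
    "reach_from_sigma_star",
    "reach_kernel",
    "wlc_reach",
]

#: Number density (molecules / nm^3) of a 1 uM solution: 1e-6 mol/L *
#: N_A / 1e24 nm^3/L, with the 2019 SI Avogadro constant.
NM3_PER_UM: float = 6.02214076e-7

#: sigma(0) / (1/L^3) for the Gaussian reach kernel: (3/(2*pi))^(3/2).
SIGMA0_RATIO: float = (3.0 / (2.0 * math.pi)) ** 1.5

# Structure-based reference estimates for the reach of the phosphatase
# SHP-1 (N-SH2 binding pocket to catalytic site): the allosterically open
# crystal conformation, and the fully stretched upper bound.  These are
# documented reference constants, not computed by this package.
REACH_SHP1_CRYSTAL_NM: float = 5.3
REACH_SHP1_MAX_STRETCH_NM: float = 20.4

#: Worm-like-chain reach conventions exposed by :func:`wlc_reach`.
WLC_CONVENTIONS = ("wlc_sqrt_lclp", "wlc_sqrt_2lclp")


def sigma_star_from_reach(reach_nm: float) -> float:
    """Local concentration sigma* (uM) for a molecular reach ``L`` (nm).

    sigma* = 1/L^3 in molecules/nm^3, converted to uM.  Strictly
    decreasing in ``L``.
    """
    reach_nm = float(reach_nm)
    if not reach_nm > 0:
        raise ValueError(f"molecular reach must be positive, got {reach_nm}")
    return 1.0 / (reach_nm**3 * NM3_PER_UM)


def reach_from_sigma_star(sigma_um: float) -> float:
    """Molecular reach L = (sigma*)^(-1/3) (nm) for sigma* in uM."""
    sigma_um = float(sigma_um)
    if not sigma_um > 0:
        raise ValueError(f"local concentration must be positive, got {sigma_um}")
    return (sigma_um * NM3_PER_UM) ** (-1.0 / 3.0)


def reach_kernel(r_nm, reach_nm: float):
    """Gaussian local-density kernel sigma(r) in nm^-3.

    sigma(r) = (3 / (2 pi L^2))^(3/2) * exp(-3 r^2 / (2 L^2))

    for anchor separation ``r`` (nm).  Normalised: the integral of
    sigma over all of 3D space is 1; the integral over the plane
    through the anchor is sqrt(3/(2 pi)) / L.
    """
    reach_nm = float(reach_nm)
    if not reach_nm > 0:
        raise ValueError(f"molecular reach must be positive, got {reach_nm}")
    r = np.asarray(r_nm, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be non-negative")
    pref = (3.0 / (2.0 * math.pi * reach_nm**2)) ** 1.5
    out = pref * np.exp(-3.0 * r**2 / (2.0 * reach_nm**2))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TetherSpec:
    """A flexible tether described as a worm-like chain.

    Parameters
    ----------
    n_units:
        Number of chain units (PEG linkers or amino acids).
    unit_length:
        Contour length per unit, nm.  0.4 nm is the standard value for
        both a PEG monomer and an amino acid.
    persistence_length:
        WLC persistence length, nm.  0.4 nm for random amino-acid
        sequences.
    convention:
        ``"wlc_sqrt_lclp"`` gives L = sqrt(lc*lp) (the polymer-physics
        end-to-end prediction used for peptide-reach estimates);
        ``"wlc_sqrt_2lclp"`` gives L = sqrt(2*lc*lp) (the convention
        under which squared reaction reach is linear in tether length
        with slope 4*l_unit*lp, see :mod:`tetherkin.reach`).
    """

    n_units: int
    unit_length: float = 0.4
    persistence_length: float = 0.4
    convention: str = "wlc_sqrt_lclp"

    def __post_init__(self) -> None:
        if self.n_units < 0 or self.n_units != int(self.n_units):
            raise ValueError("n_units must be a non-negative integer")
        if not self.unit_length > 0:
            raise ValueError("unit_length must be positive")
        if not self.persistence_length > 0:
            raise ValueError("persistence_length must be positive")
        if self.convention not in WLC_CONVENTIONS:
            raise ValueError(
                f"convention must be one of {WLC_CONVENTIONS}, got {self.convention!r}"
            )

    @property
    def contour_length(self) -> float:
        """Contour length lc = n_units * unit_length, nm."""
        return self.n_units * self.unit_length


def wlc_reach(tether: TetherSpec) -> float:
    """Worm-like-chain reach prediction (nm) for a tether.

    A degenerate tether (``n_units == 0``) returns 0.0 with a warning.
    """
    if tether.n_units == 0:
        warnings.warn("degenerate tether with n_units=0: reach is 0", stacklevel=2)
        return 0.0
    lclp = tether.contour_length * tether.persistence_length
    if tether.convention == "wlc_sqrt_lclp":
        return math.sqrt(lclp)
    return math.sqrt(2.0 * lclp)
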