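"""Effective concentration and substrate coverage on a cell membrane.

When a receptor-enzyme complex is confined to the (locally flat) plasma
membrane with surface density rho0, a substrate anchored in the same
membrane experiences the enzyme at an effective concentration given by
the planar integral of the Gaussian reach kernel,

    C_eff = Int sigma(r) rho0 dA = sqrt(3/(2 pi)) * rho0 / L_rxn,

where L_rxn is the combined reach (receptor + enzyme + substrate, in
quadrature).  Because receptor positions are random, only substrates
with at least one complex within reach can react at all; for a Poisson
point field the covered fraction is

    P(>=1) = 1 - exp(-pi * rho0 * L_rxn^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import units

__all__ = [
    "MembraneScenario",
    "density_from_copy_number",
    "effective_concentration",
    "coverage_probability",
    "density_for_coverage",
]

_PLANAR_PREFACTOR = math.sqrt(3.0 / (2.0 * math.pi))


@dataclass(frozen=True)
class MembraneScenario:
    """Receptor density and the reach components of the complex.

    ``rho0`` in receptors/nm^2; reaches in nm.  ``cytosolic_conc`` (uM)
    is a reference for comparing the membrane-local enhancement against
    the freely diffusing enzyme pool.
    """

    rho0: float
    L_receptor: float = 6.55
    L_enzyme: float = 13.0
    L_substrate: float = 0.0
    cytosolic_conc: float = 1.0

    def __post_init__(self) -> None:
        if self.rho0 < 0:
            raise ValueError("rho0 must be non-negative")
        for name in ("L_receptor", "L_enzyme", "L_substrate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def L_rxn(self) -> float:
        """Combined reach, nm (root-sum-square of the components)."""
        return math.sqrt(
            self.L_receptor**2 + self.L_enzyme**2 + self.L_substrate**2
        )


def density_from_copy_number(copies: float, cell_radius_nm: float) -> float:
    """Uniform surface density (nm^-2) of ``copies`` receptors on a sphere."""
    if copies < 0:
        raise ValueError("copies must be non-negative")
    if not cell_radius_nm > 0:
        raise ValueError("cell_radius_nm must be positive")
    return copies / (4.0 * math.pi * cell_radius_nm**2)


def effective_concentration(scenario: MembraneScenario) -> float:
    """Membrane effective concentration C_eff in uM.

    C_eff = sqrt(3/(2 pi)) * rho0 / L_rxn (nm^-3), converted to uM.
    """
    l_rxn = scenario.L_rxn
    if not l_rxn > 0:
        raise ValueError("the combined reach must be positive")
    c_nm3 = _PLANAR_PREFACTOR * scenario.rho0 / l_rxn
    return c_nm3 / units.NM3_PER_UM


def coverage_probability(scenario: MembraneScenario) -> float:
    """Fraction of substrates with >= 1 complex within reach.

    1 - exp(-pi * rho0 * L_rxn^2); in [0, 1], increasing in both rho0
    and L_rxn.
    """
    lam = math.pi * scenario.rho0 * scenario.L_rxn**2
    return 1.0 - math.exp(-lam)


def density_for_coverage(target: float, l_rxn: float) -> float:
    """Receptor density (nm^-2) achieving a target covered fraction.

    Exact inverse of :func:`coverage_probability`:
    rho0 = -ln(1 - target) / (pi * L_rxn^2).
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target coverage must be strictly between 0 and 1")
    if not l_rxn > 0:
        raise ValueError("l_rxn must be positive")
    return -math.log1p(-target) / (math.pi * l_rxn**2)
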