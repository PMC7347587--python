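"""Physical constants and genome geometry for UV-C inactivation kinetics.

All quantities are in CGS units (erg, cm, s); energies per mole of photons
carry Avogadro's number explicitly.  The default values are the canonical
parameter set for *E. coli* exposed to a 253.7 nm low-pressure mercury lamp
and are deliberately kept at their printed 4-5 significant figures rather
than updated to CODATA values, so that every derived quantity in this
package reproduces the reference numbers exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

__all__ = [
    "PhysicalConstants",
    "GenomeSpec",
    "default_constants",
    "default_ecoli_genome",
    "activation_energy",
    "photon_energy",
    "UVC_BAND_CM",
]

# UV-C wavelength band (200-280 nm) in cm; outside it we warn, not fail.
UVC_BAND_CM = (2.0e-5, 2.8e-5)


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants plus the lamp wavelength, CGS units.

    Attributes
    ----------
    avogadro_n0 : float
        Avogadro's constant, mol^-1.
    planck_h : float
        Planck's constant, erg*s.
    light_speed_c : float
        Speed of light, cm/s.
    wavelength_lambda : float
        Wavelength of the UV-C source, cm.
    """

    avogadro_n0: float = 6.0225e23
    planck_h: float = 6.6256e-27
    light_speed_c: float = 2.9979e10
    wavelength_lambda: float = 2.537e-5

    def __post_init__(self) -> None:
        for name in ("avogadro_n0", "planck_h", "light_speed_c", "wavelength_lambda"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        lo, hi = UVC_BAND_CM
        if not lo <= self.wavelength_lambda <= hi:
            warnings.warn(
                f"wavelength {self.wavelength_lambda:g} cm lies outside the "
                f"UV-C band [{lo:g}, {hi:g}] cm",
                stacklevel=2,
            )

    def with_wavelength(self, wavelength_cm: float) -> "PhysicalConstants":
        """Return a copy with a different source wavelength (cm)."""
        return replace(self, wavelength_lambda=wavelength_cm)


@dataclass(frozen=True)
class GenomeSpec:
    """Geometry of the genomic target matrix.

    The genome is modelled as a slab of volume ``VG`` and thickness ``dx``
    containing ``2*Nj`` nitrogenous bases (both strands), each presenting an
    effective impact cross-section ``sigma`` to incoming photons.

    Derived quantities:

    * ``n_star`` -- base number density, 2*Nj/VG (bases/cm^3)
    * ``genome_area_ag`` -- slab area VG/dx (cm^2), so area*thickness = volume
    * ``ems_z`` -- effective macroscopic section Z = n_star*sigma (cm^-1),
      the inverse of the photon mean free path
    """

    base_pairs_nj: float = 5.2e6
    genome_volume_vg: float = 4.3716e-13
    genome_thickness_dx: float = 5.5111e-5
    impact_section_sigma: float = 4.9627e-16
    label: str = "E. coli (mean)"

    def __post_init__(self) -> None:
        for name in (
            "base_pairs_nj",
            "genome_volume_vg",
            "genome_thickness_dx",
            "impact_section_sigma",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def n_star(self) -> float:
        """Bases per unit genome volume, counting both strands (cm^-3)."""
        return 2.0 * self.base_pairs_nj / self.genome_volume_vg

    @property
    def genome_area_ag(self) -> float:
        """Genome slab area A_G = VG/dx (cm^2)."""
        return self.genome_volume_vg / self.genome_thickness_dx

    @property
    def ems_z(self) -> float:
        """Effective macroscopic section Z = N*·sigma (cm^-1)."""
        return self.n_star * self.impact_section_sigma


def default_constants() -> PhysicalConstants:
    """Canonical physical constants (CGS) for the 253.7 nm mercury line."""
    return PhysicalConstants()


def default_ecoli_genome() -> GenomeSpec:
    """Mean *E. coli* genome: 5.2 Mbp in a 4.3716e-13 cm^3 slab."""
    return GenomeSpec()


def activation_energy(constants: PhysicalConstants) -> float:
    """Energy of one einstein (mole of photons), Ea = n0*h*c/lambda (erg/mol)."""
    return (
        constants.avogadro_n0
        * constants.planck_h
        * constants.light_speed_c
        / constants.wavelength_lambda
    )


def photon_energy(constants: PhysicalConstants) -> float:
    """Energy of a single photon, h*c/lambda (erg)."""
    return constants.planck_h * constants.light_speed_c / constants.wavelength_lambda
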