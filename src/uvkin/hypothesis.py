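"""Proportionality-hypothesis accounting: photons per pyrimidine dimer.

The hypothesis states that the lethal impact number f(tu) is proportional
to the genome's base-pair count Nj, with coefficient

    Nj / f(tu) = Phi_mu * n0 * h * VG / (2 * sigma * lambda),

i.e. the ratio of the measured quantum mortality yield to its theoretical
mean 2σλ/(VG·n0·h).  A coefficient near one confirms the hypothesis.  The
reciprocal of the yield, Dp = 1/Phi_mu, counts the photons needed to form a
single pyrimidine dimer; Dp >> 1 signals multi-impact kinetics.  Dp is
carried in the yield's own numeric convention (the reciprocal of a
mol/(erg·s) value read as a pure number), which is how the published
photon-per-dimer counts are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .constants_genome import GenomeSpec, PhysicalConstants
from .quantum_kinetics import theoretical_cqmy

__all__ = [
    "ProportionalityResult",
    "proportionality_coefficient",
    "photons_per_dimer",
    "cqmy_from_budget",
    "genome_photon_constant",
    "proportionality_table",
]


@dataclass(frozen=True)
class ProportionalityResult:
    """One row of the proportionality-hypothesis bookkeeping."""

    label: str
    wavelength_used: float  # cm
    coefficient_nj_over_ftu: float
    cqmy_phi_mu: float  # mol/(erg*s)
    photons_per_dimer_dp: float
    multi_impact: bool  # Dp > 1


def genome_photon_constant(
    genome: GenomeSpec, constants: PhysicalConstants
) -> float:
    """The genome/wavelength constant n0·h·VG/(2σλ) = 1/Φ̄μ.

    Every (coefficient, Dp) pair satisfies coefficient × Dp = this constant;
    it is the photons-per-dimer count of a genome whose yield exactly matches
    the theoretical mean.
    """
    return 1.0 / theoretical_cqmy(genome, constants)


def proportionality_coefficient(
    phi_mu: float, genome: GenomeSpec, constants: PhysicalConstants
) -> float:
    """Nj/f(tu) coefficient: Φμ·n0·h·VG/(2σλ) = Φμ/Φ̄μ."""
    if phi_mu <= 0:
        raise ValueError("phi_mu must be strictly positive")
    return phi_mu * genome_photon_constant(genome, constants)


def photons_per_dimer(phi_mu: float) -> float:
    """Photons required per pyrimidine dimer, Dp = 1/Φμ."""
    if phi_mu <= 0:
        raise ValueError("phi_mu must be strictly positive")
    return 1.0 / phi_mu


def cqmy_from_budget(dimers_dhat_p: float, photons_gamma_abs: float) -> float:
    """Quantum mortality yield from a photon budget: Φμ = D̂p/γ_abs.

    ``dimers_dhat_p`` is the number of dimers formed and ``photons_gamma_abs``
    the number of photons absorbed per cell; neither is directly measured in
    a plating experiment, so both are caller-supplied.
    """
    if photons_gamma_abs <= 0:
        raise ValueError("photons_gamma_abs must be strictly positive")
    if dimers_dhat_p <= 0:
        raise ValueError("dimers_dhat_p must be strictly positive")
    return dimers_dhat_p / photons_gamma_abs


def proportionality_table(
    entries: Iterable[Mapping],
    genome: Optional[GenomeSpec] = None,
    constants: Optional[PhysicalConstants] = None,
) -> list[ProportionalityResult]:
    """Complete proportionality rows from a coefficient or a Dp each.

    Each entry supplies ``label`` and exactly one of ``coefficient`` or
    ``dp``; the other, together with Φμ, is filled in from the
    genome/wavelength constant.  All rows use the 253.7 nm constant even
    when the source experiment quotes a nearby wavelength: the published
    photon-per-dimer counts are reproduced only by the single-wavelength
    constant, so the quoted wavelength is treated as annotation.
    """
    genome = genome or GenomeSpec()
    constants = constants or PhysicalConstants()
    const = genome_photon_constant(genome, constants)
    out: list[ProportionalityResult] = []
    for entry in entries:
        has_coef = entry.get("coefficient") is not None
        has_dp = entry.get("dp") is not None
        if has_coef == has_dp:
            raise ValueError(
                f"entry {entry.get('label', '?')!r} must supply exactly one of "
                "'coefficient' or 'dp'"
            )
        if has_coef:
            coefficient = float(entry["coefficient"])
            dp = const / coefficient
        else:
            dp = float(entry["dp"])
            coefficient = const / dp
        out.append(
            ProportionalityResult(
                label=str(entry.get("label", "")),
                wavelength_used=constants.wavelength_lambda,
                coefficient_nj_over_ftu=coefficient,
                cqmy_phi_mu=1.0 / dp,
                photons_per_dimer_dp=dp,
                multi_impact=dp > 1.0,
            )
        )
    return out
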