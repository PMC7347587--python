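"""Corpuscular (photon-collision) model of UV-C genome damage.

A photon traversing the genome slab sees ``N* = 2Nj/VG`` bases per cm^3,
each presenting an effective impact section ``sigma``.  The collision
statistics follow from kinetic theory:

    Z    = N*·sigma          effective macroscopic section (cm^-1)
    l̄    = 1/Z               mean free path between impacts (cm)
    Δti  = l̄/c = 1/(N*σc)    molecular excitation time (s)
    f    = N*σc              impact frequency (1/s)
    δ    = N*·σ·Δx = Z·Δx    expected impacts per slab traversal

The lethal impact number ``f(tu)`` — impacts accumulated over the minimum
mortality time — couples these collision statistics to the population-level
specific speed of mortality, k = N*σc / f(tu).  Under the proportionality
hypothesis f(tu) ≈ Nj this yields parameter-free theoretical predictions
k̄ = 2σc/VG, t̄u = 1/k̄ and the mean quantum mortality yield
Φ̄μ = 2σλ/(VG·n0·h).

Note δ is the *expected impact count* per traversal (linear in Δx), not a
Beer–Lambert absorption probability 1 - exp(-Z·Δx); the latter is exposed
separately as :func:`absorbed_probability_beer_lambert` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants_genome import GenomeSpec, PhysicalConstants
from .physical_model import KineticParams, mortality, survival

__all__ = [
    "ImpactGeometry",
    "LethalImpactBudget",
    "impact_geometry",
    "mean_free_path",
    "excitation_time",
    "impact_frequency",
    "absorbed_fraction",
    "absorbed_probability_beer_lambert",
    "lethal_impact_number",
    "ssm_from_lin",
    "mortality_from_impacts",
    "survival_from_impacts",
    "theoretical_ssm",
    "theoretical_mmt",
    "theoretical_cqmy",
    "monte_carlo_impact_oracle",
    "MonteCarloImpactResult",
]


@dataclass(frozen=True)
class ImpactGeometry:
    """Collision statistics of a photon in the genome slab."""

    mean_free_path_l: float  # cm
    excitation_time_dti: float  # s
    impact_frequency_f: float  # 1/s
    absorbed_fraction_delta: float  # expected impacts per traversal
    ems_z: float  # cm^-1


@dataclass(frozen=True)
class LethalImpactBudget:
    """Lethal impact number and its coupled mortality-rate quantities.

    Satisfies k·tu = 1 and tu = f(tu)/(N*σc) by construction.
    """

    lin_f_tu: float  # impacts, dimensionless
    ssm_k: float  # 1/s
    mmt_tu: float  # s


def mean_free_path(genome: GenomeSpec) -> float:
    """Mean photon path between impacts, l̄ = 1/(N*·sigma) (cm)."""
    return 1.0 / genome.ems_z


def excitation_time(genome: GenomeSpec, constants: PhysicalConstants) -> float:
    """Mean time between absorption events, Δti = l̄/c = 1/(N*σc) (s)."""
    return mean_free_path(genome) / constants.light_speed_c


def impact_frequency(genome: GenomeSpec, constants: PhysicalConstants) -> float:
    """Impacts per unit time, f = N*σc = 1/Δti (1/s)."""
    return genome.n_star * genome.impact_section_sigma * constants.light_speed_c


def absorbed_fraction(genome: GenomeSpec) -> float:
    """Expected impacts per traversal of the genome slab, δ = N*·σ·Δx."""
    return genome.n_star * genome.impact_section_sigma * genome.genome_thickness_dx


def absorbed_probability_beer_lambert(genome: GenomeSpec) -> float:
    """Beer–Lambert absorption probability 1 - exp(-Z·Δx), for comparison.

    The model quantity is the linear expected-impact count
    :func:`absorbed_fraction`; this exponential variant saturates at 1 and
    is provided only as an alternative bookkeeping of the same geometry.
    """
    return -np.expm1(-genome.ems_z * genome.genome_thickness_dx)


def impact_geometry(genome: GenomeSpec, constants: PhysicalConstants) -> ImpactGeometry:
    """Bundle all collision statistics for a genome/constants pair."""
    return ImpactGeometry(
        mean_free_path_l=mean_free_path(genome),
        excitation_time_dti=excitation_time(genome, constants),
        impact_frequency_f=impact_frequency(genome, constants),
        absorbed_fraction_delta=absorbed_fraction(genome),
        ems_z=genome.ems_z,
    )


def lethal_impact_number(
    k: float, genome: GenomeSpec, constants: PhysicalConstants
) -> LethalImpactBudget:
    """Impacts accumulated over the minimum mortality time: f(tu) = N*σc/k."""
    if k <= 0:
        raise ValueError("k must be strictly positive")
    f = impact_frequency(genome, constants)
    return LethalImpactBudget(lin_f_tu=f / k, ssm_k=k, mmt_tu=1.0 / k)


def ssm_from_lin(f_tu: float, genome: GenomeSpec, constants: PhysicalConstants) -> float:
    """Specific speed of mortality from the lethal impact number, k = N*σc/f(tu)."""
    if f_tu <= 0:
        raise ValueError("f_tu must be strictly positive")
    return impact_frequency(genome, constants) / f_tu


def _params_from_lin(
    f_tu: float, n0: float, genome: GenomeSpec, constants: PhysicalConstants
) -> KineticParams:
    k = ssm_from_lin(f_tu, genome, constants)
    return KineticParams.from_k(k, n0=n0, constants=constants)


def mortality_from_impacts(
    t, f_tu: float, genome: GenomeSpec, constants: PhysicalConstants
):
    """Dead-cell count N(t) = [N*σc/f(tu)]·ln(t); equals the physical-model
    mortality with k = N*σc/f(tu)."""
    return mortality(t, _params_from_lin(f_tu, 0.0, genome, constants))


def survival_from_impacts(
    t, f_tu: float, n0: float, genome: GenomeSpec, constants: PhysicalConstants
):
    """Surviving count N1(t) = N0 - [N*σc/f(tu)]·ln(t)."""
    return survival(t, _params_from_lin(f_tu, n0, genome, constants))


def theoretical_ssm(genome: GenomeSpec, constants: PhysicalConstants) -> float:
    """Mean specific speed of mortality k̄ ≈ 2σc/VG (1/s).

    Follows from k = N*σc/f(tu) under the proportionality hypothesis
    f(tu) ≈ Nj, since N*/Nj = 2/VG.
    """
    return (
        2.0
        * genome.impact_section_sigma
        * constants.light_speed_c
        / genome.genome_volume_vg
    )


def theoretical_mmt(genome: GenomeSpec, constants: PhysicalConstants) -> float:
    """Mean minimum mortality time t̄u = 1/k̄ (s)."""
    return 1.0 / theoretical_ssm(genome, constants)


def theoretical_cqmy(genome: GenomeSpec, constants: PhysicalConstants) -> float:
    """Mean cell quantum mortality yield Φ̄μ ≈ 2σλ/(VG·n0·h) (mol/(erg·s))."""
    return (
        2.0
        * genome.impact_section_sigma
        * constants.wavelength_lambda
        / (genome.genome_volume_vg * constants.avogadro_n0 * constants.planck_h)
    )


@dataclass(frozen=True)
class MonteCarloImpactResult:
    """Sampled free-path/impact statistics with standard errors."""

    n_photons: int
    mean_free_path_est: float
    mean_free_path_se: float
    excitation_time_est: float
    excitation_time_se: float
    mean_impacts_est: float
    mean_impacts_se: float
    impact_counts: np.ndarray


def monte_carlo_impact_oracle(
    genome: GenomeSpec,
    constants: PhysicalConstants,
    n_photons: int,
    seed: int,
    rng: Optional[np.random.Generator] = None,
) -> MonteCarloImpactResult:
    """Stochastic check of the analytic collision statistics.

    Photons travel through a homogeneous slab of independent targets:
    free paths are exponential with rate Z = N*σ, and the number of impacts
    over a traversal of thickness Δx is Poisson with mean Z·Δx = δ.  The
    sample means converge to l̄, Δti and δ at the 1/sqrt(n) rate; this is a
    statistical oracle for the analytic formulas, not a photon-transport
    engine (elastic scattering and target depletion are not modelled).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    z = genome.ems_z
    paths = rng.exponential(scale=1.0 / z, size=n_photons)
    impacts = rng.poisson(lam=z * genome.genome_thickness_dx, size=n_photons)
    c = constants.light_speed_c
    path_se = paths.std(ddof=1) / np.sqrt(n_photons)
    imp_se = impacts.std(ddof=1) / np.sqrt(n_photons)
    return MonteCarloImpactResult(
        n_photons=n_photons,
        mean_free_path_est=float(paths.mean()),
        mean_free_path_se=float(path_se),
        excitation_time_est=float(paths.mean() / c),
        excitation_time_se=float(path_se / c),
        mean_impacts_est=float(impacts.mean()),
        mean_impacts_se=float(imp_se),
        impact_counts=impacts,
    )
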