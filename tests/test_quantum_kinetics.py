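"""Photon-collision geometry, lethal impact numbers and theory predictions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_genome
from uvkin.constants_genome import GenomeSpec, activation_energy, default_constants
from uvkin.physical_model import KineticParams, predict_curve
from uvkin.quantum_kinetics import (
    absorbed_fraction,
    absorbed_probability_beer_lambert,
    excitation_time,
    impact_frequency,
    impact_geometry,
    lethal_impact_number,
    mean_free_path,
    monte_carlo_impact_oracle,
    mortality_from_impacts,
    ssm_from_lin,
    survival_from_impacts,
    theoretical_cqmy,
    theoretical_mmt,
    theoretical_ssm,
)

REL = 1e-3  # printed 4-5 significant figures


class TestPrintedPredictions:
    """The closed-form theory values for the default E. coli genome."""

    def test_mean_free_path(self, genome):
        assert mean_free_path(genome) == pytest.approx(1 / 1.1806e4, rel=REL)

    def test_excitation_time(self, genome, constants):
        assert excitation_time(genome, constants) == pytest.approx(
            2.8252e-15, rel=REL
        )

    def test_impact_frequency(self, genome, constants):
        assert impact_frequency(genome, constants) == pytest.approx(
            1 / 2.8252e-15, rel=REL
        )

    def test_absorbed_fraction_and_ems(self, genome):
        assert absorbed_fraction(genome) == pytest.approx(0.6506, rel=REL)
        assert genome.ems_z == pytest.approx(1.1806e4, rel=REL)

    def test_theoretical_rate_constants(self, genome, constants):
        assert theoretical_ssm(genome, constants) == pytest.approx(6.8065e7, rel=REL)
        assert theoretical_mmt(genome, constants) == pytest.approx(1.4691e-8, rel=REL)
        assert theoretical_cqmy(genome, constants) == pytest.approx(
            1.4435e-5, rel=REL
        )

    def test_mmt_in_excited_state_lifetime_band(self, genome, constants):
        assert 1e-9 < theoretical_mmt(genome, constants) < 1e-7

    def test_cqmy_in_published_order_band(self, genome, constants):
        assert 1e-6 < theoretical_cqmy(genome, constants) < 1e-4


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_reciprocal_identities_random_genomes(seed):
    """l̄·Z = 1, f·Δti = 1, k·tu = 1 and the unitary identity, to 1e-12."""
    rng = np.random.default_rng(seed)
    g = random_genome(rng)
    c = default_constants()
    geom = impact_geometry(g, c)
    assert geom.mean_free_path_l * geom.ems_z == pytest.approx(1.0, rel=1e-12)
    assert geom.impact_frequency_f * geom.excitation_time_dti == pytest.approx(
        1.0, rel=1e-12
    )
    k = rng.uniform(1e3, 1e9)
    budget = lethal_impact_number(k, g, c)
    assert budget.ssm_k * budget.mmt_tu == pytest.approx(1.0, rel=1e-12)
    # tu = f(tu) * Delta-ti
    assert budget.mmt_tu == pytest.approx(
        budget.lin_f_tu * geom.excitation_time_dti, rel=1e-12
    )
    # unitary mortality identity: N*sigma*c / (f(tu)*k) = 1
    n_sigma_c = g.n_star * g.impact_section_sigma * c.light_speed_c
    assert n_sigma_c / (budget.lin_f_tu * k) == pytest.approx(1.0, rel=1e-12)
    # round trip through the inverse
    assert ssm_from_lin(budget.lin_f_tu, g, c) == pytest.approx(k, rel=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_absorbed_fraction_three_forms_agree(seed):
    """δ = N*σΔx = 2Njσ/A_G = Δx/l̄, all to 1e-12."""
    g = random_genome(np.random.default_rng(seed))
    delta = absorbed_fraction(g)
    form_area = 2 * g.base_pairs_nj * g.impact_section_sigma / g.genome_area_ag
    form_path = g.genome_thickness_dx / mean_free_path(g)
    assert delta == pytest.approx(form_area, rel=1e-12)
    assert delta == pytest.approx(form_path, rel=1e-12)


def test_beer_lambert_variant_is_smaller_and_saturates(genome):
    delta = absorbed_fraction(genome)
    p_abs = absorbed_probability_beer_lambert(genome)
    assert 0 < p_abs < min(delta, 1.0)
    thick = GenomeSpec(genome_thickness_dx=1.0)  # many mean free paths
    assert absorbed_probability_beer_lambert(thick) == pytest.approx(1.0, abs=1e-9)


def test_sigma_scaling_of_free_path(genome):
    doubled = GenomeSpec(impact_section_sigma=2 * genome.impact_section_sigma)
    assert mean_free_path(doubled) == pytest.approx(
        mean_free_path(genome) / 2, rel=1e-12
    )


def test_lethal_impact_number_near_genome_size(genome, constants):
    """At the theoretical rate, f(tu) ≈ Nj — the proportionality hypothesis."""
    budget = lethal_impact_number(6.8065e7, genome, constants)
    assert budget.lin_f_tu == pytest.approx(genome.base_pairs_nj, rel=1e-3)


def test_lin_equal_nj_recovers_mean_rate(genome, constants):
    k = ssm_from_lin(genome.base_pairs_nj, genome, constants)
    two_sigma_c_over_vg = (
        2 * genome.impact_section_sigma * constants.light_speed_c
        / genome.genome_volume_vg
    )
    assert k == pytest.approx(two_sigma_c_over_vg, rel=1e-4)


def test_impact_curves_match_physical_model(genome, constants):
    """Collision-model curves coincide with the log-time law under k = N*σc/f(tu)."""
    rng = np.random.default_rng(0)
    t = np.linspace(1.0, 300.0, 37)
    for f_tu in rng.uniform(1e5, 1e8, size=5):
        k = ssm_from_lin(f_tu, genome, constants)
        params = KineticParams.from_k(k, n0=3e8, constants=constants)
        curve = predict_curve(t, params, clamp=False)
        np.testing.assert_allclose(
            mortality_from_impacts(t, f_tu, genome, constants),
            curve.dead_n,
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            survival_from_impacts(t, f_tu, 3e8, genome, constants),
            curve.surviving_n1,
            rtol=1e-12,
        )


def test_cross_model_rate_consistency(genome, constants):
    """Φ̄μ·Ea reproduces k̄ = 2σc/VG to 0.01 %."""
    assert theoretical_cqmy(genome, constants) * activation_energy(
        constants
    ) == pytest.approx(theoretical_ssm(genome, constants), rel=1e-4)


class TestMonteCarloOracle:
    def test_estimates_within_three_se(self, genome, constants):
        res = monte_carlo_impact_oracle(genome, constants, n_photons=100_000, seed=7)
        assert abs(res.mean_impacts_est - absorbed_fraction(genome)) <= (
            3 * res.mean_impacts_se
        )
        assert abs(res.mean_free_path_est - mean_free_path(genome)) <= (
            3 * res.mean_free_path_se
        )
        assert abs(
            res.excitation_time_est - excitation_time(genome, constants)
        ) <= 3 * res.excitation_time_se

    def test_convergence_rate(self, genome, constants):
        """Standard error shrinks roughly as 1/sqrt(n)."""
        small = monte_carlo_impact_oracle(genome, constants, 2_000, seed=3)
        large = monte_carlo_impact_oracle(genome, constants, 128_000, seed=3)
        ratio = small.mean_free_path_se / large.mean_free_path_se
        assert ratio == pytest.approx(8.0, rel=0.25)

    def test_seed_determinism(self, genome, constants):
        a = monte_carlo_impact_oracle(genome, constants, 10_000, seed=11)
        b = monte_carlo_impact_oracle(genome, constants, 10_000, seed=11)
        assert a.mean_free_path_est == b.mean_free_path_est
        assert np.array_equal(a.impact_counts, b.impact_counts)

    def test_rejects_empty_sample(self, genome, constants):
        with pytest.raises(ValueError):
            monte_carlo_impact_oracle(genome, constants, 0, seed=1)
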