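"""Synthetic CFU-survival datasets emulating the plating experiment.

The generator reproduces the structure of the bench protocol: a stationary
-phase culture of roughly 1e8 cells/ml, 3 ml per dish (N0 ≈ 3e8 cells),
exposures in 30 s steps up to 300 s, five-step decimal serial dilution of
each sample, plate counts in the standard countable range, and triplicate
experiments.  Expected survivors follow the log-time law
N1(t) = N0 - k*ln(t), clamped at zero; plate counts are Poisson draws at
the dilution whose expected colony count falls in 30-300 when possible,
optionally with lognormal multiplicative overdispersion; CFU/ml is then
back-calculated from the recorded dilution, exactly as a colony counter
log sheet would.  Fluence (2.75 mJ/(s*cm^2) times exposure) is attached as
reporting metadata only — the kinetics are parameterised by time.

Deterministic mode (``noise_model="none"``) emits the exact model values,
making the generator the algebraic inverse of
:func:`uvkin.estimation.counts_to_survivors` followed by the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants_genome import PhysicalConstants, default_constants
from .estimation import SurvivalDataset, fit_survival

__all__ = [
    "SimulationDesign",
    "simulate_dataset",
    "recovery_study",
    "DEFAULT_TIMES_S",
    "FLUENCE_MJ_PER_S_CM2",
    "COUNTABLE_RANGE",
]

DEFAULT_TIMES_S: tuple[float, ...] = tuple(float(t) for t in range(30, 301, 30))
FLUENCE_MJ_PER_S_CM2 = 2.75
COUNTABLE_RANGE = (30.0, 300.0)


@dataclass(frozen=True)
class SimulationDesign:
    """Design of one simulated exposure experiment.

    ``true_k`` is the specific speed of mortality in counts per ln-second,
    ``true_n0`` the initial population per dish (~1e8 cells/ml x 3 ml).
    ``noise_model`` is one of "none", "poisson", "poisson_lognormal"; the
    last multiplies the expected plate count by exp(N(0, sigma^2)) before
    the Poisson draw to emulate between-plate variance.
    """

    true_k: float = 5.0e7
    true_n0: float = 3.0e8
    times: Sequence[float] = DEFAULT_TIMES_S
    replicates: int = 3
    dilution_steps: int = 5
    plated_volume_ml: float = 3.0
    noise_model: str = "poisson"
    overdispersion_sigma: float = 0.0
    seed: Optional[int] = None
    strain: str = "synthetic"

    def __post_init__(self) -> None:
        if self.true_k <= 0 or self.true_n0 <= 0:
            raise ValueError("true_k and true_n0 must be strictly positive")
        if any(t <= 0 for t in self.times):
            raise ValueError("exposure times must be strictly positive")
        if self.replicates < 1 or self.dilution_steps < 1:
            raise ValueError("replicates and dilution_steps must be >= 1")
        if self.noise_model not in ("none", "poisson", "poisson_lognormal"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_model != "none" and self.seed is None:
            raise ValueError("a seed is mandatory for stochastic noise models")

    def expected_survivors(self, t: np.ndarray) -> np.ndarray:
        """Model expectation N1(t) = N0 - k*ln(t), clamped at zero."""
        return np.clip(self.true_n0 - self.true_k * np.log(t), 0.0, None)


def _pick_dilution(expected_count: float, dilution_steps: int) -> float:
    """Choose the decimal dilution whose expected plate count is countable.

    Returns the dilution factor (1, 10, ..., 10**dilution_steps).  Prefers
    the 30-300 colony window; falls back to the dilution giving the count
    closest to the window.
    """
    factors = 10.0 ** np.arange(dilution_steps + 1)
    counts = expected_count / factors
    lo, hi = COUNTABLE_RANGE
    in_window = (counts >= lo) & (counts <= hi)
    if in_window.any():
        return float(factors[np.argmax(in_window)])
    # distance to the window in log10 space; 0-count plates fall to factor 1
    with np.errstate(divide="ignore"):
        log_c = np.log10(np.where(counts > 0, counts, np.nan))
    dist = np.where(
        np.isnan(log_c),
        np.inf,
        np.maximum(np.log10(lo) - log_c, 0) + np.maximum(log_c - np.log10(hi), 0),
    )
    return float(factors[int(np.nanargmin(dist))])


def simulate_dataset(design: SimulationDesign) -> SurvivalDataset:
    """Simulate a plated survival experiment under the log-time law."""
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.times, dtype=float)
    expected = design.expected_survivors(times)
    if np.all(expected == 0):
        warnings.warn(
            "expected survivors are zero at every exposure time "
            "(beyond absolute death)",
            stacklevel=2,
        )

    rows: list[dict] = []

    def sample_record(time_s: float, replicate: int, expected_n: float) -> dict:
        # concentration in the undiluted sample, CFU/ml
        conc = expected_n / design.plated_volume_ml
        dilution = _pick_dilution(conc, design.dilution_steps)
        lam = conc / dilution
        if design.noise_model == "none":
            plate = lam
        else:
            if design.noise_model == "poisson_lognormal" and design.overdispersion_sigma > 0:
                lam = lam * rng.lognormal(mean=0.0, sigma=design.overdispersion_sigma)
            plate = rng.poisson(lam)
        return {
            "strain": design.strain,
            "time_s": time_s,
            "replicate": replicate,
            "dilution_factor": dilution,
            # colonies per ml of the counted dilution; multiply by
            # dilution_factor and plated volume to recover the population
            "cfu_per_ml": float(plate),
            "fluence_mj_cm2": FLUENCE_MJ_PER_S_CM2 * time_s,
        }

    for rep in range(1, design.replicates + 1):
        rows.append(sample_record(0.0, rep, design.true_n0))
        for t, n1 in zip(times, expected):
            rows.append(sample_record(float(t), rep, float(n1)))

    records = pd.DataFrame(rows)
    return SurvivalDataset(
        strain=design.strain,
        records=records,
        plated_volume_ml=design.plated_volume_ml,
    )


def recovery_study(
    designs: Sequence[SimulationDesign],
    n_sims: int,
    seed: int,
    confidence: float = 0.97,
    constants: Optional[PhysicalConstants] = None,
) -> pd.DataFrame:
    """Simulate-and-refit study of estimator bias, RMSE and CI coverage.

    For each design, runs ``n_sims`` independent simulate→fit cycles
    (child seeds spawned deterministically from ``seed``) and summarises
    the fitted k̂, N̂0, Φ̂μ and half-population time against the truth.
    Coverage is the fraction of slope confidence intervals (at
    ``confidence``) containing the true k, reported with its Monte Carlo
    standard error.
    """
    if n_sims < 50:
        raise ValueError("n_sims must be >= 50 for stable summaries")
    constants = constants or default_constants()
    seed_seq = np.random.SeedSequence(seed)
    out_rows = []
    for design, child in zip(designs, seed_seq.spawn(len(designs))):
        sim_seeds = child.generate_state(n_sims) % (2**31 - 1)
        k_hats = np.empty(n_sims)
        n0_hats = np.empty(n_sims)
        phi_hats = np.empty(n_sims)
        covered = np.empty(n_sims, dtype=bool)
        for i, s in enumerate(sim_seeds):
            d = SimulationDesign(
                true_k=design.true_k,
                true_n0=design.true_n0,
                times=design.times,
                replicates=design.replicates,
                dilution_steps=design.dilution_steps,
                plated_volume_ml=design.plated_volume_ml,
                noise_model=design.noise_model,
                overdispersion_sigma=design.overdispersion_sigma,
                seed=int(s) if design.noise_model != "none" else None,
                strain=design.strain,
            )
            fit = fit_survival(
                simulate_dataset(d), confidence=confidence, constants=constants
            )
            k_hats[i] = fit.ssm_k_hat
            n0_hats[i] = fit.intercept_n0_hat
            phi_hats[i] = fit.cqmy_phi_mu_hat
            covered[i] = fit.k_ci[0] <= design.true_k <= fit.k_ci[1]
        rel_err = np.abs(k_hats - design.true_k) / design.true_k
        coverage = covered.mean()
        out_rows.append(
            {
                "true_k": design.true_k,
                "true_n0": design.true_n0,
                "replicates": design.replicates,
                "noise_model": design.noise_model,
                "n_sims": n_sims,
                "k_hat_median_rel_err": float(np.median(rel_err)),
                "k_hat_bias": float(k_hats.mean() - design.true_k),
                "k_hat_rmse": float(
                    np.sqrt(np.mean((k_hats - design.true_k) ** 2))
                ),
                "n0_hat_bias": float(n0_hats.mean() - design.true_n0),
                "n0_hat_rmse": float(
                    np.sqrt(np.mean((n0_hats - design.true_n0) ** 2))
                ),
                "phi_mu_hat_mean": float(phi_hats.mean()),
                "ci_coverage": float(coverage),
                "ci_coverage_mc_se": float(
                    np.sqrt(coverage * (1 - coverage) / n_sims)
                ),
            }
        )
    return pd.DataFrame(out_rows)
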