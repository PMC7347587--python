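"""Least-squares estimation of mortality kinetics from CFU survival data.

Survivor counts are regressed on the natural log of exposure time,

    N1 = N0 - k * ln(t),

so the slope magnitude estimates the specific speed of mortality k, the
intercept estimates the initial population N0, and the quantum mortality
yield follows as Phi_mu = k * lambda / (n0*h*c).  Alongside the point
estimates the fit reports the correlation and determination coefficients,
a mean-response confidence band and an individual-observation (fiducial)
prediction band at the requested confidence level (default 0.97), and the
slope confidence interval used for coverage studies.  Strain-level
estimates can be compared against a theoretical reference rate with a
one-sample t test (default significance 0.03).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .constants_genome import PhysicalConstants, default_constants
from .physical_model import cqmy_from_ssm

__all__ = [
    "SurvivalDataset",
    "FitResult",
    "TTestReport",
    "counts_to_survivors",
    "fit_survival",
    "mortality_view",
    "MortalityView",
    "t_test_vs_theory",
]

REQUIRED_COLUMNS = ("time_s", "replicate", "dilution_factor", "cfu_per_ml")


@dataclass
class SurvivalDataset:
    """CFU counts of one strain across exposure times.

    ``records`` has columns time_s, replicate, dilution_factor, cfu_per_ml;
    rows with time_s == 0 are the unexposed controls that define N0 (or the
    100 % viability level in normalized mode).  ``plated_volume_ml`` scales
    CFU/ml concentrations to population counts.
    """

    strain: str
    records: pd.DataFrame
    plated_volume_ml: float = 3.0

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing required columns: {missing}")
        if (self.records["cfu_per_ml"] < 0).any():
            raise ValueError("cfu_per_ml counts must be non-negative")
        if (self.records["dilution_factor"] <= 0).any():
            raise ValueError("dilution_factor must be strictly positive")
        if (self.records["time_s"] < 0).any():
            raise ValueError("time_s must be non-negative")
        if self.plated_volume_ml <= 0:
            raise ValueError("plated_volume_ml must be strictly positive")

    @property
    def controls(self) -> pd.DataFrame:
        return self.records[self.records["time_s"] == 0]

    @property
    def exposed(self) -> pd.DataFrame:
        return self.records[self.records["time_s"] > 0]

    def n_distinct_times(self) -> int:
        return self.exposed["time_s"].nunique()


@dataclass(frozen=True)
class TTestReport:
    """One-sample t test of mean(k̂) against a theoretical reference."""

    statistic: float
    df: int
    p_value: float
    reference_k: float
    alpha: float
    reject: bool
    mean_k_hat: float


@dataclass
class FitResult:
    """Ordinary-least-squares fit of survivors on ln(time)."""

    strain: str
    mode: str  # "absolute" | "normalized"
    confidence_level: float
    slope: float  # count per ln-second, negative for survival fits
    intercept_n0_hat: float
    ssm_k_hat: float  # |slope|
    cqmy_phi_mu_hat: float
    corr_r: float  # signed Pearson r of (ln t, N1)
    det_r2: float
    slope_ci: tuple[float, float]
    k_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    band: pd.DataFrame  # per-time mean-response and prediction limits
    residuals: np.ndarray
    n_obs: int
    df_resid: int
    negative_n0_flag: bool
    log_times: np.ndarray = field(repr=False, default=None)
    survivors: np.ndarray = field(repr=False, default=None)
    t_test: Optional[TTestReport] = None


def counts_to_survivors(
    dataset: SurvivalDataset, mode: str = "absolute"
) -> tuple[pd.DataFrame, float]:
    """Convert CFU records to survivor counts N1 plus the control level N0.

    absolute mode: N1 = cfu_per_ml * dilution_factor * plated_volume_ml.
    normalized mode: N1 as percent of the mean control count (N0 = 100).
    """
    if mode not in ("absolute", "normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    rec = dataset.records.copy()
    rec["n1"] = rec["cfu_per_ml"] * rec["dilution_factor"] * dataset.plated_volume_ml

    controls = rec[rec["time_s"] == 0]
    if controls.empty:
        raise ValueError(f"strain {dataset.strain!r}: no t=0 control records")
    n0 = float(controls["n1"].mean())
    if n0 <= 0:
        raise ValueError(f"strain {dataset.strain!r}: control count is zero")

    if mode == "normalized":
        rec["n1"] = 100.0 * rec["n1"] / n0
        n0 = 100.0
    return rec, n0


def fit_survival(
    dataset: SurvivalDataset,
    confidence: float = 0.97,
    mode: str = "absolute",
    constants: Optional[PhysicalConstants] = None,
    exclude_below_detection: bool = True,
) -> FitResult:
    """Fit N1 = N0 - k*ln(t) by OLS and report the full statistics.

    Replicates are pooled; t=0 controls set N0/100 % only and are excluded
    from the regression (ln 0 is undefined).  Zero plate counts mean the
    survivor concentration fell below the detection limit of the counted
    dilution, not that survivors were observed to be zero, so by default
    they are censored out of the regression (``exclude_below_detection``).
    Requires at least three distinct positive exposure times after
    censoring.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    constants = constants or default_constants()
    rec, _ = counts_to_survivors(dataset, mode=mode)
    exposed = rec[rec["time_s"] > 0]
    if exclude_below_detection:
        exposed = exposed[exposed["cfu_per_ml"] > 0]
    if exposed["time_s"].nunique() < 3:
        raise ValueError(
            f"strain {dataset.strain!r}: need >= 3 distinct positive exposure "
            f"times with detectable counts, got {exposed['time_s'].nunique()}"
        )
    ln_t = np.log(exposed["time_s"].to_numpy(dtype=float))
    n1 = exposed["n1"].to_numpy(dtype=float)

    X = sm.add_constant(ln_t)
    model = sm.OLS(n1, X).fit()
    intercept, slope = model.params
    alpha = 1.0 - confidence
    ci = model.conf_int(alpha=alpha)
    slope_ci = (float(ci[1][0]), float(ci[1][1]))
    intercept_ci = (float(ci[0][0]), float(ci[0][1]))
    k_hat = abs(slope)
    # CI of |slope| for a negative slope: flip and sort.
    k_ci = tuple(sorted((abs(slope_ci[0]), abs(slope_ci[1]))))
    if slope_ci[0] < 0 < slope_ci[1]:
        k_ci = (0.0, max(abs(slope_ci[0]), abs(slope_ci[1])))

    corr_r = float(np.corrcoef(ln_t, n1)[0, 1]) if len(n1) > 1 else math.nan
    negative_n0 = intercept < 0
    if negative_n0:
        warnings.warn(
            f"strain {dataset.strain!r}: fitted N0 is negative", stacklevel=2
        )

    grid = np.unique(ln_t)
    pred = model.get_prediction(sm.add_constant(grid)).summary_frame(alpha=alpha)
    band = pd.DataFrame(
        {
            "time_s": np.exp(grid),
            "ln_t": grid,
            "fit": pred["mean"].to_numpy(),
            "mean_lower": pred["mean_ci_lower"].to_numpy(),
            "mean_upper": pred["mean_ci_upper"].to_numpy(),
            "obs_lower": pred["obs_ci_lower"].to_numpy(),
            "obs_upper": pred["obs_ci_upper"].to_numpy(),
        }
    )

    return FitResult(
        strain=dataset.strain,
        mode=mode,
        confidence_level=confidence,
        slope=float(slope),
        intercept_n0_hat=float(intercept),
        ssm_k_hat=float(k_hat),
        cqmy_phi_mu_hat=cqmy_from_ssm(k_hat, constants) if k_hat > 0 else math.nan,
        corr_r=corr_r,
        det_r2=float(model.rsquared),
        slope_ci=slope_ci,
        k_ci=(float(k_ci[0]), float(k_ci[1])),
        intercept_ci=intercept_ci,
        band=band,
        residuals=np.asarray(model.resid),
        n_obs=int(model.nobs),
        df_resid=int(model.df_resid),
        negative_n0_flag=bool(negative_n0),
        log_times=ln_t,
        survivors=n1,
    )


@dataclass(frozen=True)
class MortalityView:
    """Mortality complement of a survival fit: N = N̂0 − N1."""

    strain: str
    log_times: np.ndarray
    dead_n: np.ndarray
    slope: float  # positive, equals -survival slope
    intercept: float  # zero by construction (N = k ln t)
    ldr50_s: float
    mmt_s: float


def mortality_view(fit: FitResult, dataset: SurvivalDataset) -> MortalityView:
    """Derive the mortality series and characteristic times from a fit.

    The mortality regression line is the exact mirror of the survival fit
    (slope = +k̂ through the origin of ln t), and the half-population time
    follows the fitted parameters: ldr50 = exp(N̂0/(2k̂)).
    """
    dead = fit.intercept_n0_hat - fit.survivors
    ln_ldr50 = fit.intercept_n0_hat / (2.0 * fit.ssm_k_hat)
    ldr50 = math.exp(ln_ldr50) if ln_ldr50 < math.log(np.finfo(float).max) else math.inf
    return MortalityView(
        strain=fit.strain,
        log_times=fit.log_times,
        dead_n=dead,
        slope=-fit.slope,
        intercept=0.0,
        ldr50_s=ldr50,
        mmt_s=1.0 / fit.ssm_k_hat,
    )


def t_test_vs_theory(
    k_hats, k_reference: float, alpha: float = 0.03
) -> TTestReport:
    """One-sample t test of the mean fitted rate against a reference k̄."""
    k_hats = np.asarray(list(k_hats), dtype=float)
    if k_hats.size < 2:
        raise ValueError("need at least 2 estimates for a one-sample t test")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k_hats.std(ddof=1) == 0.0:
        # degenerate sample: identical estimates carry no sampling noise
        stat = 0.0 if k_hats.mean() == k_reference else math.copysign(
            math.inf, k_hats.mean() - k_reference
        )
        pval = 1.0 if stat == 0.0 else 0.0
    else:
        res = scipy.stats.ttest_1samp(k_hats, popmean=k_reference)
        stat, pval = float(res.statistic), float(res.pvalue)
    return TTestReport(
        statistic=stat,
        df=int(k_hats.size - 1),
        p_value=pval,
        reference_k=float(k_reference),
        alpha=alpha,
        reject=bool(pval < alpha),
        mean_k_hat=float(k_hats.mean()),
    )
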