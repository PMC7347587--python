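"""Closed-form survival/mortality kinetics of the log-time physical model.

Mortality grows logarithmically with exposure time,

    N(t)  = k * ln(t),          k = Phi_mu * Ea   (specific speed of mortality)
    N1(t) = N0 - k * ln(t),     N + N1 = N0       (conservation)

where ``Phi_mu`` is the cell quantum mortality yield (dead cells per absorbed
einstein per unit time), ``Ea = n0*h*c/lambda`` the activation energy of one
einstein, and ``N0`` the initial population.  Time enters as the dimensionless
numeric value of time-in-seconds (t = 1 s gives N = 0); this operational
convention is frozen deliberately — the log-linear law is dimensionally
informal and this is how survival-count data are fitted.

Characteristic times:

* LDR50  ``exp(N0/(2k))``  — survivors equal dead (half the population)
* MMT    ``tu = 1/k``      — minimal exposure producing one dead cell
* T      ``exp(N0/k)``     — absolute death, survivors reach zero
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants_genome import PhysicalConstants, activation_energy, default_constants

__all__ = [
    "KineticParams",
    "KineticsCurve",
    "mortality",
    "survival",
    "ssm_from_cqmy",
    "cqmy_from_ssm",
    "ldr50",
    "log_ldr50",
    "minimum_mortality_time",
    "absolute_death_time",
    "log_absolute_death_time",
    "predict_curve",
]


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the log-time mortality law.

    ``ssm_k`` is always derived as ``cqmy_phi_mu * activation_energy_ea``;
    the two are never stored inconsistently.
    """

    cqmy_phi_mu: float  # mol/(erg*s)
    activation_energy_ea: float  # erg/mol
    initial_cells_n0: float = 0.0

    def __post_init__(self) -> None:
        if not self.cqmy_phi_mu > 0:
            raise ValueError("cqmy_phi_mu must be strictly positive")
        if not self.activation_energy_ea > 0:
            raise ValueError("activation_energy_ea must be strictly positive")
        if self.initial_cells_n0 < 0:
            raise ValueError("initial_cells_n0 must be non-negative")

    @property
    def ssm_k(self) -> float:
        """Specific speed of mortality k = Phi_mu * Ea (1/s)."""
        return self.cqmy_phi_mu * self.activation_energy_ea

    @classmethod
    def from_k(
        cls,
        k: float,
        n0: float = 0.0,
        constants: Optional[PhysicalConstants] = None,
    ) -> "KineticParams":
        """Build params from the SSM slope, deriving Phi_mu via Ea."""
        constants = constants or default_constants()
        ea = activation_energy(constants)
        return cls(cqmy_phi_mu=k / ea, activation_energy_ea=ea, initial_cells_n0=n0)

    @classmethod
    def from_phi_mu(
        cls,
        phi_mu: float,
        n0: float = 0.0,
        constants: Optional[PhysicalConstants] = None,
    ) -> "KineticParams":
        constants = constants or default_constants()
        return cls(
            cqmy_phi_mu=phi_mu,
            activation_energy_ea=activation_energy(constants),
            initial_cells_n0=n0,
        )


def _check_times(t: np.ndarray) -> None:
    if np.any(t <= 0):
        bad = np.flatnonzero(t <= 0)
        raise ValueError(
            f"exposure time must be > 0 for the logarithm ln(t); "
            f"offending indices {bad.tolist()}"
        )


def mortality(t, params: KineticParams, clamp: bool = False):
    """Dead-cell count N(t) = k*ln(t); optionally clamped to [0, N0]."""
    t = np.asarray(t, dtype=float)
    _check_times(t)
    n = params.ssm_k * np.log(t)
    if clamp:
        n = np.clip(n, 0.0, params.initial_cells_n0)
    return n if n.ndim else float(n)


def survival(t, params: KineticParams, clamp: bool = False):
    """Surviving count N1(t) = N0 - k*ln(t); optionally clamped at 0/N0."""
    t = np.asarray(t, dtype=float)
    _check_times(t)
    n1 = params.initial_cells_n0 - params.ssm_k * np.log(t)
    if clamp:
        n1 = np.clip(n1, 0.0, params.initial_cells_n0)
    return n1 if n1.ndim else float(n1)


def ssm_from_cqmy(phi_mu: float, ea: float) -> float:
    """Specific speed of mortality from the quantum yield: k = Phi_mu*Ea."""
    if phi_mu <= 0 or ea <= 0:
        raise ValueError("phi_mu and ea must be strictly positive")
    return phi_mu * ea


def cqmy_from_ssm(k: float, constants: Optional[PhysicalConstants] = None) -> float:
    """Quantum mortality yield from the slope: Phi_mu = k*lambda/(n0*h*c)."""
    if k <= 0:
        raise ValueError("k must be strictly positive")
    constants = constants or default_constants()
    return k / activation_energy(constants)


def log_ldr50(params: KineticParams) -> float:
    """ln of the half-population exposure time, N0/(2k)."""
    if params.initial_cells_n0 <= 0:
        raise ValueError("initial_cells_n0 must be positive for LDR50")
    return params.initial_cells_n0 / (2.0 * params.ssm_k)

def ldr50(params: KineticParams) -> float:
    """Exposure time at which survivors equal dead cells, exp(N0/(2k)).

    Returns ``inf`` with a warning when the time is beyond representable
    range; use :func:`log_ldr50` for the always-finite logarithm.
    """
    ln_t = log_ldr50(params)
    if ln_t > math.log(np.finfo(float).max):
        import warnings

        warnings.warn(
            f"LDR50 beyond representable time; ln(t) = {ln_t:g}", stacklevel=2
        )
        return math.inf
    return math.exp(ln_t)


def minimum_mortality_time(params: KineticParams) -> float:
    """Minimum mortality time tu = 1/k (s), the exposure killing one cell."""
    return 1.0 / params.ssm_k


def log_absolute_death_time(params: KineticParams) -> float:
    """ln of the absolute-death time, N0/k."""
    if params.initial_cells_n0 <= 0:
        raise ValueError("initial_cells_n0 must be positive for absolute death time")
    return params.initial_cells_n0 / params.ssm_k


def absolute_death_time(params: KineticParams) -> float:
    """Time T = exp(N0/k) at which the predicted survivors reach zero."""
    ln_t = log_absolute_death_time(params)
    if ln_t > math.log(np.finfo(float).max):
        import warnings

        warnings.warn(
            f"absolute death time beyond representable time; ln(T) = {ln_t:g}",
            stacklevel=2,
        )
        return math.inf
    return math.exp(ln_t)


@dataclass(frozen=True)
class KineticsCurve:
    """Vectorised mortality/survival curve with clamping metadata."""

    times: np.ndarray
    dead_n: np.ndarray
    surviving_n1: np.ndarray
    clamped: np.ndarray  # True where raw N1 < 0 or raw N > N0
    pre_unitary: np.ndarray  # True where t < 1 (raw mortality negative)
    params: KineticParams
    ldr50_s: float
    mmt_s: float
    absolute_death_s: float


def predict_curve(
    times: Sequence[float], params: KineticParams, clamp: bool = True
) -> KineticsCurve:
    """Evaluate the mortality and survival laws on a time grid.

    Conservation N + N1 = N0 holds exactly before clamping; with
    ``clamp=True`` (default) survivors are floored at zero, dead cells
    capped at N0, and the affected points flagged.
    """
    t = np.asarray(times, dtype=float)
    _check_times(t)
    raw_n = mortality(t, params)
    raw_n1 = survival(t, params)
    clamped_mask = (raw_n1 < 0) | (raw_n > params.initial_cells_n0)
    if clamp:
        n = np.clip(raw_n, 0.0, params.initial_cells_n0)
        n1 = np.clip(raw_n1, 0.0, params.initial_cells_n0)
    else:
        n, n1 = raw_n, raw_n1
    return KineticsCurve(
        times=t,
        dead_n=np.atleast_1d(n),
        surviving_n1=np.atleast_1d(n1),
        clamped=np.atleast_1d(clamped_mask),
        pre_unitary=np.atleast_1d(t < 1.0),
        params=params,
        ldr50_s=ldr50(params) if params.initial_cells_n0 > 0 else math.nan,
        mmt_s=minimum_mortality_time(params),
        absolute_death_s=(
            absolute_death_time(params) if params.initial_cells_n0 > 0 else math.nan
        ),
    )
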