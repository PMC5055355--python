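"""Asymptotic exponential-recovery curve for log CD4+ cell counts.

After antiretroviral therapy (ART) starts, a patient's log CD4+ count rises
from its baseline value toward a long-term plateau.  The three-parameter
curve used throughout this package is

    log CD4(t) = Asym - (Asym - Int) * exp(-c * t)

with ``Int`` the log count at ART initiation (t = 0, years), ``Asym`` the
log of the asymptotic count, and ``c > 0`` the exponential approach rate in
1/year.  The rate is carried as ``log_rate = log(c)`` so it is unconstrained
during optimisation.  All computation happens in years; clinically reported
recovery times (half-life, time-to-gain) are returned in months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrajectoryParams",
    "DerivedSummary",
    "log_cd4_trajectory",
    "half_life",
    "t90",
    "time_to_gain",
    "fold_change",
    "MONTHS_PER_YEAR",
]

MONTHS_PER_YEAR = 12.0

#: earliest admissible visit time: 2 months before ART initiation
MIN_VISIT_TIME_YEARS = -2.0 / 12.0


@dataclass(frozen=True)
class TrajectoryParams:
    """Patient-level parameters of the asymptotic recovery curve.

    Attributes
    ----------
    intercept : float
        log CD4+ count at ART initiation (log cells/mm^3).
    asymptote : float
        log of the long-term CD4+ count (log cells/mm^3).
    log_rate : float
        natural log of the approach rate ``c`` (c in 1/year).
    """

    intercept: float
    asymptote: float
    log_rate: float

    def __post_init__(self) -> None:
        vals = (self.intercept, self.asymptote, self.log_rate)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite trajectory parameters: {vals}")

    @property
    def rate(self) -> float:
        """Approach rate ``c = exp(log_rate)`` in 1/year (always > 0)."""
        return float(np.exp(self.log_rate))

    def as_array(self) -> np.ndarray:
        return np.array([self.intercept, self.asymptote, self.log_rate])


def log_cd4_trajectory(params: TrajectoryParams, t) -> np.ndarray | float:
    """Evaluate the asymptotic curve on the log scale at time ``t`` (years).

    Monotone nondecreasing in ``t`` when ``asymptote >= intercept``; equals
    ``intercept`` exactly at t = 0 and tends to ``asymptote`` as t -> inf.
    """
    t = np.asarray(t, dtype=float)
    c = np.exp(params.log_rate)
    out = params.asymptote - (params.asymptote - params.intercept) * np.exp(-c * t)
    return float(out) if out.ndim == 0 else out


def half_life(log_rate: float) -> float:
    """Time to reach half of the total log-scale CD4 gain, in months.

    t50 = -ln(0.5)/c = ln(2)/c with c = exp(log_rate) in 1/year.
    """
    if not np.isfinite(log_rate):
        raise ValueError("log_rate must be finite")
    return MONTHS_PER_YEAR * np.log(2.0) / np.exp(log_rate)


def t90(log_rate: float) -> float:
    """Time to reach 90% of the total log-scale gain, in months (-ln(0.1)/c)."""
    if not np.isfinite(log_rate):
        raise ValueError("log_rate must be finite")
    return MONTHS_PER_YEAR * np.log(10.0) / np.exp(log_rate)


def time_to_gain(params: TrajectoryParams, delta: float) -> float:
    """Months until the cell-scale count first exceeds baseline by ``delta``.

    Solves ``exp(traj(t)) - exp(Int) = delta`` in closed form:

        t = -(1/c) * ln(1 - ln((I + delta)/I) / (Asym - Int)),  I = exp(Int)

    Raises
    ------
    ValueError
        if ``delta`` is negative or at least the total attainable cell-scale
        gain ``exp(Asym) - exp(Int)`` (the asymptote is reached only in the
        limit t -> inf).
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if delta == 0:
        return 0.0
    gain_log = params.asymptote - params.intercept
    i_cells = np.exp(params.intercept)
    total_gain = np.exp(params.asymptote) - i_cells
    if gain_log <= 0 or delta >= total_gain:
        raise ValueError(
            f"a gain of {delta} cells/mm^3 is unattainable: total gain is "
            f"{max(total_gain, 0.0):.4g} cells/mm^3 and is approached only asymptotically"
        )
    inner = 1.0 - np.log1p(delta / i_cells) / gain_log
    t_years = -np.log(inner) / np.exp(params.log_rate)
    return MONTHS_PER_YEAR * t_years


def _check_cov2(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("covariance must be 2x2")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
        raise ValueError("covariance must be positive semidefinite")
    return cov


def fold_change(beta_a: float, beta_b: float, cov: np.ndarray, z: float = 1.959963984540054):
    """Exponentiated contrast ``exp(beta_a - beta_b)`` with a 95% Wald CI.

    ``cov`` is the 2x2 covariance of ``(beta_a, beta_b)``; the CI is formed
    on the log scale from the variance of the difference and exponentiated.
    Returns ``(ratio, lower, upper)``.
    """
    cov = _check_cov2(cov)
    diff = beta_a - beta_b
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    se = np.sqrt(max(var, 0.0))
    return (np.exp(diff), np.exp(diff - z * se), np.exp(diff + z * se))


@dataclass(frozen=True)
class DerivedSummary:
    """Back-transformed group-level recovery quantities with 95% CIs.

    Cell counts in cells/mm^3; times in months.  Each triple is
    (point estimate, lower, upper).
    """

    sex: str
    age_group: str
    initial_cd4: tuple
    asymptotic_cd4: tuple
    t50: tuple
    t90: tuple
    time_to_gain_50: tuple  # may hold NaNs when the gain is unattainable

    def __post_init__(self):
        for name in ("initial_cd4", "asymptotic_cd4", "t50", "t90"):
            est, lo, hi = getattr(self, name)
            if not (lo <= est <= hi):
                raise ValueError(f"{name}: CI ({lo}, {hi}) does not bracket estimate {est}")
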