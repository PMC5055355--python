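"""Synthetic longitudinal CD4 cohorts with the generative structure the
mixed-effects analysis assumes.

The generator stands in for a non-public national treatment database.  For
each patient it draws the three latent curve parameters as cell-level fixed
effects plus a trivariate-normal random effect, draws an irregular visit
schedule (first visit in the baseline window, at least five visits,
calibrated to ~6.9 visits/patient and ~3.7 years median follow-up), then
evaluates the asymptotic curve and adds log-normal observation noise.

``default_published_config`` encodes the published group-level estimates:
initial counts 83.4 -> 121 cells/mm^3 (males) and 107 -> 136 (females)
rising with age, asymptotes 301-389 cells/mm^3, half-lives 3.72 -> 4.99
months slowing with age, random-effect SDs (0.90, 0.51, 0.74) with
correlations 0.40 (Int, Asym) and -0.60 (Asym, log c), residual SD 0.58.
Group values never printed for a cell are interpolated on the log scale and
flagged in the docs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import Cohort
from .structures import AGE_GROUPS, SEXES

__all__ = [
    "CohortConfig",
    "default_published_config",
    "generate_cohort",
    "sample_visit_schedule",
    "draw_latent_params",
]

_CELLS = [(s, a) for s in SEXES for a in AGE_GROUPS]

# age-at-initiation sampling ranges per stratum (years)
_AGE_RANGES = {"19-29": (19, 30), "30-39": (30, 40), "40-49": (40, 50), "50-59": (50, 60), "60+": (60, 75)}

# Table-1 marginal composition: patients per age stratum and share female
_AGE_PROPS = np.array([5155, 13927, 9038, 3152, 797], dtype=float)
_AGE_PROPS /= _AGE_PROPS.sum()
_FEMALE_SHARE = dict(zip(AGE_GROUPS, [0.87, 0.743, 0.62, 0.549, 0.514]))


def _loggrid(lo: float, hi: float, n: int = 5) -> np.ndarray:
    """Geometric interpolation between two printed endpoint values."""
    return np.exp(np.linspace(np.log(lo), np.log(hi), n))


@dataclass
class CohortConfig:
    """Full stated world for one synthetic cohort.

    ``cell_sizes`` maps (sex, age_group) to patient counts; the three
    ``*_log`` dicts hold the cell-level fixed effects on the log scale
    (log cells/mm^3 for intercept/asymptote, log(1/year) for the rate).
    """

    cell_sizes: dict
    intercept_log: dict
    asymptote_log: dict
    log_rate: dict
    re_sd: tuple = (0.90, 0.51, 0.74)
    re_corr: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.40, 0.0], [0.40, 1.0, -0.60], [0.0, -0.60, 1.0]])
    )
    resid_sd: float = 0.58
    mean_visits: float = 6.9
    min_visits: int = 5
    followup_median_years: float = 3.7
    followup_log_sd: float = 0.384
    followup_range: tuple = (0.5, 9.0)
    baseline_window: tuple = (-2.0 / 12.0, 3.0 / 12.0)
    seed: int = 0

    def __post_init__(self):
        self.re_corr = np.asarray(self.re_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not self.cell_sizes or all(n == 0 for n in self.cell_sizes.values()):
            raise ValueError("cohort has no patients")
        for cell, n in self.cell_sizes.items():
            if n < 0:
                raise ValueError(f"negative cell size for {cell}")
            for d in (self.intercept_log, self.asymptote_log, self.log_rate):
                if n > 0 and cell not in d:
                    raise ValueError(f"no fixed effects configured for populated cell {cell}")
        if any(s < 0 for s in self.re_sd) or self.resid_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        C = self.re_corr
        if C.shape != (3, 3) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("re_corr must be a symmetric 3x3 correlation matrix")
        if np.min(np.linalg.eigvalsh(C)) < -1e-10:
            raise ValueError("re_corr must be positive semidefinite")
        if self.mean_visits < self.min_visits:
            raise ValueError("mean_visits must be >= min_visits")

    @property
    def re_cov(self) -> np.ndarray:
        s = np.asarray(self.re_sd)
        return self.re_corr * np.outer(s, s)

    @property
    def n_patients(self) -> int:
        return int(sum(self.cell_sizes.values()))

    def cell_params(self, sex: str, age_group: str) -> np.ndarray:
        key = (sex, age_group)
        return np.array([self.intercept_log[key], self.asymptote_log[key], self.log_rate[key]])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["re_corr"] = self.re_corr.tolist()
        d["cell_sizes"] = {f"{s}|{a}": int(n) for (s, a), n in self.cell_sizes.items()}
        for k in ("intercept_log", "asymptote_log", "log_rate"):
            d[k] = {f"{s}|{a}": float(v) for (s, a), v in d[k].items()}
        return d


def default_published_config(n_patients: int = 1000, seed: int = 0, corr_int_lograte: float = 0.0) -> CohortConfig:
    """Config whose fixed effects are the published group-level estimates.

    Printed anchors: male initial CD4 83.4 (19-29) rising to 121 (60+),
    female 107 rising to 136; male asymptote 301 (19-29) peaking at 323 in
    midlife, female 377 peaking at 389 (50-59); half-life 3.72 months
    (19-29) slowing to 4.99 months (60+), shared between sexes.  Interior
    cells are log-linear interpolations between the printed anchors.
    """
    male_init = _loggrid(83.4, 121.0)
    female_init = _loggrid(107.0, 136.0)
    male_asym = np.array([301.0, 323.0, 323.0, 312.0, 301.0])
    female_asym = np.array([377.0, 381.0, 385.0, 389.0, 380.0])
    t50_months = _loggrid(3.72, 4.99)  # log-linear in the rate
    log_rate_by_age = np.log(12.0 * np.log(2.0) / t50_months)

    intercept_log, asymptote_log, log_rate = {}, {}, {}
    for i, a in enumerate(AGE_GROUPS):
        intercept_log[("male", a)] = float(np.log(male_init[i]))
        intercept_log[("female", a)] = float(np.log(female_init[i]))
        asymptote_log[("male", a)] = float(np.log(male_asym[i]))
        asymptote_log[("female", a)] = float(np.log(female_asym[i]))
        log_rate[("male", a)] = float(log_rate_by_age[i])
        log_rate[("female", a)] = float(log_rate_by_age[i])

    cell_sizes = _allocate_cells(n_patients)
    corr = np.array(
        [[1.0, 0.40, corr_int_lograte], [0.40, 1.0, -0.60], [corr_int_lograte, -0.60, 1.0]]
    )
    return CohortConfig(
        cell_sizes=cell_sizes,
        intercept_log=intercept_log,
        asymptote_log=asymptote_log,
        log_rate=log_rate,
        re_corr=corr,
        seed=seed,
    )


def _allocate_cells(n_total: int) -> dict:
    """Deterministic largest-remainder allocation matching Table-1 margins."""
    fracs = {}
    for i, a in enumerate(AGE_GROUPS):
        fracs[("female", a)] = _AGE_PROPS[i] * _FEMALE_SHARE[a]
        fracs[("male", a)] = _AGE_PROPS[i] * (1.0 - _FEMALE_SHARE[a])
    cells = list(fracs)
    exact = np.array([fracs[c] * n_total for c in cells])
    base = np.floor(exact).astype(int)
    short = n_total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for j in order[:short]:
        base[j] += 1
    return {c: int(n) for c, n in zip(cells, base)}


def sample_visit_schedule(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Visit times (years from ART initiation) for one patient.

    Count is ``min_visits`` plus a Poisson excess, so the mean is exactly
    ``mean_visits``.  The first visit falls in the baseline window, the last
    visit is first-visit + follow-up span (log-normal, median
    ``followup_median_years``), interior visits are uniform between them.
    """
    n = config.min_visits + rng.poisson(config.mean_visits - config.min_visits)
    t0 = rng.uniform(*config.baseline_window)
    span = np.exp(np.log(config.followup_median_years) + config.followup_log_sd * rng.standard_normal())
    span = float(np.clip(span, *config.followup_range))
    interior = rng.uniform(t0, t0 + span, size=n - 2)
    return np.sort(np.concatenate([[t0], interior, [t0 + span]]))


def draw_latent_params(config: CohortConfig, cell: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3) latent (Int, Asym, log c) draws for one (sex, age) cell."""
    mu = config.cell_params(*cell)
    cov = config.re_cov
    # eigendecomposition instead of Cholesky so zero-variance configs work
    w, V = np.linalg.eigh(cov)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    return mu + rng.standard_normal((n, 3)) @ L.T


def generate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Simulate a full cohort; reproducible for a fixed seed.

    Every patient gets an independent substream spawned from the root seed,
    so enlarging a cell leaves previously generated patients untouched.
    Returns a :class:`~cd4traj.cohort.Cohort` whose ``latent`` table holds
    the true per-patient parameters (oracle-only, never used in fitting).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    n_total = config.n_patients
    streams = root.spawn(n_total)

    col_pid, col_sex, col_age_grp, col_age, col_t, col_cd4 = [], [], [], [], [], []
    latent_rows = []
    pid = 0
    for cell in _CELLS:
        n_cell = config.cell_sizes.get(cell, 0)
        if n_cell == 0:
            continue
        sex, age_group = cell
        lo, hi = _AGE_RANGES[age_group]
        for _ in range(n_cell):
            rng = np.random.default_rng(streams[pid])
            theta = draw_latent_params(config, cell, 1, rng)[0]
            age = rng.uniform(lo, hi)
            t = sample_visit_schedule(config, rng)
            logy = theta[1] - (theta[1] - theta[0]) * np.exp(-np.exp(theta[2]) * t)
            logy = logy + config.resid_sd * rng.standard_normal(t.size)
            pid_str = f"P{pid:06d}"
            col_pid.extend([pid_str] * t.size)
            col_sex.extend([sex] * t.size)
            col_age_grp.extend([age_group] * t.size)
            col_age.extend([round(age, 2)] * t.size)
            col_t.append(t)
            col_cd4.append(np.exp(logy))
            latent_rows.append((pid_str, sex, age_group, *theta))
            pid += 1

    visits = pd.DataFrame(
        {
            "patient_id": col_pid,
            "sex": col_sex,
            "age_group": col_age_grp,
            "age_at_init": col_age,
            "visit_time_years": np.concatenate(col_t),
            "cd4_count": np.concatenate(col_cd4),
        }
    )
    latent = pd.DataFrame(
        latent_rows, columns=["patient_id", "sex", "age_group", "intercept", "asymptote", "log_rate"]
    )
    meta = {"generator": "cd4traj.simulate.generate_cohort", "seed": int(config.seed if seed is None else seed), "config": config.to_dict()}
    return Cohort(visits=visits, latent=latent, meta=meta)
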