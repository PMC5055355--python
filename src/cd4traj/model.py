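"""Population model of CD4 recovery: `CD4TrajectoryModel` / results object.

The model couples the asymptotic curve with cell-level fixed effects (any
of the four designs per parameter) and a trivariate patient-level random
effect with unstructured covariance.  Estimation maximises the summed
marginal log-likelihood (rate-conditional adaptive quadrature by default,
plain Laplace via ``agq_nodes=1``) over the fixed effects, a log-Cholesky
parameterisation of the random-effect covariance (guaranteeing positive
definiteness), and the log residual SD, using L-BFGS-B with a
finite-difference gradient that exploits the one-hot fixed-effect designs:
perturbing a cell coefficient only requires re-evaluating that cell's
patients.

Typical use::

    model = CD4TrajectoryModel(cohort, structure=PUBLISHED_BEST)
    res = model.fit()
    res.summary()
    res.derived_summary()          # counts, half-lives, fold changes
    res.trajectory_params          # empirical-Bayes per-patient curves
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import laplace
from .cohort import Cohort
from .convergence import fit_single_patient
from .structures import AGE_GROUPS, SEXES, PARAM_NAMES, ModelStructure, PUBLISHED_BEST
from .trajectory import DerivedSummary, TrajectoryParams, fold_change, half_life, t90, time_to_gain

__all__ = ["CD4TrajectoryModel", "CD4TrajectoryResults", "PUBLISHED_BEST"]

_Z95 = 1.959963984540054
#: covariance parameters (6 log-Cholesky) + residual SD (1), counted in AIC
N_VARIANCE_PARAMS = 7


def _chol_from_packed(lam: np.ndarray) -> np.ndarray:
    """Lower-triangular Cholesky factor from the 6 unconstrained entries.

    Order: (log l11, l21, log l22, l31, l32, log l33); the log-diagonal
    keeps the implied covariance positive definite for any real input.
    """
    L = np.zeros((3, 3))
    L[0, 0] = np.exp(lam[0])
    L[1, 0] = lam[1]
    L[1, 1] = np.exp(lam[2])
    L[2, 0] = lam[3]
    L[2, 1] = lam[4]
    L[2, 2] = np.exp(lam[5])
    return L


def _packed_from_cov(Psi: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(Psi)
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]), L[2, 0], L[2, 1], np.log(L[2, 2])])


class _LaplaceObjective:
    """Negative summed marginal log-likelihood with warm-started inner modes
    and group-aware forward-difference gradients."""

    def __init__(self, packed: laplace.PackedCohort, n_fixed: int, agq_nodes: int = 21):
        self.packed = packed
        self.p = n_fixed
        self.agq_nodes = agq_nodes
        self.b = np.zeros((packed.n_patients, 3))
        # patients touched by each fixed-effect coefficient
        self.groups = [np.any(packed.idx == k, axis=1) for k in range(n_fixed)]
        self.n_evals = 0

    def _unpack(self, phi):
        beta = phi[: self.p]
        L = _chol_from_packed(phi[self.p : self.p + 6])
        Psi = L @ L.T
        sigma = float(np.exp(phi[-1]))
        return beta, Psi, sigma

    def ll_per_patient(self, phi, rows=None, update_cache=True):
        beta, Psi, sigma = self._unpack(phi)
        pk = self.packed if rows is None else self.packed.subset(rows)
        mu = beta[pk.idx]
        b0 = self.b if rows is None else self.b[rows]
        try:
            ll, bhat = laplace.loglik_vector(pk, mu, Psi, sigma, b0=b0, agq_nodes=self.agq_nodes, gtol=1e-9)
        except np.linalg.LinAlgError:
            # degenerate covariance excursion: steep penalty, leave modes alone
            self.n_evals += 1
            return np.full(pk.n_patients, -1e8)
        if update_cache:
            if rows is None:
                self.b = bhat
            else:
                self.b[rows] = bhat
        self.n_evals += 1
        return ll

    def value_and_grad(self, phi):
        """Objective and finite-difference gradient.

        Central differences throughout (forward steps are biased by the
        likelihood's curvature when the residual SD is small).  Fixed-effect
        coefficients only re-evaluate the patients they touch, which is what
        keeps the gradient affordable with one-hot designs.  Perturbed
        evaluations warm-start from, but do not overwrite, the cached
        posterior modes, keeping the objective a clean function of the
        parameters.
        """
        ll = self.ll_per_patient(phi)
        f0 = -float(np.sum(ll))
        g = np.empty_like(phi)
        for i in range(phi.size):
            h = 1e-6 * max(1.0, abs(phi[i]))
            phi_p = phi.copy()
            phi_p[i] += h
            phi_m = phi.copy()
            phi_m[i] -= h
            rows = self.groups[i] if i < self.p else None
            ll_p = self.ll_per_patient(phi_p, rows, update_cache=False)
            ll_m = self.ll_per_patient(phi_m, rows, update_cache=False)
            g[i] = (float(np.sum(ll_m)) - float(np.sum(ll_p))) / (2.0 * h)
        return f0, g


class CD4TrajectoryModel:
    """Asymptotic nonlinear mixed-effects model for a longitudinal cohort.

    Parameters
    ----------
    cohort : Cohort or DataFrame
        Long-format visit records (see :mod:`cd4traj.cohort`).
    structure : ModelStructure
        Fixed-effect design per curve parameter; defaults to the
        best-supported structure (age-by-sex cells on intercept and
        asymptote, age effect on the rate).
    """

    def __init__(self, cohort, structure: ModelStructure = PUBLISHED_BEST):
        if isinstance(cohort, Cohort):
            visits = cohort.visits
        elif isinstance(cohort, pd.DataFrame):
            visits = cohort
        else:
            raise TypeError("cohort must be a Cohort or a visits DataFrame")
        if len(visits) == 0:
            raise ValueError("empty cohort")
        self.structure = ModelStructure(*structure).validate()
        self.packed = laplace.pack_cohort(visits, self.structure)
        self._check_designs()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, structure: ModelStructure = PUBLISHED_BEST):
        return cls(df, structure)

    @classmethod
    def from_csv(cls, path, structure: ModelStructure = PUBLISHED_BEST):
        return cls(Cohort.from_csv(path), structure)

    # ------------------------------------------------------------------
    def _check_designs(self):
        """A requested cell effect with no patients in that cell is an error."""
        for k in range(self.structure.n_fixed):
            if not np.any(self.packed.idx == k):
                raise ValueError(
                    f"degenerate design: coefficient {self.structure.coef_names()[k]!r} "
                    "has no patients in its cell"
                )

    @property
    def nobs(self) -> int:
        return int(self.packed.nobs.sum())

    @property
    def n_patients(self) -> int:
        return self.packed.n_patients

    def loglike(self, beta, Psi, sigma, agq_nodes: int = 21) -> float:
        """Summed marginal log-likelihood at given parameters."""
        mu = np.asarray(beta)[self.packed.idx]
        ll, _ = laplace.loglik_vector(self.packed, mu, np.asarray(Psi), float(sigma), agq_nodes=agq_nodes)
        return float(ll.sum())

    # ------------------------------------------------------------------
    def _start_values(self) -> np.ndarray:
        """Fixed effects from per-patient least squares (crude fallback),
        covariance from the winsorized sample covariance of those fits."""
        pk = self.packed
        n = pk.n_patients
        est = np.empty((n, 3))
        resid_sds = []
        for j in range(n):
            m = pk.mask[j].astype(bool)
            t, y = pk.t[j, m], pk.y[j, m]
            fit = fit_single_patient(t, np.exp(y), n_starts=1)
            if fit.converged and abs(fit.params.log_rate) < 5:
                est[j] = fit.params.as_array()
                dof = max(t.size - 3, 1)
                resid_sds.append(np.sqrt(2.0 * fit.cost / dof))
            else:
                order = np.argsort(t)
                est[j] = (y[order[0]], float(np.mean(y[order[-2:]])), np.log(2.0))
        # winsorize columns before taking moments; individual fits can be wild
        for k in range(3):
            med = np.median(est[:, k])
            scale = 1.4826 * np.median(np.abs(est[:, k] - med)) + 1e-6
            est[:, k] = np.clip(est[:, k], med - 3 * scale, med + 3 * scale)

        offsets = self.structure.block_offsets
        beta0 = np.zeros(self.structure.n_fixed)
        for k in range(self.structure.n_fixed):
            block = 2 if k >= offsets[2] else (1 if k >= offsets[1] else 0)
            sel = pk.idx[:, block] == k
            beta0[k] = est[sel, block].mean()
        dev = est - beta0[pk.idx]
        C = np.cov(dev.T)
        Psi0 = 0.7 * C + 0.3 * np.diag(np.diag(C))
        d = np.clip(np.diag(Psi0).copy(), 0.04, 4.0)
        Psi0 = Psi0 - np.diag(np.diag(Psi0)) + np.diag(d)
        if np.min(np.linalg.eigvalsh(Psi0)) < 1e-4:
            Psi0 = np.diag(d)
        sigma0 = float(np.clip(np.median(resid_sds) if resid_sds else 0.5, 0.05, 2.0))
        return np.concatenate([beta0, _packed_from_cov(Psi0), [np.log(sigma0)]])

    def fit(
        self,
        start: np.ndarray | None = None,
        maxiter: int = 500,
        ftol: float = 1e-12,
        gtol: float = 1e-3,
        agq_nodes: int = 21,
        verbose: bool = False,
    ) -> "CD4TrajectoryResults":
        """Maximise the adaptive-quadrature marginal likelihood.

        ``agq_nodes`` controls the accuracy of the marginal likelihood:
        1 requests plain Laplace, while the default (21) uses the
        rate-conditional scheme -- the (Int, Asym) pair integrated in
        closed form and 21-node adaptive Gauss-Hermite quadrature on the
        rate's random effect -- which is accurate to ~1e-6 per patient and
        removes the Laplace bias on the variance components.

        Returns a results object in all cases; ``converged`` is a flag,
        never an exception.
        """
        p = self.structure.n_fixed
        phi0 = self._start_values() if start is None else np.asarray(start, dtype=float)
        bounds = [(None, None)] * p + [(-6.5, 2), (-5, 5), (-6.5, 2), (-5, 5), (-5, 5), (-6.5, 2), (-7, 3)]
        opts = {"maxiter": maxiter, "ftol": ftol, "gtol": gtol, "maxcor": 20}
        obj = _LaplaceObjective(self.packed, p, agq_nodes=agq_nodes)
        res = minimize(
            obj.value_and_grad,
            phi0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options=opts,
        )
        if verbose:
            print(f"L-BFGS-B: {res.message}; f={res.fun:.4f}; nit={res.nit}; evals={obj.n_evals}")
        phi = res.x
        ll_vec = obj.ll_per_patient(phi)  # refresh EB modes at the optimum
        beta, Psi, sigma = obj._unpack(phi)
        converged = bool(res.success) and bool(np.all(np.isfinite(phi)))
        grad_norm = None
        if not converged and np.all(np.isfinite(phi)):
            # a failed line search at a numerically flat point is still a
            # solution: accept when the gradient of the summed negative
            # log-likelihood is negligible (|g|_inf < 1 against a curvature
            # of order the sample size means a log-likelihood slack < 0.01)
            _, g_final = obj.value_and_grad(phi)
            grad_norm = float(np.max(np.abs(g_final)))
            converged = bool(grad_norm < 1.0)
        return CD4TrajectoryResults(
            model=self,
            params_vector=phi,
            beta=beta,
            Psi=Psi,
            sigma=sigma,
            llf=float(ll_vec.sum()),
            converged=converged,
            eb_random_effects=obj.b.copy(),
            diagnostics={
                "message": str(res.message),
                "n_iter": int(res.nit),
                "n_obj_evals": obj.n_evals,
                "final_grad_norm": grad_norm,
            },
        )


@dataclass
class CD4TrajectoryResults:
    """Fitted population model: estimates, uncertainty, diagnostics.

    Fixed-effect coefficients are cell means on the log scale; group-level
    clinical quantities come from :meth:`derived_summary` and group
    contrasts from :meth:`fold_change` / :meth:`wald_contrast`.
    """

    model: CD4TrajectoryModel
    params_vector: np.ndarray
    beta: np.ndarray
    Psi: np.ndarray
    sigma: float
    llf: float
    converged: bool
    eb_random_effects: np.ndarray
    diagnostics: dict

    def __post_init__(self):
        self._cov_params = None

    # ---- parameter views ---------------------------------------------
    @property
    def structure(self) -> ModelStructure:
        return self.model.structure

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.structure.coef_names(), name="estimate")

    @property
    def re_sd(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.Psi)), index=PARAM_NAMES, name="re_sd")

    @property
    def re_corr(self) -> pd.DataFrame:
        s = np.sqrt(np.diag(self.Psi))
        corr = self.Psi / np.outer(s, s)
        return pd.DataFrame(corr, index=PARAM_NAMES, columns=PARAM_NAMES)

    @property
    def sigma_resid(self) -> float:
        """Residual SD of log CD4 (within-patient, observation level)."""
        return self.sigma

    @property
    def k_params(self) -> int:
        return self.structure.n_fixed + N_VARIANCE_PARAMS

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def nobs(self) -> int:
        return self.model.nobs

    # ---- inference ----------------------------------------------------
    def cov_params(self) -> pd.DataFrame:
        """Covariance of the fixed effects from the GLS information matrix.

        Each patient contributes F' V^-1 F with F the curve's Jacobian wrt
        the fixed effects at the empirical-Bayes mode and V = Z Psi Z' +
        sigma^2 I the patient's marginal covariance; variance parameters
        are held at their estimates (the standard NLME convention).
        """
        if self._cov_params is not None:
            return self._cov_params
        pk = self.model.packed
        theta = self.beta[pk.idx] + self.eb_random_effects
        f, dI, dA, dL, _, _ = laplace._curve(theta, pk.t)
        n, tmax = pk.t.shape
        Z = np.stack([dI * pk.mask, dA * pk.mask, dL * pk.mask], axis=2)
        # padded slots have zero Z rows, so V is sigma^2 on their diagonal
        # and they contribute nothing to the information
        V = Z @ self.Psi @ np.swapaxes(Z, 1, 2) + (self.sigma ** 2) * np.eye(tmax)
        W = np.linalg.solve(V, Z)
        M = np.einsum("ntk,ntl->nkl", Z, W)
        p = self.structure.n_fixed
        info = np.zeros((p, p))
        for j in range(n):
            ix = pk.idx[j]
            info[np.ix_(ix, ix)] += M[j]
        cov = np.linalg.inv(info)
        names = self.structure.coef_names()
        self._cov_params = pd.DataFrame(cov, index=names, columns=names)
        return self._cov_params

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params().to_numpy())), index=self.structure.coef_names())

    def wald_contrast(self, weights, transform: bool = False):
        """Estimate and 95% CI for a linear combination of fixed effects.

        ``weights`` is a length-p vector (or dict keyed by coefficient
        name).  With ``transform=True`` the result is exponentiated.
        Returns ``(estimate, se, lower, upper)`` on the requested scale.
        """
        p = self.structure.n_fixed
        if isinstance(weights, dict):
            w = np.zeros(p)
            names = self.structure.coef_names()
            for key, val in weights.items():
                w[names.index(key)] = val
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (p,):
                raise ValueError(f"contrast length {w.shape} does not match {p} fixed effects")
        est = float(w @ self.beta)
        se = float(np.sqrt(w @ self.cov_params().to_numpy() @ w))
        lo, hi = est - _Z95 * se, est + _Z95 * se
        if transform:
            return np.exp(est), se, np.exp(lo), np.exp(hi)
        return est, se, lo, hi

    def fold_change(self, param: str, cell_a: tuple, cell_b: tuple):
        """Ratio of a parameter between two (sex, age) cells, with 95% CI.

        e.g. ``res.fold_change("intercept", ("female", "19-29"), ("male", "19-29"))``
        gives the female/male baseline-count ratio among 19-29 year olds.
        """
        ia = self.structure.coef_index(param, *cell_a)
        ib = self.structure.coef_index(param, *cell_b)
        V = self.cov_params().to_numpy()
        cov2 = np.array([[V[ia, ia], V[ia, ib]], [V[ib, ia], V[ib, ib]]])
        return fold_change(self.beta[ia], self.beta[ib], cov2)

    # ---- empirical Bayes ----------------------------------------------
    @property
    def random_effects(self) -> pd.DataFrame:
        """Posterior-mode random effects (deviations) per patient."""
        return pd.DataFrame(
            self.eb_random_effects,
            columns=[f"b_{p}" for p in PARAM_NAMES],
            index=pd.Index(self.model.packed.patient_ids, name="patient_id"),
        )

    @property
    def trajectory_params(self) -> pd.DataFrame:
        """Empirical-Bayes per-patient curve parameters (fixed + random)."""
        pk = self.model.packed
        theta = self.beta[pk.idx] + self.eb_random_effects
        df = pd.DataFrame(theta, columns=list(PARAM_NAMES))
        df.insert(0, "patient_id", pk.patient_ids)
        df.insert(1, "sex", pk.sex)
        df.insert(2, "age_group", pk.age_group)
        return df

    # ---- derived clinical quantities ----------------------------------
    def _cell_triple(self, sex: str, age_group: str):
        ix = [self.structure.coef_index(p, sex, age_group) for p in PARAM_NAMES]
        V = self.cov_params().to_numpy()
        return np.array(ix), self.beta[ix], V[np.ix_(ix, ix)]

    def derived_summary(self, gain: float = 50.0) -> list[DerivedSummary]:
        """Back-transformed group-level quantities for every sex-age cell.

        Counts are exponentiated coefficients, recovery times come from the
        rate (half-life and time to 90%), and ``time_to_gain_*`` is the
        time until the cell-scale count exceeds baseline by ``gain``
        cells/mm^3 (NaN where the asymptote precludes that gain).  CIs are
        Wald on the log scale (delta method for the gain time).
        """
        out = []
        for sex in SEXES:
            for age in AGE_GROUPS:
                _, b, V = self._cell_triple(sex, age)
                se = np.sqrt(np.diag(V))
                init = tuple(np.exp([b[0], b[0] - _Z95 * se[0], b[0] + _Z95 * se[0]]))
                asym = tuple(np.exp([b[1], b[1] - _Z95 * se[1], b[1] + _Z95 * se[1]]))
                t50v = (half_life(b[2]), half_life(b[2] + _Z95 * se[2]), half_life(b[2] - _Z95 * se[2]))
                t90v = (t90(b[2]), t90(b[2] + _Z95 * se[2]), t90(b[2] - _Z95 * se[2]))
                ttg = self._time_to_gain_ci(b, V, gain)
                out.append(DerivedSummary(sex, age, init, asym, t50v, t90v, ttg))
        return out

    def _time_to_gain_ci(self, b, V, gain):
        try:
            point = time_to_gain(TrajectoryParams(*b), gain)
        except ValueError:
            return (np.nan, np.nan, np.nan)
        grad = np.empty(3)
        for k in range(3):
            bp = b.copy()
            h = 1e-6 * max(1.0, abs(b[k]))
            bp[k] += h
            try:
                grad[k] = (time_to_gain(TrajectoryParams(*bp), gain) - point) / h
            except ValueError:
                return (point, np.nan, np.nan)
        se = float(np.sqrt(max(grad @ V @ grad, 0.0)))
        return (point, max(point - _Z95 * se, 0.0), point + _Z95 * se)

    def derived_table(self, gain: float = 50.0) -> pd.DataFrame:
        rows = []
        for d in self.derived_summary(gain):
            rows.append(
                {
                    "sex": d.sex,
                    "age_group": d.age_group,
                    "initial_cd4": d.initial_cd4[0],
                    "initial_lo": d.initial_cd4[1],
                    "initial_hi": d.initial_cd4[2],
                    "asymptotic_cd4": d.asymptotic_cd4[0],
                    "asymptotic_lo": d.asymptotic_cd4[1],
                    "asymptotic_hi": d.asymptotic_cd4[2],
                    "t50_months": d.t50[0],
                    "t90_months": d.t90[0],
                    f"time_to_gain_{gain:g}_months": d.time_to_gain_50[0],
                }
            )
        return pd.DataFrame(rows)

    # ---- reporting ----------------------------------------------------
    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Asymptotic CD4 trajectory mixed model (adaptive-quadrature marginal likelihood)")
        add("=" * 70)
        add(f"structure: {self.structure.label()}    patients: {self.model.n_patients}"
            f"    visits: {self.nobs}")
        add(f"logLik: {self.llf:.2f}    AIC: {self.aic:.2f}    k: {self.k_params}"
            f"    converged: {self.converged}")
        add("")
        add("Fixed effects (log scale)")
        add("-" * 70)
        bse = self.bse
        for name, est in self.params.items():
            se = bse[name]
            add(f"  {name:<28s} {est:9.4f}  (se {se:.4f})  exp: {np.exp(est):8.1f}")
        add("")
        add("Random effects (patient level)")
        add("-" * 70)
        sd = self.re_sd
        corr = self.re_corr
        add(f"  sd(intercept) {sd['intercept']:.3f}   sd(asymptote) {sd['asymptote']:.3f}"
            f"   sd(log_rate) {sd['log_rate']:.3f}")
        add(f"  corr(Int,Asym) {corr.loc['intercept', 'asymptote']:.3f}"
            f"   corr(Asym,logc) {corr.loc['asymptote', 'log_rate']:.3f}"
            f"   corr(Int,logc) {corr.loc['intercept', 'log_rate']:.3f}")
        add(f"  residual sd (log CD4): {self.sigma:.3f}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "structure": self.structure.label(),
            "fixed_effects": dict(self.params),
            "fixed_effect_se": {k: float(v) for k, v in self.bse.items()},
            "re_sd": dict(self.re_sd),
            "re_corr": self.re_corr.to_numpy().tolist(),
            "residual_sd": self.sigma,
            "loglik": self.llf,
            "aic": self.aic,
            "k_params": self.k_params,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    # ---- plotting ------------------------------------------------------
    def plot_group_curves(self, ax=None, t_max_years: float = 6.0):
        """Fitted mean log-scale trajectories per sex-age cell."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        tt = np.linspace(0, t_max_years, 200)
        for sex in SEXES:
            for age in AGE_GROUPS:
                _, b, _ = self._cell_triple(sex, age)
                curve = b[1] - (b[1] - b[0]) * np.exp(-np.exp(b[2]) * tt)
                ax.plot(tt, np.exp(curve), label=f"{sex} {age}", lw=1.2)
        ax.set_xlabel("years since ART initiation")
        ax.set_ylabel("CD4+ cells/mm$^3$")
        ax.legend(fontsize=7, ncol=2)
        return ax
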