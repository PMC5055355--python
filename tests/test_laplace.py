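"""Marginal-likelihood engine against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import cd4traj as c
from cd4traj.laplace import PackedCohort, loglik_vector, pack_cohort, patient_loglik_laplace

PSI = np.array(
    [
        [0.81, 0.40 * 0.90 * 0.51, 0.0],
        [0.40 * 0.90 * 0.51, 0.51**2, -0.60 * 0.51 * 0.74],
        [0.0, -0.60 * 0.51 * 0.74, 0.74**2],
    ]
)
MU = np.array([4.42, 5.71, 0.80])
SIGMA = 0.58


def _simulate_patient(rng, n=None):
    n = int(rng.integers(5, 10)) if n is None else n
    t = np.sort(rng.uniform(-0.1, 4.0, n))
    b = np.linalg.cholesky(PSI) @ rng.standard_normal(3)
    th = MU + b
    f = th[1] - (th[1] - th[0]) * np.exp(-np.exp(th[2]) * t)
    return t, f + SIGMA * rng.standard_normal(n)


class TestOracles:
    def test_fixed_rate_matches_closed_form_lmm(self, rng):
        # with the rate fixed the curve is linear in (Int, Asym); the Laplace
        # approximation must equal the closed-form Gaussian marginal
        for _ in range(20):
            t, y = _simulate_patient(rng)
            E = np.exp(-np.exp(MU[2]) * t)
            Z = np.column_stack([E, 1.0 - E])
            f0 = MU[1] - (MU[1] - MU[0]) * E
            V = Z @ PSI[:2, :2] @ Z.T + SIGMA**2 * np.eye(len(t))
            exact = multivariate_normal.logpdf(y, mean=f0, cov=V)
            lap = patient_loglik_laplace(y, t, MU, PSI, SIGMA, re_dims=(0, 1))
            assert lap == pytest.approx(exact, rel=1e-6)

    def test_zero_random_effects_matches_plain_gaussian(self, rng):
        t, y = _simulate_patient(rng)
        f0 = MU[1] - (MU[1] - MU[0]) * np.exp(-np.exp(MU[2]) * t)
        exact = norm.logpdf(y, f0, SIGMA).sum()
        assert patient_loglik_laplace(y, t, MU, PSI, SIGMA, re_dims=()) == pytest.approx(exact)
        tiny = patient_loglik_laplace(y, t, MU, np.eye(3) * 1e-10, SIGMA)
        assert tiny == pytest.approx(exact, abs=1e-5)

    def test_rate_conditional_quadrature_matches_brute_force(self, rng):
        # full 3-D random effects against a dense (non-adaptive) 40^3
        # Gauss-Hermite evaluation of the marginal integral
        x, w = np.polynomial.hermite_e.hermegauss(40)
        X = np.stack(np.meshgrid(x, x, x, indexing="ij"), -1).reshape(-1, 3)
        W = (w[:, None, None] * w[None, :, None] * w[None, None, :]).reshape(-1)
        L = np.linalg.cholesky(PSI)
        for _ in range(10):
            t, y = _simulate_patient(rng)
            th = MU + X @ L.T
            f = th[:, 1:2] - (th[:, 1:2] - th[:, 0:1]) * np.exp(
                np.clip(-np.exp(np.clip(th[:, 2:3], -30, 30)) * t[None, :], -30, 8)
            )
            llc = -0.5 * np.sum((y[None, :] - f) ** 2, axis=1) / SIGMA**2 - len(y) / 2 * np.log(
                2 * np.pi * SIGMA**2
            )
            m = llc.max()
            brute = m + np.log(np.sum(W * np.exp(llc - m))) - 1.5 * np.log(2 * np.pi)
            ours = patient_loglik_laplace(y, t, MU, PSI, SIGMA)
            assert ours == pytest.approx(brute, abs=2e-3)

    def test_single_observation_loglik_finite(self):
        ll = patient_loglik_laplace([4.5], [0.1], MU, PSI, SIGMA)
        assert np.isfinite(ll)

    def test_laplace_one_node_less_accurate_than_quadrature(self, rng):
        t, y = _simulate_patient(rng, n=6)
        packed = PackedCohort(
            y[None, :], t[None, :], np.ones((1, len(y))), np.array([len(y)]),
            np.zeros((1, 3), dtype=np.intp), np.array(["p"]), np.array(["-"]), np.array(["-"]),
        )
        ll1, _ = loglik_vector(packed, MU[None, :], PSI, SIGMA, agq_nodes=1)
        ll21, _ = loglik_vector(packed, MU[None, :], PSI, SIGMA, agq_nodes=21)
        assert np.isfinite(ll1[0]) and np.isfinite(ll21[0])
        # both finite and close; the refinement changes the value slightly
        assert abs(ll1[0] - ll21[0]) < 0.5


class TestPacking:
    def test_pack_preserves_observations(self, small_cohort):
        packed = pack_cohort(small_cohort.visits, c.PUBLISHED_BEST)
        assert packed.nobs.sum() == small_cohort.n_visits
        assert packed.n_patients == small_cohort.n_patients
        j = 0
        pid = packed.patient_ids[j]
        sub = small_cohort.visits[small_cohort.visits["patient_id"] == pid]
        m = packed.mask[j].astype(bool)
        np.testing.assert_allclose(packed.y[j, m], np.log(sub["cd4_count"].to_numpy()))
        np.testing.assert_allclose(packed.t[j, m], sub["visit_time_years"].to_numpy())

    def test_loglik_invariant_to_row_order(self, small_cohort, rng):
        shuffled = small_cohort.visits.sample(frac=1.0, random_state=1)
        a = pack_cohort(small_cohort.visits, c.PUBLISHED_BEST)
        b = pack_cohort(shuffled, c.PUBLISHED_BEST)
        beta = np.concatenate([
            [4.4] * 10,
            [5.7] * 10,
            [0.8] * 5,
        ])
        for packed in (a, b):
            ll, _ = loglik_vector(packed, beta[packed.idx], PSI, SIGMA, agq_nodes=21)
        lla, _ = loglik_vector(a, beta[a.idx], PSI, SIGMA, agq_nodes=21)
        llb, _ = loglik_vector(b, beta[b.idx], PSI, SIGMA, agq_nodes=21)
        assert lla.sum() == pytest.approx(llb.sum(), rel=1e-12)

    def test_invalid_covariance_raises(self, small_cohort):
        packed = pack_cohort(small_cohort.visits, c.PUBLISHED_BEST)
        bad = np.zeros((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            loglik_vector(packed, np.zeros((packed.n_patients, 3)), bad, SIGMA)
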