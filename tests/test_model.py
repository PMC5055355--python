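"""Mixed-model fitting: recovery, determinism, inference, empirical Bayes."""

import numpy as np
import pandas as pd
import pytest

import cd4traj as c
from cd4traj.model import CD4TrajectoryModel, N_VARIANCE_PARAMS
from cd4traj.structures import ModelStructure


@pytest.fixture(scope="module")
def fitted():
    """One fit of the full structure on a 300-patient default cohort."""
    cohort = c.generate_cohort(c.default_published_config(n_patients=300, seed=21))
    model = CD4TrajectoryModel(cohort)
    return cohort, model, model.fit()


class TestFitBasics:
    def test_noiseless_fixed_effect_recovery(self):
        # zero random effects, tiny residual noise, correctly specified
        # sex-only design: estimates land on truth to 1e-3 on the log scale
        cfg = c.default_published_config(n_patients=120, seed=13)
        cfg.re_sd = (0.0, 0.0, 0.0)
        cfg.resid_sd = 0.003
        truth = {"female": (np.log(107.0), np.log(377.0)), "male": (np.log(83.4), np.log(301.0))}
        for s in c.SEXES:
            for a in c.AGE_GROUPS:
                cfg.intercept_log[(s, a)] = truth[s][0]
                cfg.asymptote_log[(s, a)] = truth[s][1]
                cfg.log_rate[(s, a)] = np.log(2.2364)
        cohort = c.generate_cohort(cfg)
        res = CD4TrajectoryModel(cohort, structure=ModelStructure("sex", "sex", "constant")).fit()
        for s in c.SEXES:
            assert res.params[f"intercept[{s}]"] == pytest.approx(truth[s][0], abs=1e-3)
            assert res.params[f"asymptote[{s}]"] == pytest.approx(truth[s][1], abs=1e-3)
        assert res.params["log_rate[(all)]"] == pytest.approx(np.log(2.2364), abs=1e-3)

    def test_refit_is_deterministic(self):
        cohort = c.generate_cohort(c.default_published_config(n_patients=80, seed=5))
        model = CD4TrajectoryModel(cohort, structure=ModelStructure("constant", "constant", "constant"))
        r1 = model.fit()
        r2 = CD4TrajectoryModel(cohort, structure=ModelStructure("constant", "constant", "constant")).fit()
        np.testing.assert_array_equal(r1.params_vector, r2.params_vector)
        assert r1.llf == r2.llf

    def test_degenerate_design_raises(self, small_cohort):
        visits = small_cohort.visits
        no_old_males = visits[~((visits["sex"] == "male") & (visits["age_group"] == "60+"))]
        with pytest.raises(ValueError, match="degenerate design"):
            CD4TrajectoryModel(no_old_males, structure=c.PUBLISHED_BEST)

    def test_aic_identity_and_counts(self, fitted):
        _, _, res = fitted
        assert res.k_params == res.structure.n_fixed + N_VARIANCE_PARAMS
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.k_params)

    def test_converged_is_flag_not_exception(self, fitted):
        _, _, res = fitted
        assert isinstance(res.converged, bool)

    def test_fit_quality_on_moderate_cohort(self, fitted):
        cohort, _, res = fitted
        # single-cohort sanity: variance components in a generous bracket
        assert 0.6 < res.re_sd["intercept"] < 1.2
        assert 0.3 < res.re_sd["asymptote"] < 0.75
        assert 0.4 < res.re_sd["log_rate"] < 1.1
        assert 0.5 < res.sigma < 0.66
        assert res.re_corr.loc["intercept", "asymptote"] > 0
        assert res.re_corr.loc["asymptote", "log_rate"] < 0


class TestInference:
    def test_cov_params_symmetric_pd(self, fitted):
        _, _, res = fitted
        V = res.cov_params().to_numpy()
        assert np.allclose(V, V.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(V)) > 0
        assert (res.bse > 0).all()

    def test_unit_contrast_equals_coefficient(self, fitted):
        _, _, res = fitted
        w = np.zeros(res.structure.n_fixed)
        w[3] = 1.0
        est, se, lo, hi = res.wald_contrast(w)
        assert est == res.beta[3]
        assert se == pytest.approx(res.bse.iloc[3])
        assert lo < est < hi

    def test_zero_contrast_degenerate(self, fitted):
        _, _, res = fitted
        est, se, lo, hi = res.wald_contrast(np.zeros(res.structure.n_fixed))
        assert est == 0.0 and se == 0.0 and lo == hi == 0.0

    def test_dimension_mismatch_raises(self, fitted):
        _, _, res = fitted
        with pytest.raises(ValueError):
            res.wald_contrast(np.ones(3))

    def test_fold_change_self_is_one(self, fitted):
        _, _, res = fitted
        ratio, lo, hi = res.fold_change("intercept", ("male", "19-29"), ("male", "19-29"))
        assert ratio == 1.0

    def test_named_contrast_matches_fold_change(self, fitted):
        _, _, res = fitted
        ratio, _, _ = res.fold_change("intercept", ("female", "19-29"), ("male", "19-29"))
        est, *_ = res.wald_contrast(
            {"intercept[female:19-29]": 1.0, "intercept[male:19-29]": -1.0}, transform=True
        )
        assert est == pytest.approx(ratio)


class TestEmpiricalBayes:
    def test_on_curve_patient_has_zero_effects(self, fitted):
        # a patient whose observations sit exactly on the *fitted* cell-mean
        # curve receives a zero random-effect deviation: the empirical-Bayes
        # estimate then equals the fixed effects
        from cd4traj.laplace import loglik_vector, PackedCohort

        _, _, res = fitted
        mu_hat = np.array([
            res.params["intercept[female:30-39]"],
            res.params["asymptote[female:30-39]"],
            res.params["log_rate[30-39]"],
        ])
        t = np.array([0.05, 0.4, 1.0, 1.8, 2.6, 3.5])
        y = mu_hat[1] - (mu_hat[1] - mu_hat[0]) * np.exp(-np.exp(mu_hat[2]) * t)
        packed = PackedCohort(
            y[None, :], t[None, :], np.ones((1, 6)), np.array([6]),
            np.zeros((1, 3), dtype=np.intp), np.array(["p"]), np.array(["-"]), np.array(["-"]),
        )
        _, b = loglik_vector(packed, mu_hat[None, :], res.Psi, res.sigma, agq_nodes=21)
        assert np.all(np.abs(b) < 1e-6)

    def test_shrinkage_toward_cell_means(self, fitted):
        cohort, model, res = fitted
        pk = model.packed
        eb = res.random_effects.to_numpy()
        n_checked = 0
        n_shrunk = 0
        for j in range(pk.n_patients):
            m = pk.mask[j].astype(bool)
            fit = c.fit_single_patient(pk.t[j, m], np.exp(pk.y[j, m]))
            if not fit.converged:
                continue
            mu_j = res.beta[pk.idx[j]]
            ls_dev = fit.params.as_array() - mu_j
            n_checked += 1
            if np.linalg.norm(eb[j]) <= np.linalg.norm(ls_dev) + 1e-8:
                n_shrunk += 1
        assert n_checked > 50
        assert n_shrunk / n_checked > 0.95

    def test_eb_correlation_reflects_generating_correlation(self, fitted):
        _, _, res = fitted
        tp = res.trajectory_params
        di = tp["intercept"] - tp.groupby(["sex", "age_group"], observed=True)["intercept"].transform("mean")
        da = tp["asymptote"] - tp.groupby(["sex", "age_group"], observed=True)["asymptote"].transform("mean")
        corr = np.corrcoef(di, da)[0, 1]
        # EB estimates are shrunken, so the raw correlation is attenuated /
        # noise-coupled; require the right sign and a sane magnitude
        assert 0.15 < corr < 0.75


class TestDerived:
    def test_derived_summary_identities(self, fitted):
        _, _, res = fitted
        for d in res.derived_summary():
            assert d.t90[0] / d.t50[0] == pytest.approx(np.log(10) / np.log(2), rel=1e-12)
            assert d.initial_cd4[1] <= d.initial_cd4[0] <= d.initial_cd4[2]
            assert d.asymptotic_cd4[1] <= d.asymptotic_cd4[0] <= d.asymptotic_cd4[2]
            assert d.t50[1] <= d.t50[0] <= d.t50[2]

    def test_derived_table_shape(self, fitted):
        _, _, res = fitted
        table = res.derived_table()
        assert len(table) == 10  # 2 sexes x 5 age strata
        assert (table["initial_cd4"] > 0).all()

    def test_json_roundtrip(self, fitted, tmp_path):
        _, _, res = fitted
        import json

        path = tmp_path / "fit.json"
        res.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["structure"] == "age_sex/age_sex/age"
        assert payload["aic"] == pytest.approx(res.aic)
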