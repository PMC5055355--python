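"""Synthetic-cohort generator: determinism, calibration, latent moments."""

import numpy as np
import pandas as pd
import pytest

import cd4traj as c
from cd4traj.simulate import CohortConfig, _allocate_cells, default_published_config, generate_cohort


class TestDefaultConfig:
    def test_printed_anchor_values(self):
        cfg = default_published_config()
        assert np.exp(cfg.intercept_log[("male", "19-29")]) == pytest.approx(83.4)
        assert np.exp(cfg.intercept_log[("male", "60+")]) == pytest.approx(121.0)
        assert np.exp(cfg.intercept_log[("female", "19-29")]) == pytest.approx(107.0)
        assert np.exp(cfg.intercept_log[("female", "60+")]) == pytest.approx(136.0)
        assert np.exp(cfg.asymptote_log[("male", "19-29")]) == pytest.approx(301.0)
        assert np.exp(cfg.asymptote_log[("female", "19-29")]) == pytest.approx(377.0)
        # rate fixed effects reproduce the printed half-lives (months)
        assert c.half_life(cfg.log_rate[("male", "19-29")]) == pytest.approx(3.72)
        assert c.half_life(cfg.log_rate[("female", "60+")]) == pytest.approx(4.99)

    def test_variance_components_are_printed_values(self):
        cfg = default_published_config()
        assert cfg.re_sd == (0.90, 0.51, 0.74)
        assert cfg.resid_sd == 0.58
        assert cfg.re_corr[0, 1] == pytest.approx(0.40)
        assert cfg.re_corr[1, 2] == pytest.approx(-0.60)
        assert cfg.re_corr[0, 2] == 0.0  # unprinted, defaults to zero

    def test_cell_allocation_matches_margins(self):
        sizes = _allocate_cells(32069)
        assert sum(sizes.values()) == 32069
        by_age = {a: sizes[("female", a)] + sizes[("male", a)] for a in c.AGE_GROUPS}
        assert by_age["30-39"] == pytest.approx(13927, abs=2)
        female = sizes[("female", "19-29")] / by_age["19-29"]
        assert female == pytest.approx(0.87, abs=0.005)

    def test_invalid_configs_rejected(self):
        cfg = default_published_config()
        with pytest.raises(ValueError):
            CohortConfig(
                cell_sizes={},
                intercept_log=cfg.intercept_log,
                asymptote_log=cfg.asymptote_log,
                log_rate=cfg.log_rate,
            )
        bad = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, -0.99], [0.0, -0.99, 1.0]])
        with pytest.raises(ValueError):
            CohortConfig(
                cell_sizes=cfg.cell_sizes,
                intercept_log=cfg.intercept_log,
                asymptote_log=cfg.asymptote_log,
                log_rate=cfg.log_rate,
                re_corr=bad,  # not positive semidefinite
            )


class TestGeneration:
    def test_same_seed_identical(self):
        cfg = default_published_config(n_patients=50, seed=5)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.visits, b.visits)
        pd.testing.assert_frame_equal(a.latent, b.latent)

    def test_different_seed_differs(self):
        cfg = default_published_config(n_patients=50, seed=5)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg, seed=6)
        assert not a.visits["cd4_count"].equals(b.visits["cd4_count"])

    def test_substreams_stable_under_enlargement(self):
        # growing a cohort must not perturb previously generated patients
        small = generate_cohort(default_published_config(n_patients=100, seed=9))
        big = generate_cohort(default_published_config(n_patients=200, seed=9))
        first = small.visits["patient_id"].iloc[0]
        pd.testing.assert_frame_equal(
            small.visits[small.visits["patient_id"] == first].reset_index(drop=True),
            big.visits[big.visits["patient_id"] == first].reset_index(drop=True),
        )

    def test_degenerate_noise_reproduces_cell_curves(self):
        cfg = default_published_config(n_patients=40, seed=3)
        cfg.re_sd = (0.0, 0.0, 0.0)
        cfg.resid_sd = 0.0
        cohort = generate_cohort(cfg)
        for (sex, age), sub in cohort.visits.groupby(["sex", "age_group"], observed=True):
            p = c.TrajectoryParams(*cfg.cell_params(sex, age))
            expected = np.exp(c.log_cd4_trajectory(p, sub["visit_time_years"].to_numpy()))
            np.testing.assert_allclose(sub["cd4_count"].to_numpy(), expected, rtol=1e-10)

    def test_counts_positive_times_sorted_and_windowed(self, small_cohort):
        v = small_cohort.visits
        assert (v["cd4_count"] > 0).all()
        assert (v["visit_time_years"] >= -2 / 12 - 1e-12).all()
        for _, sub in v.groupby("patient_id"):
            assert sub["visit_time_years"].is_monotonic_increasing

    def test_latent_moments_match_config(self, large_cohort):
        # 10k patients: sample SDs and correlation of the latent parameters
        # within 3 Monte-Carlo SEs of the configured values
        lat = large_cohort.latent
        cfg_sd = {"intercept": 0.90, "asymptote": 0.51, "log_rate": 0.74}
        n = len(lat)
        for col, truth in cfg_sd.items():
            dev = lat.groupby(["sex", "age_group"], observed=True)[col].transform("mean")
            sd = (lat[col] - dev).std()
            mc_se = truth / np.sqrt(2 * n)
            assert abs(sd - truth) < 3 * mc_se, (col, sd)
        di = lat["intercept"] - lat.groupby(["sex", "age_group"], observed=True)["intercept"].transform("mean")
        da = lat["asymptote"] - lat.groupby(["sex", "age_group"], observed=True)["asymptote"].transform("mean")
        corr = np.corrcoef(di, da)[0, 1]
        assert abs(corr - 0.40) < 3 * (1 - 0.40**2) / np.sqrt(n)

    def test_observation_residual_sd_matches_config(self, large_cohort):
        lat = large_cohort.latent.set_index("patient_id")
        v = large_cohort.visits
        th = lat.loc[v["patient_id"]]
        f = th["asymptote"].to_numpy() - (
            th["asymptote"].to_numpy() - th["intercept"].to_numpy()
        ) * np.exp(-np.exp(th["log_rate"].to_numpy()) * v["visit_time_years"].to_numpy())
        resid = np.log(v["cd4_count"].to_numpy()) - f
        assert resid.std() == pytest.approx(0.58, abs=3 * 0.58 / np.sqrt(2 * len(resid)))


class TestVisitSchedule:
    def test_minimum_visits_enforced(self, large_cohort):
        counts = large_cohort.visits.groupby("patient_id").size()
        assert counts.min() >= 5

    def test_mean_visits_calibrated(self, large_cohort):
        counts = large_cohort.visits.groupby("patient_id").size()
        assert counts.mean() == pytest.approx(6.9, abs=0.1)

    def test_median_followup_calibrated(self, large_cohort):
        g = large_cohort.visits.groupby("patient_id")["visit_time_years"]
        span = g.max() - g.min()
        assert span.median() == pytest.approx(3.7, abs=0.1)

    def test_first_visit_in_baseline_window(self, large_cohort):
        first = large_cohort.visits.groupby("patient_id")["visit_time_years"].min()
        assert (first >= -2 / 12 - 1e-12).all()
        assert (first <= 3 / 12 + 1e-12).all()
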