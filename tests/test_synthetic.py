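"""Synthetic cohort generator: distributions, schedules, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogtraj.bentline import bentline_mean
from cogtraj.synthetic import (
    ClassParams,
    ConfigError,
    GeneratorConfig,
    Normal,
    generate_biomarkers,
    generate_cohort,
    generate_covariates,
    generate_longitudinal,
    sample_person_params,
    sample_visit_schedule,
)


def degenerate_config(**kw):
    cfg = GeneratorConfig.default(n_participants=5, seed=0)
    cfg.classes = (
        ClassParams(
            "only",
            1.0,
            alpha1=Normal(0.0, 0.0),
            alpha2=Normal(-0.02, 0.0),
            alpha3=Normal(-0.25, 0.0),
            tau=Normal(62.0, 0.0),
        ),
    )
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        cfg = GeneratorConfig.default()
        cfg.classes = tuple(
            ClassParams(c.name, c.weight * 0.5, c.alpha1, c.alpha2, c.alpha3, c.tau)
            for c in cfg.classes
        )
        with pytest.raises(ConfigError, match="sum to 1"):
            cfg.validate()

    def test_min_three_visits_enforced(self):
        cfg = GeneratorConfig.default()
        cfg.n_visits_min = 2
        with pytest.raises(ConfigError, match="n_visits_min"):
            cfg.validate()

    def test_age_bounds(self):
        cfg = GeneratorConfig.default()
        cfg.baseline_age_lower, cfg.baseline_age_upper = 74.0, 40.0
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_residual_sd_positive(self):
        cfg = GeneratorConfig.default()
        cfg.residual_sd = 0.0
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_unknown_class_label(self):
        cfg = GeneratorConfig.default()
        with pytest.raises(ConfigError, match="unknown class"):
            sample_person_params("no-such-class", cfg, np.random.default_rng(0))

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig.default(n_participants=12, seed=5)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = GeneratorConfig.from_yaml(p)
        assert back.n_participants == 12
        assert back.classes == cfg.classes
        assert back.residual_sd == cfg.residual_sd


class TestPersonParams:
    def test_degenerate_distribution_returns_means(self):
        cfg = degenerate_config()
        cfg.classes = (
            ClassParams(
                "only",
                1.0,
                alpha1=Normal(0.0, 0.0),
                alpha2=Normal(-0.02, 0.0),
                alpha3=Normal(-0.25, 0.0),
                tau=Normal(62.0, 0.0),
            ),
        )
        p = sample_person_params("only", cfg, np.random.default_rng(1))
        assert (p.alpha1, p.alpha2, p.alpha3, p.tau) == (0.0, -0.02, -0.25, 62.0)

    def test_sample_means_within_mc_error(self):
        cfg = GeneratorConfig.default()
        rng = np.random.default_rng(2)
        draws = np.array(
            [sample_person_params("steep", cfg, rng).as_array() for _ in range(10_000)]
        )
        cls = cfg.classes[0]
        for j, nv in enumerate((cls.alpha1, cls.alpha2, cls.alpha3, cls.tau)):
            se = nv.sd / np.sqrt(10_000)
            assert abs(draws[:, j].mean() - nv.mean) <= 3 * se + 1e-12

    def test_steep_post_slope_more_negative_than_minimal(self):
        cfg = GeneratorConfig.default()
        rng = np.random.default_rng(3)
        steep = np.array(
            [sample_person_params("steep", cfg, rng).alpha3 for _ in range(1000)]
        )
        minimal = np.array(
            [sample_person_params("minimal", cfg, rng).alpha3 for _ in range(1000)]
        )
        assert steep.mean() < minimal.mean()

    def test_correlated_draws_respect_correlation_sign(self):
        cfg = GeneratorConfig.default()
        corr = np.eye(4)
        corr[0, 3] = corr[3, 0] = 0.8
        cfg.param_correlation = corr
        rng = np.random.default_rng(4)
        draws = np.array(
            [sample_person_params("minimal", cfg, rng).as_array() for _ in range(4000)]
        )
        r = np.corrcoef(draws[:, 0], draws[:, 3])[0, 1]
        assert r > 0.6


class TestVisitSchedule:
    def test_no_jitter_schedule(self):
        cfg = degenerate_config()
        cfg.baseline_age_mean, cfg.baseline_age_sd = 58.0, 0.0
        cfg.visit_interval_mean, cfg.visit_interval_sd = 2.0, 0.0
        cfg.n_visits_min = cfg.n_visits_max = 4
        ages = sample_visit_schedule(cfg, np.random.default_rng(0))
        assert np.allclose(ages, [58.0, 60.0, 62.0, 64.0])

    def test_forced_visit_count(self):
        cfg = GeneratorConfig.default()
        cfg.n_visits_min = cfg.n_visits_max = 3
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert sample_visit_schedule(cfg, rng).size == 3

    def test_mean_follow_up_matches_interval_arithmetic(self):
        cfg = GeneratorConfig.default()
        rng = np.random.default_rng(2)
        fu, nv = [], []
        for _ in range(10_000):
            ages = sample_visit_schedule(cfg, rng)
            fu.append(ages[-1] - ages[0])
            nv.append(ages.size)
        expected = (np.mean(nv) - 1) * cfg.visit_interval_mean
        assert abs(np.mean(fu) - expected) <= 0.5

    def test_ages_strictly_increasing(self):
        cfg = GeneratorConfig.default()
        rng = np.random.default_rng(3)
        for _ in range(200):
            assert np.all(np.diff(sample_visit_schedule(cfg, rng)) > 0)


class TestLongitudinal:
    def test_noiseless_scores_equal_bentline(self):
        from cogtraj.bentline import PersonParams

        p = PersonParams(0.4, -0.02, -0.3, 63.0)
        ages = np.array([58.0, 60.0, 64.0, 68.0])
        s = generate_longitudinal(p, ages, 0.0, np.random.default_rng(0))
        assert np.allclose(s.scores, bentline_mean(ages, p))

    def test_flat_trajectory(self):
        from cogtraj.bentline import PersonParams

        s = generate_longitudinal(
            PersonParams(1.0, 0.0, 0.0, 60.0), [55, 58, 61], 0.0, np.random.default_rng(0)
        )
        assert np.allclose(s.scores, 1.0)

    def test_empirical_residual_sd(self):
        from cogtraj.bentline import PersonParams

        p = PersonParams(0.0, 0.0, 0.0, 60.0)
        rng = np.random.default_rng(1)
        ages = np.arange(50, 70, 0.1)
        pooled = np.concatenate(
            [generate_longitudinal(p, ages, 0.3, rng).scores for _ in range(250)]
        )
        assert abs(pooled.std() - 0.3) <= 0.003  # 50 000 visits, 1%

    def test_negative_residual_sd_rejected(self):
        from cogtraj.bentline import PersonParams

        with pytest.raises(ValueError):
            generate_longitudinal(
                PersonParams(0, 0, 0, 60), [58, 60, 62], -0.1, np.random.default_rng(0)
            )


class TestBiomarkersAndCovariates:
    def test_ticv_is_sum_of_tissues(self):
        cohort = generate_cohort(GeneratorConfig.default(n_participants=40, seed=8))
        b = cohort.biomarkers.dropna(subset=["gm"])
        assert np.allclose(b["ticv"], b[["gm", "wm", "csf"]].sum(axis=1))

    def test_zero_shifts_share_distribution(self):
        cfg = GeneratorConfig.default()
        cfg.biomarker_effects = {k: (0.0, 0.0, 0.0) for k in cfg.biomarker_effects}
        rng = np.random.default_rng(9)
        cov = {"cu_at_reference": True, "age_last": 65.0}
        steep = [generate_biomarkers("steep", cov, cfg, rng)["dvr"] for _ in range(2000)]
        minimal = [generate_biomarkers("minimal", cov, cfg, rng)["dvr"] for _ in range(2000)]
        assert abs(np.mean(steep) - np.mean(minimal)) < 0.02

    def test_steep_class_has_higher_dvr(self):
        cfg = GeneratorConfig.default()
        rng = np.random.default_rng(10)
        cov = {"cu_at_reference": True, "age_last": 65.0}
        steep = [generate_biomarkers("steep", cov, cfg, rng)["dvr"] for _ in range(5000)]
        minimal = [generate_biomarkers("minimal", cov, cfg, rng)["dvr"] for _ in range(5000)]
        assert np.mean(steep) > np.mean(minimal)

    def test_prevalence_extremes(self):
        cfg = GeneratorConfig.default()
        cfg.covariate_prevalences = dict(cfg.covariate_prevalences)
        cfg.covariate_prevalences["always"] = (1.0, 1.0, 1.0)
        cfg.covariate_prevalences["never"] = (0.0, 0.0, 0.0)
        rng = np.random.default_rng(11)
        recs = [generate_covariates("minimal", cfg, rng) for _ in range(100)]
        assert all(r["always"] for r in recs)
        assert not any(r["never"] for r in recs)

    def test_marginal_female_fraction(self):
        cfg = GeneratorConfig.default()
        rng = np.random.default_rng(12)
        weights = [c.weight for c in cfg.classes]
        per_class = cfg.covariate_prevalences["female"]
        expected = float(np.dot(weights, per_class))
        ks = rng.choice(3, size=10_000, p=weights)
        frac = np.mean(
            [generate_covariates(int(k), cfg, rng)["female"] for k in ks]
        )
        assert abs(frac - expected) <= 0.02


class TestCohortAssembly:
    def test_bit_reproducible(self):
        a = generate_cohort(GeneratorConfig.default(n_participants=30, seed=21))
        b = generate_cohort(GeneratorConfig.default(n_participants=30, seed=21))
        pd.testing.assert_frame_equal(a.long, b.long)
        pd.testing.assert_frame_equal(a.biomarkers, b.biomarkers)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_prefix_stable_when_growing_n(self):
        small = generate_cohort(GeneratorConfig.default(n_participants=20, seed=22))
        big = generate_cohort(GeneratorConfig.default(n_participants=40, seed=22))
        pd.testing.assert_frame_equal(
            small.long, big.long[big.long.participant_id.isin(small.long.participant_id)].reset_index(drop=True),
        )

    def test_every_participant_fully_described(self, small_cohort):
        ids = set(small_cohort.long["participant_id"])
        assert ids == set(small_cohort.truth["participant_id"])
        assert ids == set(small_cohort.biomarkers["participant_id"])
        assert ids == set(small_cohort.covariates["participant_id"])

    def test_min_visits_and_monotone_ages(self, small_cohort):
        for _, grp in small_cohort.long.groupby("participant_id"):
            assert len(grp) >= 3
            assert np.all(np.diff(grp["visit_age_years"]) > 0)

    def test_class_mixture_chi2(self):
        cohort = generate_cohort(GeneratorConfig.default(n_participants=50_000, seed=23))
        counts = cohort.truth["class"].value_counts()
        cfg = GeneratorConfig.default()
        expected = {c.name: c.weight * 50_000 for c in cfg.classes}
        chi2 = sum(
            (counts[k] - expected[k]) ** 2 / expected[k] for k in expected
        )
        # not rejected at alpha = 0.01, df = 2
        assert chi2 < stats.chi2.ppf(0.99, df=2)

    def test_unobserved_cp_monotone_in_spread_and_preset(self):
        from dataclasses import replace as drep

        def unobserved_fraction(cfg):
            cohort = generate_cohort(cfg)
            first_last = cohort.long.groupby("participant_id")["visit_age_years"].agg(
                ["first", "last"]
            )
            t = cohort.truth.set_index("participant_id")["tau"]
            out = (t < first_last["first"]) | (t > first_last["last"])
            return out.mean()

        fracs = []
        for sd in (1.0, 5.0, 12.0):
            cfg = GeneratorConfig.default(n_participants=800, seed=24)
            cfg.classes = tuple(
                drep(c, tau=type(c.tau)(c.tau.mean, sd)) for c in cfg.classes
            )
            fracs.append(unobserved_fraction(cfg))
        assert fracs[0] < fracs[1] < fracs[2]

        preset = GeneratorConfig.mostly_unobserved_cp(n_participants=2000, seed=25)
        assert unobserved_fraction(preset) >= 0.70

    def test_write_csvs(self, tmp_path, small_cohort):
        paths = small_cohort.write_csvs(tmp_path)
        assert set(paths) == {"cohort_long", "truth", "biomarkers", "covariates"}
        for p in paths.values():
            assert p.exists()
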