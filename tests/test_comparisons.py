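"""Covariate recodes, omnibus/post-hoc battery, effect sizes, lsmeans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cogtraj.comparisons import (
    adjusted_group_means,
    bh_adjust,
    cliffs_delta,
    compare_groups,
    cramers_v,
    depression_flag,
    libra_tertiles,
    omnibus_test,
    pairwise_posthoc,
    recode_bmi,
    recode_memory,
    recode_polypharmacy,
    recode_srh,
    recode_whr,
    welch_anova,
)


class TestRecodes:
    @pytest.mark.parametrize(
        "bmi, expected",
        [
            (17.0, "underweight"),
            (18.5, "normal"),
            (24.9, "normal"),
            (25.0, "overweight"),
            (29.9, "overweight"),
            (30.0, "obese"),
            (45.0, "obese"),
        ],
    )
    def test_bmi(self, bmi, expected):
        assert recode_bmi(bmi) == expected

    @pytest.mark.parametrize(
        "whr, sex, expected",
        [
            (0.80, "female", "low"),
            (0.83, "female", "moderate"),
            (0.86, "female", "high"),
            (0.95, "male", "low"),
            (0.97, "male", "moderate"),
            (1.0, "male", "high"),  # overlap resolved in favour of high
            (1.2, "male", "high"),
        ],
    )
    def test_whr(self, whr, sex, expected):
        assert recode_whr(whr, sex) == expected

    def test_whr_unknown_sex(self):
        with pytest.raises(ValueError):
            recode_whr(0.9, "unknown")

    @pytest.mark.parametrize(
        "rx, expected",
        [(0, "no_polypharmacy"), (4, "no_polypharmacy"), (5, "polypharmacy"),
         (9, "polypharmacy"), (10, "hyperpolypharmacy"), (15, "hyperpolypharmacy")],
    )
    def test_polypharmacy(self, rx, expected):
        assert recode_polypharmacy(rx) == expected

    @pytest.mark.parametrize(
        "srh, expected", [(1, "poor"), (2, "poor"), (3, "good"), (4, "excellent"), (5, "excellent")]
    )
    def test_srh(self, srh, expected):
        assert recode_srh(srh) == expected

    @pytest.mark.parametrize(
        "rating, expected",
        [(1, "major_problems"), (3, "major_problems"), (4, "neutral"), (5, "no_problems"), (7, "no_problems")],
    )
    def test_memory(self, rating, expected):
        assert recode_memory(rating) == expected

    def test_out_of_range_rejected(self):
        for fn, bad in ((recode_srh, 0), (recode_srh, 6), (recode_memory, 8), (recode_bmi, -1), (recode_polypharmacy, -1)):
            with pytest.raises(ValueError):
                fn(bad)

    @given(st.floats(10, 60))
    @settings(max_examples=200, deadline=None)
    def test_bmi_total_and_exclusive(self, bmi):
        """Every positive BMI maps to exactly one category (no gaps/overlap)."""
        assert recode_bmi(bmi) in {"underweight", "normal", "overweight", "obese"}

    @given(st.floats(0.5, 1.5), st.sampled_from(["female", "male"]))
    @settings(max_examples=200, deadline=None)
    def test_whr_total(self, whr, sex):
        assert recode_whr(whr, sex) in {"low", "moderate", "high"}

    def test_depression_flag(self):
        assert depression_flag(True, 2) is True  # self-report dominates
        assert depression_flag(False, 30) is False
        assert depression_flag(None, 16) is True  # CES-D boundary
        assert depression_flag(None, 15) is False
        assert depression_flag(None, None) is None

    def test_libra_tertiles_1_to_9(self):
        cats, cuts = libra_tertiles(list(range(1, 10)))
        assert cuts[0] == pytest.approx(11 / 3)
        assert cuts[1] == pytest.approx(19 / 3)
        assert list(cats.value_counts()[["low", "moderate", "high"]]) == [3, 3, 3]

    def test_libra_degenerate_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            libra_tertiles([2.0, 2.0, 2.0, 2.0])

    def test_libra_too_few(self):
        with pytest.raises(ValueError):
            libra_tertiles([1.0, 2.0])


class TestEffectSizes:
    def test_cramers_v_perfect_association(self):
        assert cramers_v([[10, 0], [0, 10]]) == pytest.approx(1.0)

    def test_cramers_v_independence(self):
        assert cramers_v([[5, 5], [5, 5]]) == pytest.approx(0.0)

    def test_cramers_v_oracle(self, rng):
        for _ in range(100):
            t = rng.integers(1, 30, size=(3, 4))
            chi2 = stats.chi2_contingency(t, correction=False)[0]
            oracle = np.sqrt(chi2 / (t.sum() * (min(t.shape) - 1)))
            assert cramers_v(t) == pytest.approx(oracle, abs=1e-12)

    def test_cramers_v_permutation_invariance(self, rng):
        t = rng.integers(1, 20, size=(3, 3))
        v = cramers_v(t)
        assert cramers_v(t[::-1]) == pytest.approx(v)
        assert cramers_v(t[:, ::-1]) == pytest.approx(v)

    def test_cramers_v_zero_margin_dropped(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            v = cramers_v([[10, 0, 5], [3, 0, 2]])
        assert 0 <= v <= 1

    def test_cliffs_delta_examples(self):
        assert cliffs_delta([1, 2, 3], [1, 2, 3]) == 0.0
        assert cliffs_delta([4, 5], [1, 2]) == 1.0
        # enumeration: 1 win (3>2), 6 losses, 2 ties over 9 cross-pairs
        assert cliffs_delta([1, 2, 3], [2, 3, 4]) == pytest.approx(-5 / 9)

    def test_cliffs_delta_enumeration_oracle(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 15))
            b = rng.normal(size=rng.integers(2, 15))
            gt = sum(1 for x in a for y in b if x > y)
            lt = sum(1 for x in a for y in b if x < y)
            oracle = (gt - lt) / (len(a) * len(b))
            assert cliffs_delta(a, b) == pytest.approx(oracle, abs=1e-12)

    @given(
        st.lists(st.integers(-20, 20), min_size=2, max_size=15),
        st.lists(st.integers(-20, 20), min_size=2, max_size=15),
    )
    @settings(max_examples=100, deadline=None)
    def test_cliffs_delta_antisymmetry_and_monotone_invariance(self, a, b):
        d = cliffs_delta(a, b)
        assert cliffs_delta(b, a) == pytest.approx(-d, abs=1e-12)
        f = lambda x: np.exp(np.asarray(x, dtype=float) / 3)  # strictly monotone
        assert cliffs_delta(f(a), f(b)) == pytest.approx(d, abs=1e-12)


class TestBH:
    def test_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_matches_step_up_oracle(self, rng):
        def oracle(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                rank = m - rank_from_top
                running = min(running, p[idx] * m / rank)
                adj[idx] = running
            return adj

        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 20))
            assert np.max(np.abs(bh_adjust(p) - oracle(p))) <= 1e-12

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        p = rng.uniform(0, 1, 25)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestOmnibus:
    def test_chi_square_hand_value(self):
        # 2x2 table ((10,0),(0,10)): uncorrected chi2 = 20
        res = omnibus_test(
            {"g1": ["a"] * 10, "g2": ["b"] * 10}, "categorical", variable="v"
        )
        assert res.test_used in ("chi_square", "fisher_exact")
        assert res.p_omnibus < 0.001

    def test_chi_square_statistic_uncorrected(self):
        vals = {"g1": ["a"] * 30 + ["b"] * 10, "g2": ["a"] * 10 + ["b"] * 30}
        res = omnibus_test(vals, "categorical", variable="v")
        assert res.test_used == "chi_square"
        t = np.array([[30, 10], [10, 30]])
        chi2 = stats.chi2_contingency(t, correction=False)[0]
        assert res.statistic == pytest.approx(chi2)

    def test_identical_groups_kruskal_zero(self):
        vals = {"g1": [1.0, 2.0, 3.0, 4.0], "g2": [1.0, 2.0, 3.0, 4.0]}
        res = omnibus_test(vals, "continuous", policy="kruskal_wallis", variable="v")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_constant_variable_untestable(self):
        res = omnibus_test(
            {"g1": [2.0, 2.0, 2.0], "g2": [2.0, 2.0, 2.0]},
            "continuous",
            policy="kruskal_wallis",
            variable="v",
        )
        assert res.test_used == "untestable"

    def test_welch_matches_textbook_formula(self, rng):
        for _ in range(50):
            groups = [rng.normal(rng.normal(), rng.uniform(0.5, 2), rng.integers(5, 30)) for _ in range(3)]
            f, df1, df2, p = welch_anova(groups)
            # textbook Welch: weights w = n/s^2
            n = np.array([len(g) for g in groups])
            m = np.array([g.mean() for g in groups])
            v = np.array([g.var(ddof=1) for g in groups])
            w = n / v
            mw = (w * m).sum() / w.sum()
            k = len(groups)
            num = ((w * (m - mw) ** 2).sum()) / (k - 1)
            lam = (3 / (k**2 - 1)) * ((1 / (n - 1)) * (1 - w / w.sum()) ** 2).sum()
            F = num / (1 + 2 * lam * (k - 2) / 3)
            df2_o = 1 / lam
            assert f == pytest.approx(F, abs=1e-8, rel=1e-8)
            assert df1 == k - 1
            assert df2 == pytest.approx(df2_o, rel=1e-8)
            p_o = stats.f.sf(F, k - 1, df2_o)
            assert p == pytest.approx(p_o, rel=1e-8)

    def test_welch_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        groups = [rng.normal(0, 1, 20), rng.normal(0.5, 2, 25), rng.normal(1, 0.5, 15)]
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [20, 25, 15]),
            }
        )
        pg = pingouin.welch_anova(data=df, dv="y", between="g")
        f, df1, df2, p = welch_anova(groups)
        assert f == pytest.approx(float(pg["F"].iloc[0]), rel=1e-6)
        assert p == pytest.approx(float(pg["p_unc"].iloc[0]), rel=1e-6)

    def test_welch_approaches_classical_under_homoscedasticity(self):
        """With exactly equal group variances and sizes the Welch statistic
        equals the classical F divided by its small-sample correction factor
        1 + 2*lambda*(k-2)/3, approaching the classical F as n grows."""
        g = np.random.default_rng(3)
        k, n = 3, 40
        groups = []
        for shift in (0.0, 0.5, 1.0):
            x = g.normal(0, 1, n)
            groups.append((x - x.mean()) / x.std(ddof=1) + shift)
        f, df1, df2, p = welch_anova(groups)
        f_classic, _ = stats.f_oneway(*groups)
        lam = (3 / (k**2 - 1)) * k * (1 / (n - 1)) * (1 - 1 / k) ** 2
        assert f == pytest.approx(f_classic / (1 + 2 * lam * (k - 2) / 3), abs=1e-8)
        assert f == pytest.approx(f_classic, rel=0.02)  # asymptotic agreement

    def test_fisher_on_sparse_2x2(self):
        vals = {"g1": ["a"] * 3 + ["b"] * 1, "g2": ["a"] * 1 + ["b"] * 3}
        res = omnibus_test(vals, "categorical", variable="v")
        assert res.test_used == "fisher_exact"
        _, p = stats.fisher_exact([[3, 1], [1, 3]])
        assert res.p_omnibus == pytest.approx(p)

    def test_mc_fisher_seeded_and_reproducible(self):
        vals = {
            "g1": ["a"] * 3 + ["b"] * 1 + ["c"] * 2,
            "g2": ["a"] * 1 + ["b"] * 3 + ["c"] * 1,
            "g3": ["a"] * 2 + ["b"] * 2 + ["c"] * 4,
        }
        r1 = omnibus_test(vals, "categorical", variable="v", seed=5)
        r2 = omnibus_test(vals, "categorical", variable="v", seed=5)
        assert r1.test_used == "fisher_exact_mc"
        assert r1.p_omnibus == r2.p_omnibus


class TestPairwise:
    def test_skipped_when_omnibus_ns(self):
        vals = {"g1": [1.0, 2.0, 3.0, 4.0], "g2": [1.1, 2.1, 2.9, 4.2]}
        res = omnibus_test(vals, "continuous", policy="kruskal_wallis", variable="v")
        out = pairwise_posthoc(vals, res)
        assert out == []
        assert "skipped" in res.notes

    def test_all_pairs_with_bh(self, rng):
        vals = {
            "a": rng.normal(0, 1, 30),
            "b": rng.normal(1.5, 1, 30),
            "c": rng.normal(3.0, 1, 30),
        }
        res = omnibus_test(vals, "continuous", policy="kruskal_wallis", variable="v")
        out = pairwise_posthoc(vals, res, q=0.05)
        assert len(out) == 3
        for pr in out:
            assert pr.p_adj >= pr.p_raw - 1e-15
            assert pr.significant == (pr.p_adj < 0.05)
            assert pr.effect_name == "cliffs_delta"


class TestAdjustedMeans:
    def test_null_adjustment_limit(self, rng):
        n = 3000
        g = rng.choice(["a", "b"], n)
        age = rng.normal(60, 5, n)
        sex = rng.choice(["female", "male"], n)
        y = np.where(g == "a", 0.0, 1.0) + rng.normal(0, 0.5, n)
        means, _ = adjusted_group_means(y, g, age, sex)
        raw = pd.Series(y).groupby(pd.Series(g)).mean()
        for _, row in means.iterrows():
            assert row["lsmean"] == pytest.approx(raw[row["group"]], abs=0.05)

    def test_noiseless_group_effects_recovered(self, rng):
        n = 200
        g = rng.choice(["a", "b", "c"], n)
        age = rng.normal(60, 5, n)
        sex = rng.choice(["female", "male"], n)
        effect = {"a": 0.0, "b": 1.0, "c": 2.0}
        y = np.array([effect[x] for x in g]) + 0.1 * (age - age.mean())
        means, contrasts = adjusted_group_means(y, g, age, sex)
        got = dict(zip(means["group"], means["lsmean"]))
        assert got["b"] - got["a"] == pytest.approx(1.0, abs=1e-8)
        assert got["c"] - got["a"] == pytest.approx(2.0, abs=1e-8)

    def test_equal_groups_contrast_zero(self, rng):
        n = 100
        g = np.repeat(["a", "b"], n // 2)
        age = rng.normal(60, 5, n)
        sex = rng.choice(["female", "male"], n)
        y = 0.2 * (age - 60)  # no group effect at all
        means, contrasts = adjusted_group_means(y, g, age, sex)
        got = dict(zip(means["group"], means["lsmean"]))
        assert got["a"] - got["b"] == pytest.approx(0.0, abs=1e-8)

    def test_collinear_design_rejected(self):
        y = [1.0, 2.0, 3.0, 4.0]
        g = ["a", "a", "b", "b"]
        age = [60.0, 60.0, 60.0, 60.0]  # constant age -> collinear with intercept
        sex = ["female", "female", "female", "female"]
        with pytest.raises(ValueError, match="collinear"):
            adjusted_group_means(y, g, age, sex)


class TestBattery:
    def test_compare_groups_family_wide_bh(self, rng):
        n = 120
        df = pd.DataFrame(
            {
                "grp": rng.choice(["s", "i", "m"], n),
                "x": rng.normal(0, 1, n),
                "flag": rng.random(n) < 0.5,
            }
        )
        df.loc[df["grp"] == "s", "x"] += 2.0
        results = compare_groups(
            df, "grp", {"x": ("continuous", "kruskal_wallis"), "flag": ("categorical", None)},
            seed=0,
        )
        by_var = {r.variable: r for r in results}
        assert by_var["x"].p_omnibus < 0.05
        assert len(by_var["x"].pairwise) == 3
        for pr in by_var["x"].pairwise:
            assert pr.p_adj is not None
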