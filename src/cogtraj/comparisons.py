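"""Health-covariate recoding and the trajectory-group comparison battery.

Covariates are recoded into standard epidemiological categories (BMI class,
sex-specific waist-to-hip-ratio class, polypharmacy bands, self-rated health
and self-rated memory bands, a depression flag combining self-report with
CES-D >= 16, sample tertiles of a lifestyle risk score).  Variables are then
compared across trajectory groups with an omnibus test chosen by type
(chi-square or Fisher's exact for categorical; Welch's heteroscedastic ANOVA
or Kruskal-Wallis for continuous), significant omnibus tests are followed by
pairwise post-hocs of the same family, p-values are Benjamini-Hochberg
corrected across the declared family, and effect sizes are Cramer's V
(categorical) or Cliff's delta (continuous).  Age/sex-adjusted group means
(least-squares means) are available as a sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.oneway import anova_oneway

__all__ = [
    "ComparisonResult",
    "PairwiseResult",
    "recode_bmi",
    "recode_whr",
    "recode_polypharmacy",
    "recode_srh",
    "recode_memory",
    "depression_flag",
    "libra_tertiles",
    "omnibus_test",
    "pairwise_posthoc",
    "bh_adjust",
    "cramers_v",
    "cliffs_delta",
    "welch_anova",
    "adjusted_group_means",
    "compare_groups",
    "recode_covariates",
]


# ---------------------------------------------------------------------------
# recoding
# ---------------------------------------------------------------------------


def recode_bmi(bmi: float) -> str:
    """BMI class on half-open bins: <18.5 / [18.5,25) / [25,30) / >=30."""
    if not bmi > 0:
        raise ValueError("BMI must be positive")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def recode_whr(whr: float, sex: str) -> str:
    """Sex-specific waist-to-hip-ratio class.

    Women: <=0.80 low, (0.80, 0.86) moderate, >=0.86 high.
    Men: <=0.95 low, (0.95, 1.0) moderate, >=1.0 high (the printed bands
    overlap at 1.0; the high band takes precedence).
    """
    if not whr > 0:
        raise ValueError("WHR must be positive")
    if sex == "female":
        low, high = 0.80, 0.86
    elif sex == "male":
        low, high = 0.95, 1.00
    else:
        raise ValueError(f"unknown sex code {sex!r}")
    if whr <= low:
        return "low"
    if whr >= high:
        return "high"
    return "moderate"


def recode_polypharmacy(rx_count: int) -> str:
    """0-4 none / 5-9 polypharmacy / >=10 hyperpolypharmacy."""
    if rx_count < 0:
        raise ValueError("prescription count must be >= 0")
    if rx_count <= 4:
        return "no_polypharmacy"
    if rx_count <= 9:
        return "polypharmacy"
    return "hyperpolypharmacy"


def recode_srh(srh: int) -> str:
    """Self-rated health Likert 1-5: 1-2 poor, 3 good, 4-5 excellent."""
    if not 1 <= srh <= 5:
        raise ValueError("self-rated health must be in 1..5")
    if srh <= 2:
        return "poor"
    if srh == 3:
        return "good"
    return "excellent"


def recode_memory(memory_rating: int) -> str:
    """Self-rated memory Likert 1-7: 1-3 major, 4 neutral, 5-7 none."""
    if not 1 <= memory_rating <= 7:
        raise ValueError("memory rating must be in 1..7")
    if memory_rating <= 3:
        return "major_problems"
    if memory_rating == 4:
        return "neutral"
    return "no_problems"


def depression_flag(self_reported_depression, cesd):
    """Self-report dominates; otherwise CES-D >= 16; both missing -> NA."""
    sr_missing = self_reported_depression is None or (
        isinstance(self_reported_depression, float) and np.isnan(self_reported_depression)
    )
    if not sr_missing:
        return bool(self_reported_depression)
    cesd_missing = cesd is None or (isinstance(cesd, float) and np.isnan(cesd))
    if cesd_missing:
        return None
    return bool(cesd >= 16)


def libra_tertiles(scores) -> tuple[pd.Series, tuple]:
    """Sample-tertile risk groups (type-7 quantile cut points).

    Returns (categories low/moderate/high, (lower_cut, upper_cut)).  The cut
    points are data-dependent; all-equal inputs yield a single degenerate
    group, flagged with a warning.
    """
    s = pd.Series(scores, dtype=float)
    vals = s.dropna().to_numpy()
    if vals.size < 3:
        raise ValueError("need at least 3 non-missing scores for tertiles")
    lo, hi = np.quantile(vals, [1 / 3, 2 / 3])  # numpy default = type-7
    if lo == hi:
        warnings.warn("degenerate tertiles: all cut points equal")
    cats = pd.Series(index=s.index, dtype=object)
    cats[s <= lo] = "low"
    cats[(s > lo) & (s <= hi)] = "moderate"
    cats[s > hi] = "high"
    cats[s.isna()] = None
    return cats, (float(lo), float(hi))


def recode_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Apply every category recode to a covariate table (new columns)."""
    out = df.copy()
    out["bmi_cat"] = out["bmi"].map(recode_bmi)
    out["whr_cat"] = [recode_whr(w, s) for w, s in zip(out["whr"], out["sex"])]
    out["rx_cat"] = out["rx_count"].map(recode_polypharmacy)
    out["srh_cat"] = out["srh"].map(recode_srh)
    out["memory_cat"] = out["memory_rating"].map(recode_memory)
    out["depressed"] = [
        depression_flag(a, b)
        for a, b in zip(out.get("self_reported_depression"), out.get("cesd"))
    ]
    if "libra" in out.columns:
        cats, cuts = libra_tertiles(out["libra"])
        out["libra_cat"] = cats
        out.attrs["libra_cuts"] = cuts
    return out


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------


def cramers_v(table) -> float:
    """Cramer's V = sqrt(chi2 / (n (min(r,c) - 1))), chi2 uncorrected.

    Zero-margin rows/columns are dropped with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    rz = t.sum(1) > 0
    cz = t.sum(0) > 0
    if not (rz.all() and cz.all()):
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        t = t[rz][:, cz]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping zero margins")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    chi2 = stats.chi2_contingency(t, correction=False)[0]
    return float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))


def cliffs_delta(a, b) -> float:
    """Cliff's dominance delta: (#{a>b} - #{a<b}) / (nA nB), ties -> 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = a[:, None] - b[None, :]
    return float((np.sign(diff)).mean())


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# omnibus and pairwise tests
# ---------------------------------------------------------------------------


@dataclass
class PairwiseResult:
    pair: tuple
    statistic: float
    p_raw: float
    p_adj: float | None = None
    significant: bool | None = None
    effect_size: float | None = None
    effect_name: str | None = None


@dataclass
class ComparisonResult:
    variable: str
    test_used: str
    statistic: float
    df: object
    p_omnibus: float
    pairwise: list = field(default_factory=list)
    effect_size: float | None = None
    effect_name: str | None = None
    adjusted: pd.DataFrame | None = None
    notes: str = ""


def welch_anova(groups) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA: (F, df1, df2, p)."""
    res = anova_oneway(list(groups), use_var="unequal", welch_correction=True)
    return float(res.statistic), float(res.df_num), float(res.df_denom), float(res.pvalue)


def _contingency(values_by_group: dict) -> pd.DataFrame:
    labels, values = [], []
    for g, vals in values_by_group.items():
        for v in vals:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            labels.append(g)
            values.append(v)
    return pd.crosstab(pd.Series(labels, name="group"), pd.Series(values, name="value"))


def _mc_fisher(table: np.ndarray, seed, n_mc: int = 10000) -> tuple[float, float]:
    """Seeded Monte-Carlo conditional test for r x c tables.

    Permutes cell memberships holding margins approximately fixed via label
    permutation and compares the chi-square statistic; returns (chi2, p).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(table, dtype=int)
    obs_chi2 = stats.chi2_contingency(t, correction=False)[0]
    rows = np.repeat(np.arange(t.shape[0]), t.sum(1))
    cols = np.concatenate([np.repeat(np.arange(t.shape[1]), r) for r in t])
    # margins are fixed under permutation, so the expected table is constant
    n = t.sum()
    expected = np.outer(t.sum(1), t.sum(0)) / n
    count = 0
    sim = np.zeros_like(t)
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        sim[:] = 0
        np.add.at(sim, (rows, perm), 1)
        chi2 = float(((sim - expected) ** 2 / expected).sum())
        if chi2 >= obs_chi2 - 1e-12:
            count += 1
    return float(obs_chi2), (count + 1) / (n_mc + 1)


def omnibus_test(
    values_by_group: dict,
    variable_type: str,
    policy: str = "kruskal_wallis",
    variable: str = "",
    seed=None,
) -> ComparisonResult:
    """Omnibus group comparison for one variable.

    Categorical: chi-square test of independence, switching to Fisher's
    exact (2x2) or a seeded Monte-Carlo conditional test (r x c) when any
    expected cell is < 5.  Continuous: Welch ANOVA or Kruskal-Wallis per
    ``policy``.  A variable constant across all groups is untestable.
    """
    groups = {g: np.asarray(v) for g, v in values_by_group.items()}
    if len(groups) < 2 or any(len(v) == 0 for v in groups.values()):
        raise ValueError("need >= 2 non-empty groups")

    if variable_type == "categorical":
        table = _contingency(values_by_group)
        if table.shape[1] < 2:
            return ComparisonResult(variable, "untestable", np.nan, None, np.nan,
                                    notes="constant across groups")
        t = table.to_numpy()
        chi2, p, dof, expected = stats.chi2_contingency(t, correction=False)
        if (expected < 5).any():
            if t.shape == (2, 2):
                _, p = stats.fisher_exact(t)
                return ComparisonResult(
                    variable, "fisher_exact", np.nan, None, float(p),
                    effect_size=cramers_v(t), effect_name="cramers_v",
                )
            chi2, p = _mc_fisher(t, seed)
            return ComparisonResult(
                variable, "fisher_exact_mc", chi2, None, float(p),
                effect_size=cramers_v(t), effect_name="cramers_v",
                notes="Monte-Carlo conditional test (seeded)",
            )
        return ComparisonResult(
            variable, "chi_square", float(chi2), int(dof), float(p),
            effect_size=cramers_v(t), effect_name="cramers_v",
        )

    if variable_type != "continuous":
        raise ValueError(f"unknown variable_type {variable_type!r}")
    arrs = [np.asarray(v, dtype=float) for v in groups.values()]
    arrs = [a[np.isfinite(a)] for a in arrs]
    if any(a.size == 0 for a in arrs):
        raise ValueError("a group has no finite values")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return ComparisonResult(variable, "untestable", np.nan, None, np.nan,
                                notes="constant across groups")
    if policy == "welch_anova":
        f, df1, df2, p = welch_anova(arrs)
        return ComparisonResult(variable, "welch_anova", f, (df1, df2), p)
    if policy == "kruskal_wallis":
        try:
            h, p = stats.kruskal(*arrs)
        except ValueError:  # all values identical
            return ComparisonResult(variable, "untestable", np.nan, None, np.nan,
                                    notes="constant across groups")
        return ComparisonResult(variable, "kruskal_wallis", float(h), len(arrs) - 1, float(p))
    raise ValueError(f"unknown continuous policy {policy!r}")


def _pair_test(a, b, test_used: str, seed=None) -> tuple[float, float]:
    """Two-group test in the same family as the omnibus."""
    if test_used in ("chi_square", "fisher_exact", "fisher_exact_mc"):
        table = _contingency({"a": a, "b": b}).to_numpy()
        if table.shape[1] < 2:
            return np.nan, 1.0
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        if (expected < 5).any():
            if table.shape == (2, 2):
                _, p = stats.fisher_exact(table)
                return np.nan, float(p)
            return _mc_fisher(table, seed)
        return float(chi2), float(p)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if test_used == "welch_anova":
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    if test_used == "kruskal_wallis":
        h, p = stats.kruskal(a, b)
        return float(h), float(p)
    raise ValueError(f"no pairwise form for test {test_used!r}")


def pairwise_posthoc(
    values_by_group: dict,
    omnibus: ComparisonResult,
    alpha: float = 0.05,
    q: float = 0.05,
    seed=None,
    adjust: bool = True,
) -> list[PairwiseResult]:
    """All-pairs post-hoc tests in the omnibus family.

    Run only when the omnibus p is below ``alpha`` (otherwise an empty list
    is returned and the skip is recorded on the omnibus result).  With
    ``adjust=True`` BH correction is applied within this variable's pairs;
    set ``adjust=False`` to collect raw p-values into a wider family first.
    """
    if not (omnibus.p_omnibus < alpha):
        omnibus.notes = (omnibus.notes + "; " if omnibus.notes else "") + "pairwise skipped (omnibus ns)"
        return []
    names = list(values_by_group)
    out = []
    categorical = omnibus.test_used in ("chi_square", "fisher_exact", "fisher_exact_mc")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for (i, gi), (j, gj) in (
        ((i, names[i]), (j, names[j]))
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ):
        stat, p = _pair_test(
            values_by_group[gi], values_by_group[gj], omnibus.test_used,
            seed=ss.spawn(1)[0],
        )
        pr = PairwiseResult((gi, gj), stat, p)
        if categorical:
            table = _contingency({gi: values_by_group[gi], gj: values_by_group[gj]}).to_numpy()
            try:
                pr.effect_size = cramers_v(table)
                pr.effect_name = "cramers_v"
            except ValueError:
                pass
        else:
            a = np.asarray(values_by_group[gi], dtype=float)
            b = np.asarray(values_by_group[gj], dtype=float)
            pr.effect_size = cliffs_delta(a[np.isfinite(a)], b[np.isfinite(b)])
            pr.effect_name = "cliffs_delta"
        out.append(pr)
    if adjust and out:
        padj = bh_adjust([r.p_raw for r in out])
        for r, pa in zip(out, padj):
            r.p_adj = float(pa)
            r.significant = bool(pa < q)
    omnibus.pairwise = out
    return out


# ---------------------------------------------------------------------------
# age/sex-adjusted (least-squares) group means
# ---------------------------------------------------------------------------


def adjusted_group_means(
    outcome, group, age, sex, q: float = 0.05
) -> tuple[pd.DataFrame, list[PairwiseResult]]:
    """Least-squares group means of a linear model outcome ~ group + age + sex.

    Adjusted means are evaluated at the sample-mean age and the sample sex
    mix; pairwise contrasts are t-tests on the model coefficients with BH
    correction.  Returns (per-group frame with lsmean and SE, contrasts).
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(outcome, dtype=float),
            "g": np.asarray(group),
            "age": np.asarray(age, dtype=float),
            "sex": np.asarray(sex),
        }
    ).dropna()
    if df.empty:
        raise ValueError("no complete cases")
    levels = sorted(df["g"].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    sex_num = (
        df["sex"].astype(float)
        if np.issubdtype(df["sex"].dtype, np.number)
        else (df["sex"] == "female").astype(float)
    )
    dummies = np.column_stack([(df["g"] == lv).to_numpy(float) for lv in levels[1:]])
    X = np.column_stack([np.ones(len(df)), dummies, df["age"].to_numpy(), sex_num])
    names = ["intercept"] + [f"g[{lv}]" for lv in levels[1:]] + ["age", "sex"]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"collinear design matrix (columns: {names})")
    import statsmodels.api as sm

    fit = sm.OLS(df["y"].to_numpy(), X).fit()
    cov = fit.cov_params()
    mean_age = df["age"].mean()
    mean_sex = sex_num.mean()

    def rowvec(level):
        d = [1.0] + [1.0 if lv == level else 0.0 for lv in levels[1:]] + [mean_age, mean_sex]
        return np.asarray(d)

    rows = []
    for lv in levels:
        x = rowvec(lv)
        est = float(x @ fit.params)
        se = float(np.sqrt(x @ cov @ x))
        rows.append({"group": lv, "lsmean": est, "se": se, "n": int((df["g"] == lv).sum())})
    means = pd.DataFrame(rows)

    contrasts = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            L = rowvec(levels[i]) - rowvec(levels[j])
            est = float(L @ fit.params)
            se = float(np.sqrt(L @ cov @ L))
            if se == 0:
                tstat, p = np.nan, 1.0
            else:
                tstat = est / se
                p = 2 * stats.t.sf(abs(tstat), fit.df_resid)
            contrasts.append(
                PairwiseResult((levels[i], levels[j]), float(tstat), float(p))
            )
    padj = bh_adjust([c.p_raw for c in contrasts])
    for c, pa in zip(contrasts, padj):
        c.p_adj = float(pa)
        c.significant = bool(pa < q)
    return means, contrasts


# ---------------------------------------------------------------------------
# battery driver
# ---------------------------------------------------------------------------


def compare_groups(
    data: pd.DataFrame,
    group_col: str,
    variables: dict,
    q: float = 0.05,
    alpha: float = 0.05,
    seed=None,
    adjust_covariates: tuple | None = None,
) -> list[ComparisonResult]:
    """Run the omnibus + post-hoc battery over a variable dictionary.

    ``variables`` maps column name -> ("categorical" | "continuous",
    policy), where policy is the continuous test ("kruskal_wallis" or
    "welch_anova"; ignored for categorical).  Pairwise raw p-values from all
    significant omnibus tests form one BH family (one reporting table = one
    family).  Missing values are excluded pairwise per variable.  When
    ``adjust_covariates=("age", "sex")`` columns exist, continuous variables
    also get age/sex-adjusted group means.
    """
    results = []
    ss = np.random.SeedSequence(seed)
    for var, (vtype, policy) in variables.items():
        sub = data[[group_col, var]].dropna()
        values_by_group = {
            g: grp[var].to_numpy() for g, grp in sub.groupby(group_col, sort=True)
        }
        if len(values_by_group) < 2:
            results.append(
                ComparisonResult(var, "untestable", np.nan, None, np.nan,
                                 notes="fewer than 2 non-empty groups")
            )
            continue
        res = omnibus_test(values_by_group, vtype, policy, variable=var,
                           seed=ss.spawn(1)[0])
        pairwise_posthoc(values_by_group, res, alpha=alpha, q=q,
                         seed=ss.spawn(1)[0], adjust=False)
        if (
            adjust_covariates
            and vtype == "continuous"
            and all(c in data.columns for c in adjust_covariates)
        ):
            sub2 = data[[group_col, var, *adjust_covariates]].dropna()
            try:
                means, contrasts = adjusted_group_means(
                    sub2[var], sub2[group_col], sub2[adjust_covariates[0]],
                    sub2[adjust_covariates[1]], q=q,
                )
                res.adjusted = means
            except ValueError as exc:
                res.notes = (res.notes + "; " if res.notes else "") + f"adjustment failed: {exc}"
        results.append(res)

    # one BH family across all post-hoc pairs in this table
    family = [(res, pr) for res in results for pr in res.pairwise]
    if family:
        padj = bh_adjust([pr.p_raw for _, pr in family])
        for (_, pr), pa in zip(family, padj):
            pr.p_adj = float(pa)
            pr.significant = bool(pa < q)
    return results


def results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        base = {
            "variable": r.variable,
            "test": r.test_used,
            "statistic": r.statistic,
            "df": str(r.df),
            "p_omnibus": r.p_omnibus,
            "effect_size": r.effect_size,
            "effect_name": r.effect_name,
            "notes": r.notes,
        }
        if not r.pairwise:
            rows.append(base)
        for pr in r.pairwise:
            rows.append(
                {
                    **base,
                    "pair": f"{pr.pair[0]} vs {pr.pair[1]}",
                    "p_pair_raw": pr.p_raw,
                    "p_pair_bh": pr.p_adj,
                    "pair_significant": pr.significant,
                    "pair_effect": pr.effect_size,
                    "pair_effect_name": pr.effect_name,
                }
            )
    return pd.DataFrame(rows)
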