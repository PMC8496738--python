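import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dtialps.cohort import EXCLUSION_FLAGS, make_cohort
from dtialps.stats import (
    DEFAULT_CANDIDATES,
    ancova_adjusted_compare,
    apply_exclusions,
    cohort_summary,
    encode_predictors,
    icc_absolute_agreement,
    ks_normality,
    pooled_mean,
    stepwise_multivariable,
    univariable_regressions,
    vif,
)


# ---------------------------------------------------------------------------
# exclusion flow

def _flagged_cohort(n_total, flag_counts):
    df = make_cohort(seed=0).iloc[:0]
    base = make_cohort(seed=0)
    reps = int(np.ceil(n_total / len(base)))
    df = pd.concat([base] * reps, ignore_index=True).iloc[:n_total].copy()
    i = 0
    for flag, k in flag_counts.items():
        df.loc[df.index[i : i + k], flag] = True
        i += k
    return df


def test_screening_flow_retains_expected_count():
    """239 screened, disjoint exclusions 2+3+4+29 -> 201 analyzed."""
    df = _flagged_cohort(
        239,
        {"under_18": 2, "motion_artifact": 3, "infratentorial_only": 4, "idh1_missing": 29},
    )
    out = apply_exclusions(df)
    assert len(out) == 201
    c = out.attrs["exclusion_counts"]
    assert c["excluded_total"] == 38
    assert c["idh1_missing"] == 29


def test_no_flags_retains_all():
    df = make_cohort(seed=1)
    assert len(apply_exclusions(df)) == len(df)


def test_all_flagged_empty_with_warning():
    df = make_cohort(seed=1)
    df["under_18"] = True
    with pytest.warns(UserWarning, match="empty"):
        out = apply_exclusions(df)
    assert out.empty


# ---------------------------------------------------------------------------
# normality

def test_ks_normality_calibration(rng):
    """Type-I rate of the Lilliefors-corrected test is ~5% at alpha=0.05."""
    rejections = sum(
        ks_normality(rng.normal(size=100)) < 0.05 for _ in range(400)
    )
    assert 0.02 < rejections / 400 < 0.09


def test_ks_normality_detects_exponential(rng):
    x = rng.exponential(size=200)
    assert ks_normality(x) < 0.01


def test_ks_normality_input_validation(rng):
    with pytest.raises(ValueError, match="at least 5"):
        ks_normality([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="constant"):
        ks_normality(np.ones(10))


# ---------------------------------------------------------------------------
# ICC

def test_icc_identical_raters_is_one(rng):
    x = rng.normal(size=10)
    r = icc_absolute_agreement(np.column_stack([x, x]))
    assert r.icc == pytest.approx(1.0)


def test_icc_absolute_agreement_penalizes_offset(rng):
    x = rng.normal(size=20)
    X = np.column_stack([x, x + 1.5])
    absagree = icc_absolute_agreement(X).icc
    # consistency ICC from the same mean squares ignores the rater effect
    n, k = X.shape
    grand = X.mean()
    msr = k * ((X.mean(1) - grand) ** 2).sum() / (n - 1)
    ssc = n * ((X.mean(0) - grand) ** 2).sum()
    sse = ((X - grand) ** 2).sum() - (n - 1) / k * msr * k - ssc
    mse = (((X - X.mean(1, keepdims=True) - X.mean(0) + grand) ** 2).sum()) / ((n - 1) * (k - 1))
    consistency = (msr - mse) / (msr + (k - 1) * mse)
    assert absagree < consistency


def test_icc_fixture_matches_mean_squares_oracle():
    """6x2 fixture: hand mean-squares arithmetic to 1e-10."""
    X = np.array([[9, 2], [1, 1], [8, 4], [7, 1], [10, 5], [6, 2]], dtype=float)
    n, k = X.shape
    grand = X.mean()
    msr = k * ((X.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((X.mean(0) - grand) ** 2).sum() / (k - 1)
    mse = ((X - X.mean(1, keepdims=True) - X.mean(0, keepdims=True) + grand) ** 2).sum() / (
        (n - 1) * (k - 1)
    )
    expect = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    r = icc_absolute_agreement(X)
    assert r.icc == pytest.approx(expect, abs=1e-10)
    assert r.ci95[0] < r.icc < r.ci95[1]


def test_icc_matches_pingouin_reference(rng):
    pg = pytest.importorskip("pingouin")
    x = rng.normal(size=15)
    X = np.column_stack([x + rng.normal(0, 0.4, 15), x + 0.3 + rng.normal(0, 0.4, 15)])
    mine = icc_absolute_agreement(X)
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile([0, 1], 15),
            "score": X.ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    row = ref[ref["Type"] == "ICC(A,1)"].iloc[0] if (ref["Type"] == "ICC(A,1)").any() else ref.iloc[1]
    assert mine.icc == pytest.approx(float(row["ICC"]), abs=1e-10)
    np.testing.assert_allclose(mine.ci95, row["CI95"], atol=0.011)  # pingouin rounds


def test_icc_missing_cells_rejected():
    X = np.array([[1.0, 2.0], [3.0, np.nan], [2.0, 2.0], [1.0, 1.0], [0.0, 1.0]])
    with pytest.raises(ValueError, match="missing"):
        icc_absolute_agreement(X)


# ---------------------------------------------------------------------------
# ANCOVA

def test_constant_covariate_reduces_to_raw_group_means():
    df = make_cohort(seed=2)
    df["age"] = 50.0
    r = ancova_adjusted_compare(df, group="grade")
    raw = df.groupby("grade")["alps"].mean()
    for g in raw.index:
        assert r.adjusted_means[g] == pytest.approx(raw[g], rel=1e-12)


def test_ancova_matches_statsmodels():
    df = make_cohort(seed=3)
    r = ancova_adjusted_compare(df, group="idh1", covariate="age")
    fit = sm.OLS.from_formula("alps ~ C(idh1) + age", data=df).fit()
    # adjusted-mean difference equals the group coefficient
    coef = fit.params["C(idh1)[T.wild-type]"]
    (c,) = r.contrasts
    assert c.pair == ("mutant", "wild-type")
    assert c.difference == pytest.approx(-coef, rel=1e-10)
    assert c.p_raw == pytest.approx(fit.pvalues["C(idh1)[T.wild-type]"], rel=1e-10)


def test_shared_age_trend_is_adjusted_away(rng):
    """Two groups differing only through a common age trend: the adjusted
    difference is ~0 (within 2 SE at n=300)."""
    n = 300
    group = np.repeat(["a", "b"], n // 2)
    age = np.where(group == "a", rng.normal(40, 8, n), rng.normal(60, 8, n))
    y = 1.0 + 0.01 * age + rng.normal(0, 0.05, n)
    df = pd.DataFrame({"alps": y, "grp": group, "age": age})
    r = ancova_adjusted_compare(df, group="grp", covariate="age")
    (c,) = r.contrasts
    se = (c.ci95[1] - c.ci95[0]) / (2 * sps.t.ppf(1 - 0.025, n - 3))
    assert abs(c.difference) < 2 * se


def test_bonferroni_multiplier_is_number_of_pairs():
    df = make_cohort(seed=4)
    r = ancova_adjusted_compare(df, group="grade")
    assert len(r.contrasts) == 3
    for c in r.contrasts:
        assert c.p_bonferroni == pytest.approx(min(1.0, c.p_raw * 3), rel=1e-12)


def test_ancova_needs_multiple_populated_groups():
    df = make_cohort(seed=5)
    df["grade"] = "II"
    with pytest.raises(ValueError, match=">= 2 groups"):
        ancova_adjusted_compare(df, group="grade")


# ---------------------------------------------------------------------------
# regressions

def test_perfect_predictor_gives_beta_one():
    df = make_cohort(seed=6)
    df["alps"] = 2.0 * df["age"]
    r = univariable_regressions(df, predictors=("age",))["age"]
    assert r.beta["age"] == pytest.approx(1.0, abs=1e-12)
    assert r.p["age"] < 1e-100


def test_standardized_beta_equals_pearson_r():
    df = make_cohort(seed=7)
    res = univariable_regressions(df)
    enc = encode_predictors(df, list(DEFAULT_CANDIDATES))
    for name, r in res.items():
        pearson = sps.pearsonr(enc[name], df["alps"])
        assert r.beta[name] == pytest.approx(pearson.statistic, abs=1e-10)
        assert r.p[name] == pytest.approx(pearson.pvalue, rel=1e-6)


def test_zero_variance_predictor_skipped():
    df = make_cohort(seed=8)
    df["age"] = 50.0
    with pytest.warns(UserWarning, match="zero variance"):
        res = univariable_regressions(df, predictors=("age", "edema_cm3"))
    assert "age" not in res and "edema_cm3" in res


def test_univariable_type_one_rate(rng):
    """Independent noise predictor at n=201: p<0.05 in ~5% of 1000 sims."""
    df = make_cohort(seed=9)
    hits = 0
    for _ in range(1000):
        df["noise"] = rng.normal(size=len(df))
        r = univariable_regressions(df, predictors=("noise",))["noise"]
        hits += r.p["noise"] < 0.05
    assert 0.03 < hits / 1000 < 0.07


def test_stepwise_thresholds_degenerate_cases():
    df = make_cohort(seed=10)
    allin = stepwise_multivariable(df, p_enter=1.0, p_remove=1.0)
    assert set(allin.predictors) == set(DEFAULT_CANDIDATES)
    none = stepwise_multivariable(df, p_enter=0.0)
    assert none.predictors == []


def test_stepwise_entry_type_one_rate(rng):
    """A single pure-noise candidate enters in ~5% of runs."""
    df = make_cohort(seed=20_000)
    entered = 0
    for _ in range(1000):
        df["noise"] = rng.normal(size=len(df))
        r = stepwise_multivariable(df, candidates=("noise",))
        entered += "noise" in r.predictors
    assert 0.03 < entered / 1000 < 0.07


def test_stepwise_recovers_generative_predictors():
    df = make_cohort(seed=11)
    r = stepwise_multivariable(df)
    assert {"idh1", "edema_cm3"} <= set(r.predictors)
    assert r.p["idh1"] < 0.001 and r.p["edema_cm3"] < 0.001


# ---------------------------------------------------------------------------
# VIF

def test_vif_orthogonal_predictors_one():
    n = 64
    x1 = np.tile([1.0, -1.0], n // 2)
    x2 = np.repeat([1.0, -1.0], n // 2)
    df = pd.DataFrame({"x1": x1, "x2": x2})
    v = vif(df, ("x1", "x2"))
    assert v["x1"] == pytest.approx(1.0, abs=1e-12)
    assert v["x2"] == pytest.approx(1.0, abs=1e-12)


def test_vif_near_collinear_large(rng):
    x1 = rng.normal(size=200)
    df = pd.DataFrame({"x1": x1, "x2": x1 + rng.normal(0, 0.01, 200), "x3": rng.normal(size=200)})
    v = vif(df, ("x1", "x2", "x3"))
    assert v["x1"] > 100 and v["x2"] > 100
    assert v["x3"] < 2


def test_vif_matches_statsmodels_oracle(rng):
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = rng.normal(size=(50, 3))
    X[:, 1] += 0.7 * X[:, 0]
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    mine = vif(df, ("a", "b", "c"))
    Xc = sm.add_constant(X)
    for j, name in enumerate(["a", "b", "c"]):
        ref = variance_inflation_factor(Xc, j + 1)
        assert mine[name] == pytest.approx(ref, abs=1e-10)


def test_vif_perfect_collinearity_inf(rng):
    x = rng.normal(size=30)
    df = pd.DataFrame({"a": x, "b": 2 * x})
    with pytest.warns(UserWarning, match="collinear"):
        v = vif(df, ("a", "b"))
    assert np.isinf(v["a"])


# ---------------------------------------------------------------------------
# summaries

def test_summary_single_group_equals_pooled():
    df = make_cohort(seed=12)
    df = df[df["grade"] == "II"]
    s = cohort_summary(df)
    assert s.loc["alps_mean", "II"] == pytest.approx(s.loc["alps_mean", "All"])


def test_pooled_mean_identity_random(rng):
    df = make_cohort(seed=13)
    s = cohort_summary(df)
    sizes = np.array([s.loc["n", g] for g in ("II", "III", "IV")])
    means = np.array([s.loc["alps_mean", g] for g in ("II", "III", "IV")])
    assert pooled_mean(means, sizes) == pytest.approx(s.loc["alps_mean", "All"], rel=1e-12)


@settings(max_examples=50, deadline=None)
@given(
    means=st.lists(st.floats(-10, 10), min_size=2, max_size=5),
    sizes_raw=st.lists(st.integers(1, 50), min_size=5, max_size=5),
)
def test_pooled_mean_equals_direct_concatenation(means, sizes_raw):
    sizes = sizes_raw[: len(means)]
    direct = np.concatenate([np.full(n, m) for m, n in zip(means, sizes)]).mean()
    assert pooled_mean(np.array(means), np.array(sizes)) == pytest.approx(direct, rel=1e-9, abs=1e-9)
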