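import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvdarbor.quant import cohort_table
from pvdarbor.simulate import get_profile, simulate_cohort
from pvdarbor.stats import (
    AnovaError,
    clopper_pearson,
    holm_adjust,
    multiple_t_tests,
    penetrance,
    score_phenotype,
    tukey_hsd,
    two_way_anova,
)


def brute_force_anova(df):
    """Balanced two-way sums of squares from explicit cell/grand means."""
    grand = df.value.mean()
    ss = {}
    ss["A"] = sum(
        len(g) * (g.value.mean() - grand) ** 2 for _, g in df.groupby("genotype")
    )
    ss["B"] = sum(len(g) * (g.value.mean() - grand) ** 2 for _, g in df.groupby("region"))
    cells = df.groupby(["genotype", "region"])
    ss["cells"] = sum(len(g) * (g.value.mean() - grand) ** 2 for _, g in cells)
    ss["AB"] = ss["cells"] - ss["A"] - ss["B"]
    ss["resid"] = sum(((g.value - g.value.mean()) ** 2).sum() for _, g in cells)
    return ss


TOY = pd.DataFrame(
    {
        "value": [3.0, 5.0, 2.0, 4.0, 8.0, 10.0, 4.0, 6.0],
        "genotype": ["wt"] * 4 + ["mut"] * 4,
        "region": (["p"] * 2 + ["a"] * 2) * 2,
    }
)


def test_anova_matches_brute_force_on_toy_data():
    table = two_way_anova(TOY)
    oracle = brute_force_anova(TOY)
    assert table.loc["genotype", "SS"] == pytest.approx(oracle["A"], abs=1e-9)
    assert table.loc["region", "SS"] == pytest.approx(oracle["B"], abs=1e-9)
    assert table.loc["interaction", "SS"] == pytest.approx(oracle["AB"], abs=1e-9)
    assert table.loc["residual", "SS"] == pytest.approx(oracle["resid"], abs=1e-9)


def test_anova_matches_statsmodels_type2_unbalanced():
    """Independent oracle on an unbalanced design."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(7)
    rows = []
    for g, r, n in [("a", "x", 4), ("a", "y", 7), ("b", "x", 5), ("b", "y", 3)]:
        for _ in range(n):
            rows.append({"value": rng.normal(loc=(g == "b") * 0.8), "genotype": g, "region": r})
    df = pd.DataFrame(rows)
    ours = two_way_anova(df)
    fit = ols("value ~ C(genotype)*C(region)", df).fit()
    ref = sm.stats.anova_lm(fit, typ=2)
    assert ours.loc["genotype", "SS"] == pytest.approx(ref.loc["C(genotype)", "sum_sq"], rel=1e-9)
    assert ours.loc["region", "SS"] == pytest.approx(ref.loc["C(region)", "sum_sq"], rel=1e-9)
    assert ours.loc["interaction", "SS"] == pytest.approx(
        ref.loc["C(genotype):C(region)", "sum_sq"], rel=1e-9
    )
    assert ours.loc["genotype", "p"] == pytest.approx(ref.loc["C(genotype)", "PR(>F)"], rel=1e-9)


def test_anova_ss_decomposition_balanced():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        {
            "value": rng.normal(size=24),
            "genotype": ["a"] * 12 + ["b"] * 12,
            "region": (["x"] * 4 + ["y"] * 4 + ["z"] * 4) * 2,
        }
    )
    table = two_way_anova(df)
    total = ((df.value - df.value.mean()) ** 2).sum()
    assert table["SS"].sum() == pytest.approx(total, abs=1e-9)


def test_additive_design_has_zero_interaction():
    """Factor-B effect as a pure constant shift: interaction SS is 0."""
    base = np.array([1.0, 2.0, 3.0, 1.5])
    df = pd.DataFrame(
        {
            "value": np.concatenate([base, base + 5.0, base + 1.0, base + 6.0]),
            "genotype": ["a"] * 8 + ["b"] * 8,
            "region": (["x"] * 4 + ["y"] * 4) * 2,
        }
    )
    table = two_way_anova(df)
    assert table.loc["interaction", "SS"] == pytest.approx(0.0, abs=1e-9)


def test_anova_empty_cell_named():
    df = TOY[~((TOY.genotype == "mut") & (TOY.region == "a"))]
    with pytest.raises(AnovaError, match="mut"):
        two_way_anova(df)


def test_anova_needs_two_levels():
    with pytest.raises(AnovaError, match="2 levels"):
        two_way_anova(TOY.assign(genotype="wt"))


# ------------------------------------------------------------------ Tukey
def test_tukey_identical_groups_p_near_one():
    df = pd.DataFrame({"value": [1.0, 2, 3, 1, 2, 3], "genotype": ["a"] * 3 + ["b"] * 3})
    tk = tukey_hsd(df, factor="genotype")
    assert tk.loc[0, "p_adj"] > 0.99


def test_tukey_detects_shifted_group():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(
        {
            "value": np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(8, 1, 10)]),
            "genotype": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
        }
    )
    tk = tukey_hsd(df, factor="genotype").set_index(["level_a", "level_b"])
    assert tk.loc[("a", "c"), "p_adj"] < 0.001
    assert tk.loc[("b", "c"), "p_adj"] < 0.001
    assert tk.loc[("a", "b"), "p_adj"] > 0.5


def test_tukey_matches_scipy_oracle():
    from scipy.stats import tukey_hsd as scipy_tukey

    rng = np.random.default_rng(2)
    a, b, c = rng.normal(size=8), rng.normal(2, 1, 8), rng.normal(0.2, 1, 8)
    df = pd.DataFrame({"value": np.concatenate([a, b, c]), "genotype": ["a"] * 8 + ["b"] * 8 + ["c"] * 8})
    ours = tukey_hsd(df, factor="genotype").set_index(["level_a", "level_b"])
    ref = scipy_tukey(a, b, c)
    assert ours.loc[("a", "b"), "p_adj"] == pytest.approx(ref.pvalue[0, 1], rel=1e-6)
    assert ours.loc[("a", "c"), "p_adj"] == pytest.approx(ref.pvalue[0, 2], rel=1e-6)
    assert ours.loc[("b", "c"), "p_adj"] == pytest.approx(ref.pvalue[1, 2], rel=1e-6)


def test_tukey_single_level_rejected():
    df = pd.DataFrame({"value": [1.0, 2.0], "genotype": ["a", "a"]})
    with pytest.raises(AnovaError):
        tukey_hsd(df, factor="genotype")


# ------------------------------------------------------------------ t-tests
def test_welch_identical_groups():
    x = np.array([1.0, 2, 3, 4])
    out = multiple_t_tests({"same": (x, x.copy())})
    assert out.loc["same", "p"] == pytest.approx(1.0)


def test_welch_toy_pair():
    out = multiple_t_tests({"toy": (np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))})
    assert out.loc["toy", "t"] == pytest.approx(-3.674, abs=1e-3)
    assert out.loc["toy", "p"] == pytest.approx(0.0213, abs=5e-4)


def test_welch_matches_scipy():
    from scipy.stats import ttest_ind

    rng = np.random.default_rng(11)
    x, y = rng.normal(0, 1, 9), rng.normal(0.5, 2, 14)
    out = multiple_t_tests({"p": (x, y)})
    ref = ttest_ind(x, y, equal_var=False)
    assert out.loc["p", "t"] == pytest.approx(ref.statistic, rel=1e-12)
    assert out.loc["p", "p"] == pytest.approx(ref.pvalue, rel=1e-12)


def test_degenerate_pairs_flagged():
    out = multiple_t_tests(
        {
            "tiny": (np.array([1.0]), np.array([1.0, 2.0])),
            "const": (np.array([2.0, 2.0]), np.array([2.0, 2.0])),
        }
    )
    assert out.loc["tiny", "error"] == "group with n < 2"
    assert out.loc["const", "error"] == "zero variance"


@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=8))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_holm_adjustment_properties(ps):
    p = np.array(ps)
    adj = holm_adjust(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0)
    # order preserved
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


# ------------------------------------------------------------------ penetrance
def test_clopper_pearson_zero_of_ten():
    lo, hi = clopper_pearson(0, 10)
    assert lo == 0.0
    assert hi == pytest.approx(0.308, abs=5e-4)


def test_clopper_pearson_all_phenotypic():
    lo, hi = clopper_pearson(12, 12)
    assert hi == 1.0
    assert lo > 0.7


@given(st.integers(min_value=1, max_value=40), st.data())
@settings(deadline=None, max_examples=50, derandomize=True)
def test_ci_contains_point_estimate(n, data):
    k = data.draw(st.integers(min_value=0, max_value=n))
    lo, hi = clopper_pearson(k, n)
    assert lo <= k / n <= hi


def test_penetrance_on_simulated_mixture(wt_profile):
    """A 30% dma-1 / 70% wild-type mixed cohort scores a penetrance near
    the mixing fraction against the wild-type BCI reference."""
    ref_cohort = cohort_table([a for a, _ in simulate_cohort(wt_profile, 15, seed=30)])
    ref = ref_cohort.groupby("region")["bci"].mean().to_dict()

    mut = get_profile("dma-1")
    n_wt, n_mut = 42, 18
    arbors = [a for a, _ in simulate_cohort(wt_profile, n_wt, seed=31)]
    arbors += [a for a, _ in simulate_cohort(mut, n_mut, seed=32)]
    # distinct animal ids across the merged cohort
    for i, a in enumerate(arbors):
        a.metadata["animal_id"] = f"m{i:03d}"
    table = cohort_table(arbors)
    res = penetrance(table, ref)
    true_frac = n_mut / (n_wt + n_mut)
    se = np.sqrt(true_frac * (1 - true_frac) / (n_wt + n_mut))
    assert abs(res.fraction - true_frac) <= 2 * se + 0.05
    assert res.ci_low <= res.fraction <= res.ci_high


def test_penetrance_empty_cohort_rejected():
    with pytest.raises(ValueError, match="empty"):
        penetrance(pd.DataFrame(), {"-1": 1.0, "+1": 1.0})


def test_score_phenotype_requires_all_regions(wt_profile):
    table = cohort_table([a for a, _ in simulate_cohort(wt_profile, 2, seed=1)])
    ref = {"-1": 0.6, "+1": 0.7}
    calls = score_phenotype(table, ref)
    assert calls.dtype == bool and len(calls) == 2
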