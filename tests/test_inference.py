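"""Covariate-adjusted group inference: ANCOVA, post-hoc contrasts, FDR,
max-statistic permutation tests.

The ANCOVA implementation is checked against statsmodels' OLS + anova_lm
(Type II drop-one sums of squares coincide with our drop-the-effect
computation in this no-interaction model) and against classical one-way
ANOVA when there are no covariates.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_cohort_table
from mstnet.inference import (bh_fdr, fit_ancova, medication_contrast,
                              nodal_permutation_test, posthoc_pairwise,
                              run_group_analysis)

COVS = ("age", "sex", "education")


# ------------------------------------------------------------------ ANCOVA


def test_ancova_matches_statsmodels_oracle(rng):
    """Group and covariate F tests agree with statsmodels anova_lm(typ=2)
    on a small hand-built table."""
    table = make_cohort_table(rng, {"A": 8, "B": 7, "C": 9},
                              effects={"B": 0.8}, noise=1.0)
    ours = {r.effect: r for r in fit_ancova(table, "y", covariates=COVS)}
    model = smf.ols("y ~ C(group) + age + C(sex) + education", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    pairs = {"C(group)": "group", "age": "age", "C(sex)": "sex",
             "education": "education"}
    for sm_name, name in pairs.items():
        assert ours[name].F == pytest.approx(aov.loc[sm_name, "F"], rel=1e-8)
        assert ours[name].p == pytest.approx(aov.loc[sm_name, "PR(>F)"], rel=1e-6)
    assert ours["group"].df_error == int(aov.loc["Residual", "df"])


def test_ancova_reduces_to_oneway_anova(rng):
    """With no covariates and two groups, our F equals the classical
    one-way ANOVA F, over 100 random tables."""
    for _ in range(100):
        table = make_cohort_table(rng, {"A": 6, "B": 8},
                                  effects={"B": rng.normal()}, noise=1.0)
        res = fit_ancova(table, "y", covariates=())[0]
        a = table.loc[table.group == "A", "y"]
        b = table.loc[table.group == "B", "y"]
        f_classic, p_classic = stats.f_oneway(a, b)
        assert res.F == pytest.approx(f_classic, rel=1e-8)
        assert res.p == pytest.approx(p_classic, rel=1e-8)


def test_ancova_attributes_covariate_effect(rng):
    """measure = 0.1*age + noise with group-balanced age: age F large,
    group F small."""
    table = make_cohort_table(rng, {"A": 40, "B": 40})
    table["y"] = 0.1 * table["age"] + 0.2 * rng.standard_normal(len(table))
    res = {r.effect: r for r in fit_ancova(table, "y", covariates=COVS)}
    assert res["age"].p < 1e-6
    assert res["group"].p > 0.01
    assert res["age"].partial_eta_sq > 5 * res["group"].partial_eta_sq


def test_ancova_partial_eta_and_dfs(rng):
    table = make_cohort_table(rng, {"A": 10, "B": 12, "C": 11})
    res = fit_ancova(table, "y", covariates=COVS)
    grp = res[0]
    assert grp.effect == "group"
    assert grp.df_effect == 2
    assert grp.df_error == 33 - 6  # intercept + 2 dummies + 3 covariates
    for r in res:
        assert 0 <= r.partial_eta_sq <= 1
        assert r.F >= 0 and 0 <= r.p <= 1
    assert set(grp.adjusted_means) == {"A", "B", "C"}


def test_ancova_rejects_degenerate_designs(rng):
    table = make_cohort_table(rng, {"A": 6, "B": 6})
    table["dup"] = table["age"]
    with pytest.raises(ValueError):
        fit_ancova(table, "y", covariates=("age", "dup"))
    tiny = make_cohort_table(rng, {"A": 6})
    tiny.loc[len(tiny)] = tiny.iloc[0]
    tiny.loc[len(tiny) - 1, "group"] = "B"
    with pytest.raises(ValueError):  # group B has one subject
        fit_ancova(tiny, "y", covariates=COVS)


def test_null_ancova_rejection_rate_calibrated(rng):
    """Two identical groups: the group test rejects at ~alpha."""
    rejections = 0
    reps = 400
    for _ in range(reps):
        table = make_cohort_table(rng, {"A": 15, "B": 15})
        rejections += fit_ancova(table, "y", covariates=COVS)[0].p < 0.05
    rate = rejections / reps
    assert 0.02 < rate < 0.08


# ---------------------------------------------------------------- post hoc


def test_posthoc_antisymmetry_and_zero(rng):
    table = make_cohort_table(rng, {"A": 10, "B": 10, "C": 10},
                              effects={"C": 1.0})
    ph = posthoc_pairwise(table, "y", covariates=COVS)
    assert len(ph) == 3
    ab = ph[(ph.group_a == "A") & (ph.group_b == "B")].iloc[0]
    # recompute with swapped labels to verify antisymmetry
    swapped = table.copy()
    swapped["group"] = swapped["group"].map({"A": "B", "B": "A", "C": "C"})
    ph2 = posthoc_pairwise(swapped, "y", covariates=COVS)
    ba = ph2[(ph2.group_a == "A") & (ph2.group_b == "B")].iloc[0]
    assert ba.difference == pytest.approx(-ab.difference)
    assert ba.p == pytest.approx(ab.p)


def test_posthoc_detects_planted_difference(rng):
    hits = 0
    for _ in range(20):
        table = make_cohort_table(rng, {"A": 30, "B": 30},
                                  effects={"B": -1.0}, noise=1.0)
        ph = posthoc_pairwise(table, "y", covariates=COVS)
        row = ph.iloc[0]
        hits += (row.p < 0.05) and (
            (row.difference > 0) == (row.group_a == "A")
        )
    assert hits >= 16


def test_posthoc_hsd_never_more_liberal(rng):
    table = make_cohort_table(rng, {"A": 12, "B": 12, "C": 12},
                              effects={"C": 0.7})
    lsd = posthoc_pairwise(table, "y", covariates=COVS, method="lsd")
    hsd = posthoc_pairwise(table, "y", covariates=COVS, method="hsd")
    assert np.all(hsd["p"].to_numpy() >= lsd["p"].to_numpy() - 1e-12)


# --------------------------------------------------------------------- BH


def test_bh_examples():
    np.testing.assert_array_equal(
        bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05), [True] * 4
    )
    np.testing.assert_array_equal(
        bh_fdr([0.01, 0.04, 0.2], q=0.05), [True, False, False]
    )
    np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [False] * 3)


def test_bh_input_validation():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_fdr([0.5], q=0.0)


def brute_force_bh(p, q):
    p = np.asarray(p)
    order = np.argsort(p, kind="stable")
    m = len(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_star]] = True
    return flags


@settings(max_examples=100, derandomize=True, deadline=None)
@given(p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
       q=st.floats(0.01, 0.3))
def test_bh_matches_brute_force_scan(p, q):
    np.testing.assert_array_equal(bh_fdr(p, q), brute_force_bh(p, q))


# ------------------------------------------------------------ permutation


def test_permutation_determinism(rng):
    x = rng.standard_normal((30, 12))
    labels = ["A"] * 15 + ["B"] * 15
    r1 = nodal_permutation_test(x, labels, n_perm=300, seed=11)
    r2 = nodal_permutation_test(x, labels, n_perm=300, seed=11)
    assert [r.p_fwe for r in r1] == [r.p_fwe for r in r2]
    assert all(1 / 301 <= r.p_fwe <= 1 for r in r1)


def test_permutation_detects_planted_shift(rng):
    """A single node with a 3-SD group shift reaches FWE significance in at
    least 90% of 20 replicates."""
    hits = 0
    for _ in range(20):
        x = rng.standard_normal((40, 10))
        x[:20, 3] += 3.0
        res = nodal_permutation_test(
            x, ["A"] * 20 + ["B"] * 20, n_perm=500, seed=rng.integers(2**31)
        )
        hits += res[3].p_fwe < 0.05
    assert hits >= 18


def test_permutation_equivariance(rng):
    """p values are invariant to node relabeling and to positive rescaling
    of the metric."""
    x = rng.standard_normal((24, 8))
    labels = ["A"] * 12 + ["B"] * 12
    base = nodal_permutation_test(x, labels, n_perm=400, seed=5)
    perm = rng.permutation(8)
    shuffled = nodal_permutation_test(x[:, perm], labels, n_perm=400, seed=5)
    assert [base[j].p_fwe for j in perm] == [r.p_fwe for r in shuffled]
    scaled = nodal_permutation_test(7.3 * x, labels, n_perm=400, seed=5)
    assert [r.p_fwe for r in base] == [r.p_fwe for r in scaled]


def test_permutation_rejects_bad_inputs(rng):
    x = rng.standard_normal((9, 4))
    with pytest.raises(ValueError):
        nodal_permutation_test(x, ["A"] * 3 + ["B"] * 3 + ["C"] * 3, n_perm=200)
    with pytest.raises(ValueError):
        nodal_permutation_test(x, ["A"] * 9, n_perm=200)
    with pytest.raises(ValueError):
        nodal_permutation_test(x, ["A"] * 5 + ["B"] * 4, n_perm=50)


# -------------------------------------------------- medication & pipeline


def test_medication_contrast_null_and_planted(rng):
    table = make_cohort_table(rng, {"A": 60})
    table["lithium"] = rng.random(60) < 0.5
    null = medication_contrast(table, "y", "lithium", covariates=COVS)
    assert null.effect == "lithium"
    assert 0 <= null.p <= 1
    table2 = table.copy()
    table2["y"] += np.where(table2["lithium"], 1.5, 0.0)
    planted = medication_contrast(table2, "y", "lithium", covariates=COVS)
    assert planted.p < 0.01


def test_medication_flag_duplicated_as_covariate_rejected(rng):
    table = make_cohort_table(rng, {"A": 40})
    table["lithium"] = rng.random(40) < 0.5
    with pytest.raises(ValueError):
        medication_contrast(table, "y", "lithium",
                            covariates=("age", "lithium"))


def test_run_group_analysis_shape(rng):
    table = make_cohort_table(rng, {"HC": 12, "SCZ": 12, "BD": 12})
    for m in ("strength", "diameter_norm", "kappa", "leaf_fraction"):
        table[m] = rng.standard_normal(36)
    effects, posthoc = run_group_analysis(table)
    assert set(effects["measure"]) == {
        "strength", "diameter_norm", "kappa", "leaf_fraction"
    }
    grp = effects[effects.effect == "group"]
    assert len(grp) == 4
    assert grp["fdr_significant"].notna().all()
    assert len(posthoc) == 4 * 3  # 3 pairs per measure
    assert {"adj_mean_HC", "adj_se_HC"} <= set(effects.columns)
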