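"""Statistical engine against closed-form and enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from translen import (
    TestConfig,
    adjust_pvalues,
    fit_lmm,
    fit_ttest,
    fit_wilcoxon,
    results_to_frame,
    run_differential_length,
)
from translen.simulate import SimScenario, simulate_scenario
from translen.stats import InsufficientDataError

from conftest import make_length_table


# ---------------------------------------------------------------- t-test


def pooled_t_oracle(a, b):
    """Closed-form pooled-variance two-sample t."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    sp2 = ((n - 1) * a.var(ddof=1) + (m - 1) * b.var(ddof=1)) / (n + m - 2)
    se = np.sqrt(sp2 * (1 / n + 1 / m))
    t = (b.mean() - a.mean()) / se
    from scipy.stats import t as tdist

    return b.mean() - a.mean(), se, t, 2 * tdist.sf(abs(t), n + m - 2)


def test_ttest_worked_example():
    est, se, t, p = fit_ttest([1, 2, 3, 4], [0, 0, 1, 1])
    assert est == pytest.approx(2.0)
    assert t == pytest.approx(2.828427, abs=1e-5)
    # closed form for df=2: p = 1 - t/sqrt(t^2+2) with t = 2*sqrt(2)
    assert p == pytest.approx(1 - np.sqrt(8 / 10), abs=1e-9)


def test_ttest_identical_samples_and_sign():
    est, _, t, p = fit_ttest([1, 3, 1, 3], [0, 0, 1, 1])
    assert est == pytest.approx(0.0, abs=1e-12)
    assert t == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)
    est, *_ = fit_ttest([10, 12, 6, 8], [0, 0, 1, 1])
    assert est == pytest.approx(-4.0)  # negative = shorter in treated


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    a=st.lists(st.floats(10, 2000), min_size=3, max_size=12),
    b=st.lists(st.floats(10, 2000), min_size=3, max_size=12),
)
def test_ttest_matches_closed_form(a, b):
    y = np.array(a + b)
    cond = np.array([0] * len(a) + [1] * len(b))
    if np.var(a) + np.var(b) < 1e-12:
        return  # degenerate draw: no residual variance
    est, se, t, p = fit_ttest(y, cond)
    est_o, se_o, t_o, p_o = pooled_t_oracle(a, b)
    assert est == pytest.approx(est_o, abs=1e-10, rel=1e-10)
    assert se == pytest.approx(se_o, rel=1e-10)
    assert t == pytest.approx(t_o, rel=1e-9)
    assert p == pytest.approx(p_o, rel=1e-9, abs=1e-12)


def test_ttest_degenerate_errors():
    with pytest.raises(InsufficientDataError):
        fit_ttest([1.0, 2.0, 3.0], [0, 0, 1])
    with pytest.raises(InsufficientDataError, match="variance"):
        fit_ttest([5.0, 5.0, 5.0, 5.0], [0, 0, 1, 1])


def test_ttest_with_covariate_adjusts():
    # covariate perfectly explains a nuisance trend; estimate recovers the pure shift
    rng = np.random.default_rng(1)
    x = np.array([0.0, 1.0, 2.0, 3.0] * 4)
    cond = np.repeat([0, 1], 8)
    y = 100 + 10 * x - 5 * cond + rng.normal(0, 0.01, 16)
    est, _, _, p = fit_ttest(y, cond, covariates=x)
    assert est == pytest.approx(-5.0, abs=0.05)


# ------------------------------------------------------------- Wilcoxon


def exact_rank_p(a, b):
    """Two-sided Mann-Whitney p by exhaustive enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    obs = ranks[:n].sum()
    sums = [sum(c) for c in combinations(ranks, n)]
    mu = n * (len(pooled) + 1) / 2
    extreme = sum(abs(s - mu) >= abs(obs - mu) - 1e-9 for s in sums)
    return extreme / len(sums)


def test_wilcoxon_worked_examples():
    _, _, p = fit_wilcoxon([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
    assert p == pytest.approx(0.1)
    _, _, p = fit_wilcoxon([1, 3, 5, 2, 4, 6], [0, 0, 0, 1, 1, 1])
    assert p == pytest.approx(0.7)
    est, u, p = fit_wilcoxon([7, 7, 7, 7, 7, 7], [0, 0, 0, 1, 1, 1])
    assert p == 1.0 and est == 0.0


@pytest.mark.parametrize("n,m", [(2, 3), (3, 3), (4, 5), (6, 6)])
def test_wilcoxon_matches_enumeration(n, m, rng):
    for _ in range(10):
        y = rng.permutation(np.arange(1.0, n + m + 1))  # tie-free
        cond = np.array([0] * n + [1] * m)
        _, _, p = fit_wilcoxon(y, cond)
        assert p == pytest.approx(exact_rank_p(y[:n], y[n:]), abs=1e-12)


def test_wilcoxon_empty_group_errors():
    with pytest.raises(InsufficientDataError):
        fit_wilcoxon([1.0, 2.0], [0, 0])


# ------------------------------------------------------------------ LMM


def test_lmm_recovers_library_mean_contrast(rng):
    # balanced 2+2 libraries: beta_cond equals the OLS contrast of library means
    lib_means = {"c1": 100.0, "c2": 102.0, "t1": 90.0, "t2": 92.0}
    y, cond, libs = [], [], []
    for lib, mu in lib_means.items():
        y.append(rng.normal(mu, 0.5, 50))
        cond += [0 if lib.startswith("c") else 1] * 50
        libs += [lib] * 50
    est, se, stat, p, vc, status = fit_lmm(np.concatenate(y), np.array(cond), np.array(libs))
    assert est == pytest.approx(-10.0, abs=1.5)


def test_lmm_zero_library_variance_matches_ttest(rng):
    y = rng.normal(1000, 150, 120)
    cond = np.repeat([0, 1], 60)
    libs = np.repeat(np.arange(6), 20)
    est_lmm, *_ = fit_lmm(y, cond, libs)
    est_t, *_ = fit_ttest(y, cond)
    assert est_lmm == pytest.approx(est_t, abs=1e-6)


def test_lmm_logscale_scale_invariance(rng):
    y = rng.normal(1000, 100, 120)
    cond = np.repeat([0, 1], 60)
    libs = np.repeat(np.arange(6), 20)
    est1, *_ = fit_lmm(np.log2(y), cond, libs)
    est2, *_ = fit_lmm(np.log2(2 * y), cond, libs)
    assert est1 == pytest.approx(est2, abs=1e-8)


def test_lmm_single_library_per_condition_warns(rng):
    y = rng.normal(1000, 100, 40)
    cond = np.repeat([0, 1], 20)
    libs = np.repeat([0, 1], 20)
    with pytest.warns(UserWarning, match="confounded"):
        fit_lmm(y, cond, libs)


# ------------------------------------------------------------------- BH


def test_bh_worked_examples():
    assert adjust_pvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert adjust_pvalues([0.5]) == pytest.approx([0.5])
    assert adjust_pvalues([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=200)
    ours = adjust_pvalues(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    assert ours == pytest.approx(theirs, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_properties(p):
    adj = adjust_pvalues(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    assert np.all((adj >= 0) & (adj <= 1))
    perm = np.random.default_rng(0).permutation(len(p))
    assert adjust_pvalues(np.asarray(p)[perm]) == pytest.approx(adj[perm])


def test_bonferroni_option():
    assert adjust_pvalues([0.01, 0.4], method="bonferroni") == pytest.approx([0.02, 0.8])


def test_pvalues_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        adjust_pvalues([0.5, 1.2])


# ------------------------------------------------- run_differential_length


def test_identical_conditions_give_zero_estimates(two_by_two_design):
    rows = []
    for feat in ("tx1", "tx2"):
        for i in range(6):
            L = 100 + 10 * i
            rows.append((f"{feat}c{i}a", "ctrl_1", feat, 0, L))
            rows.append((f"{feat}c{i}b", "ctrl_2", feat, 0, L))
            rows.append((f"{feat}t{i}a", "treat_1", feat, 0, L))
            rows.append((f"{feat}t{i}b", "treat_2", feat, 0, L))
    res = run_differential_length(make_length_table(rows), two_by_two_design, TestConfig(model="ttest"))
    assert all(r.estimate == pytest.approx(0.0) for r in res)


def test_single_feature_adj_equals_p():
    sc = SimScenario(n_genes=1, count=20, seed=7)
    table, design = simulate_scenario(sc)
    res = run_differential_length(table, design)
    assert len(res) == 1
    assert res[0].adj_p_value == pytest.approx(res[0].p_value)


def test_estimate_equivariance(two_by_two_design, rng):
    rows = []
    base = rng.integers(200, 1200, 40)
    libs = ["ctrl_1", "ctrl_2", "treat_1", "treat_2"]
    for i, L in enumerate(base):
        rows.append((f"r{i}", libs[i % 4], "tx", 0, int(L)))
    t1 = make_length_table(rows)
    t2 = make_length_table([(r, l, f, p, int(3 * e)) for r, l, f, p, e in rows])  # scale by 3
    t3 = make_length_table([(r, l, f, p, e + 500) for r, l, f, p, e in rows])  # shift by 500
    cfg = TestConfig(model="ttest")
    e1 = run_differential_length(t1, two_by_two_design, cfg)[0].estimate
    e2 = run_differential_length(t2, two_by_two_design, cfg)[0].estimate
    e3 = run_differential_length(t3, two_by_two_design, cfg)[0].estimate
    assert e2 == pytest.approx(3 * e1, rel=1e-9)
    assert e3 == pytest.approx(e1, abs=1e-9)
    log1 = run_differential_length(t1, two_by_two_design, TestConfig(model="ttest", logscale=True))[0].estimate
    log2 = run_differential_length(t2, two_by_two_design, TestConfig(model="ttest", logscale=True))[0].estimate
    assert log2 == pytest.approx(log1, abs=1e-9)


def test_results_sorted_by_p_and_failures_flagged(two_by_two_design):
    rows = [("a1", "ctrl_1", "tx_ok", 0, 100), ("a2", "ctrl_2", "tx_ok", 0, 120),
            ("a3", "treat_1", "tx_ok", 0, 300), ("a4", "treat_2", "tx_ok", 0, 320),
            # constant-length feature: zero residual variance -> flagged, not dropped
            ("b1", "ctrl_1", "tx_const", 0, 50), ("b2", "ctrl_2", "tx_const", 0, 50),
            ("b3", "treat_1", "tx_const", 0, 50), ("b4", "treat_2", "tx_const", 0, 50)]
    res = run_differential_length(make_length_table(rows), two_by_two_design, TestConfig(model="ttest"))
    frame = results_to_frame(res)
    assert set(frame.feature_id) == {"tx_ok", "tx_const"}
    flagged = frame.set_index("feature_id").loc["tx_const"]
    assert flagged.status.startswith("failed")
    ps = frame.p_value.to_numpy()
    finite = ps[np.isfinite(ps)]
    assert np.all(np.diff(finite) >= 0)


def test_wilcoxon_with_covariates_is_config_error():
    with pytest.raises(ValueError, match="covariates"):
        TestConfig(model="wilcoxon", covariates=("batch",))


def test_null_simulation_fpr_near_alpha():
    # 200 null genes, t-test on lib-variance-free data: p<0.05 fraction near 0.05
    sc = SimScenario(n_genes=200, count=20, shortening_prop=1.0, lib_sd_frac=1e-9, seed=11)
    table, design = simulate_scenario(sc)
    res = run_differential_length(table, design, TestConfig(model="ttest"))
    frac = np.mean([r.p_value < 0.05 for r in res])
    se = np.sqrt(0.05 * 0.95 / 200)
    assert abs(frac - 0.05) < 3 * se
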