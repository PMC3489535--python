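"""Contrast construction, t-tests, degrees of freedom and BH FDR."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import protlmm as pl
from protlmm.dataio import FeatureTable
from protlmm.inference import adjust_fdr, condition_mean_vector
from protlmm.model import build_model_spec, fit_reduced

from conftest import fit_quiet, two_condition_table


def test_contrast_requires_zero_sum():
    with pytest.raises(ValueError, match="sum to 0"):
        pl.ComparisonSpec("bad", {"A": 1.0, "B": 1.0})
    with pytest.raises(ValueError):
        pl.ComparisonSpec("bad", {"A": 0.0, "B": 0.0})


def test_contrast_recovers_constructed_truth():
    """Noise-free 2-feature data with a true difference of 1.5."""
    rows = []
    conds = [f"c{j}" for j in range(8)]
    means = {c: 10.0 for c in conds}
    means["c0"], means["c2"] = 11.5, 10.0  # c0 - c2 = 1.5
    for c in conds:
        for k in range(2):
            s = f"{c}_s{k}"
            for i, off in [(0, 0.0), (1, -2.0)]:
                rows.append({"ProteinName": "P", "FeatureName": f"f{i}",
                             "Condition": c, "BioReplicate": s, "Run": s,
                             "Intensity": 1.0,
                             "LogIntensity": means[c] + off})
    table = FeatureTable(pd.DataFrame(rows), log_base=2)
    design = pl.infer_design(table)
    fit = fit_quiet(table.protein_data("P"), design)
    res = pl.test_contrast(fit, pl.ComparisonSpec("x", {"c0": 1, "c2": -1}))
    assert res.estimate == pytest.approx(1.5, abs=1e-10)
    # noise-free: SE vanishes (to numerical precision) and p collapses to 0
    assert res.se < 1e-10
    assert res.p < 1e-10 or res.status == "degenerate"


def test_averaging_contrast_weights(factorial):
    """+-1/2 coefficients average condition means over two time levels."""
    table, _, design = factorial
    fit = fit_quiet(table.protein_data(table.proteins[0]), design)
    comp = pl.ComparisonSpec("avg", {
        "low:normoxia:6": 0.5, "low:normoxia:24": 0.5,
        "high:normoxia:6": -0.5, "high:normoxia:24": -0.5})
    res = pl.test_contrast(fit, comp)
    manual = 0.5 * (pl.quantify_condition(fit, "low:normoxia:6").estimate
                    + pl.quantify_condition(fit, "low:normoxia:24").estimate) \
        - 0.5 * (pl.quantify_condition(fit, "high:normoxia:6").estimate
                 + pl.quantify_condition(fit, "high:normoxia:24").estimate)
    assert res.estimate == pytest.approx(manual, abs=1e-10)


def test_balanced_reduced_df_formula(factorial):
    """Residual df equals IJK(L-1) + (I-1)J(K-1); 72 for I=2,J=8,K=2,L=3."""
    table, _, design = factorial
    pdata = table.protein_data(table.proteins[0])
    pdata = pdata[pdata["FeatureName"].isin(pdata["FeatureName"].unique()[:2])]
    fit = fit_quiet(pdata, design)
    assert fit.df_residual == 72
    res = pl.test_contrast(fit, pl.ComparisonSpec(
        "x", {design.conditions[0]: 1, design.conditions[1]: -1}))
    assert res.df == 72


@pytest.mark.parametrize("I,J,K,L", [(1, 2, 3, 2), (2, 2, 2, 2), (3, 4, 2, 2),
                                     (2, 3, 3, 1), (4, 2, 3, 3)])
def test_df_grid_matches_formula(I, J, K, L):
    """Balanced reduced-scope residual df on a grid of (I, J, K, L)."""
    rng = np.random.default_rng(I * 100 + J * 10 + K + L)
    rows = []
    for j in range(J):
        c = f"c{j}"
        for k in range(K):
            s = f"{c}_s{k}"
            for l in range(L):
                r = f"{s}_t{l}"
                for i in range(I):
                    rows.append({"ProteinName": "P", "FeatureName": f"f{i}",
                                 "Condition": c, "BioReplicate": s, "Run": r,
                                 "Intensity": 1.0,
                                 "LogIntensity": rng.normal(10, 1)})
    table = FeatureTable(pd.DataFrame(rows), log_base=2)
    fit = fit_quiet(table.protein_data("P"), pl.infer_design(table))
    assert fit.df_residual == pl.balanced_df(I, J, K, L)


def test_pooled_t_test_is_degenerate_case():
    """One feature, two conditions, L=1: exact classical pooled t-test."""
    table = two_condition_table(n_per_group=5, diff=0.4, seed=8)
    design = pl.infer_design(table)
    fit = fit_quiet(table.protein_data("P"), design)
    res = pl.test_contrast(fit, pl.ComparisonSpec("AB", {"A": 1, "B": -1}))
    df = table.data
    a = df.loc[df["Condition"] == "A", "LogIntensity"]
    b = df.loc[df["Condition"] == "B", "LogIntensity"]
    t_ref, p_ref = stats.ttest_ind(a, b)
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
        / (len(a) + len(b) - 2)
    se_ref = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    assert res.estimate == pytest.approx(a.mean() - b.mean(), abs=1e-12)
    assert res.se == pytest.approx(se_ref, abs=1e-12)
    assert res.df == len(a) + len(b) - 2
    assert res.t == pytest.approx(t_ref, abs=1e-10)
    assert res.p == pytest.approx(p_ref, abs=1e-12)


def test_symmetric_data_gives_t_zero():
    table = two_condition_table(n_per_group=3, diff=0.0, seed=1)
    df = table.data.copy()
    df.loc[df["Condition"] == "B", "LogIntensity"] = \
        df.loc[df["Condition"] == "A", "LogIntensity"].to_numpy()
    fit = fit_quiet(df, pl.infer_design(table))
    res = pl.test_contrast(fit, pl.ComparisonSpec("AB", {"A": 1, "B": -1}))
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_type_i_error_calibration():
    """Null simulation, reduced scope: rejection rate at p<0.05 in 0.05+-0.02."""
    table, _ = pl.generate_factorial(n_proteins=300, features_range=(2, 4),
                                     frac_differential=0.0, sigma_subject=0.0,
                                     seed=77)
    design = pl.infer_design(table)
    comp = pl.ComparisonSpec("null", {"low:normoxia:6": 1,
                                      "high:normoxia:6": -1})
    ps = []
    for prot in table.proteins:
        fit = fit_quiet(table.protein_data(prot), design)
        ps.append(pl.test_contrast(fit, comp).p)
    rate = np.mean(np.asarray(ps) < 0.05)
    assert 0.03 <= rate <= 0.07


# -- BH adjustment ----------------------------------------------------------

def brute_force_bh(pvals):
    """Literal step-up definition: adj_p(i) = min_{j>=i} m * p(j) / j."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * pvals[order[j]] / (j + 1)
                      for j in range(rank_pos, m)]
        adj[idx] = min(1.0, min(candidates))
    return adj


def test_bh_hand_example():
    assert np.allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    assert adjust_fdr([]).size == 0


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
def test_bh_matches_brute_force(pvals):
    assert np.allclose(adjust_fdr(pvals), brute_force_bh(np.asarray(pvals)))


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8))
def test_bh_monotone_and_order_invariant(pvals):
    adj = adjust_fdr(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    perm = np.random.default_rng(0).permutation(len(pvals))
    assert np.allclose(adj[perm], adjust_fdr(np.asarray(pvals)[perm]))


# -- scope and joint-modeling properties ------------------------------------

def _pvals_for(table, design, comp, scope="reduced"):
    out = []
    for prot in table.proteins:
        fit = fit_quiet(table.protein_data(prot), design, scope=scope)
        out.append(pl.test_contrast(fit, comp).p)
    return np.asarray(out)


def test_joint_model_more_sensitive_than_pairwise():
    """Median p over differential proteins: joint <= pairwise-only model."""
    table, truth = pl.generate_factorial(
        n_proteins=60, features_range=(2, 5), frac_differential=1.0,
        effect_sizes=(0.4,), sigma_subject=0.0, seed=31)
    design = pl.infer_design(table)
    comp = pl.ComparisonSpec("eff", {"low:normoxia:6": 1,
                                     "high:normoxia:6": -1})
    p_joint = _pvals_for(table, design, comp)
    pair = table.with_data(table.data[table.data["Condition"].isin(
        ["low:normoxia:6", "high:normoxia:6"])])
    p_pair = _pvals_for(pair, pl.infer_design(pair), comp)
    assert np.median(p_joint) <= np.median(p_pair)


def test_expanded_scope_more_conservative_on_null_split():
    """Random split of one condition's replicates (sigma_S > 0): expanded
    scope declares no more significant proteins than reduced scope."""
    table, _ = pl.generate_factorial(
        n_proteins=40, features_range=(2, 4), K=4, frac_differential=0.0,
        sigma_subject=0.4, seed=55)
    df = table.data[table.data["Condition"] == "low:normoxia:6"].copy()
    subjects = sorted(df["BioReplicate"].unique())
    half = set(subjects[:2])
    df["Condition"] = np.where(df["BioReplicate"].isin(half), "g1", "g2")
    split = FeatureTable(df, log_base=2)
    design = pl.infer_design(split)
    comp = pl.ComparisonSpec("split", {"g1": 1, "g2": -1})
    n_sig = {}
    for scope in ("reduced", "expanded"):
        p = _pvals_for(split, design, comp, scope=scope)
        n_sig[scope] = int(np.sum(adjust_fdr(p) < 0.05))
    assert n_sig["expanded"] <= n_sig["reduced"]


def test_compare_proteins_table(factorial):
    table, _, design = factorial
    comps = [pl.ComparisonSpec("a", {"low:normoxia:6": 1,
                                     "high:normoxia:6": -1}),
             pl.ComparisonSpec("b", {"low:hypoxia:6": 1,
                                     "low:hypoxia:24": -1})]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = pl.analyze(table, comparisons=comps)
    res = bundle["results"]
    assert len(res) == 2 * len(table.proteins)
    assert set(res["Label"]) == {"a", "b"}
    ok = res[res["status"] == "ok"]
    assert (ok["adj.pvalue"] >= ok["pvalue"] - 1e-12).all()
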