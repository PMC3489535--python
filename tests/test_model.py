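"""Per-protein model construction and fitting.

The reduced-scope fit is validated against an explicit normal-equations
oracle ((X'WX)^-1 X'Wy computed independently), the expanded-scope REML
against statsmodels MixedLM, and the loess weighting against simulated
homo-/heteroscedastic truth.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import protlmm as pl
from protlmm.dataio import FeatureTable
from protlmm.model import (build_design_matrix, build_model_spec,
                           fit_expanded, fit_reduced, loess_weight_fit)

from conftest import fit_quiet, two_condition_table


def _random_instance(rng, n_cond=3, n_feat=2, n_subj=2, n_tech=2,
                     drop_frac=0.0):
    rows = []
    for j in range(n_cond):
        c = f"c{j}"
        for k in range(n_subj):
            s = f"{c}_s{k}"
            for l in range(n_tech):
                r = f"{s}_t{l}"
                for i in range(n_feat):
                    rows.append({"ProteinName": "P", "FeatureName": f"f{i}",
                                 "Condition": c, "BioReplicate": s, "Run": r,
                                 "Intensity": 1.0,
                                 "LogIntensity": rng.normal(10, 1)})
    df = pd.DataFrame(rows)
    if drop_frac:
        keep = rng.random(len(df)) > drop_frac
        # never empty out a whole condition
        for c in df["Condition"].unique():
            keep[df.index[df["Condition"] == c][0]] = True
        df = df[keep].reset_index(drop=True)
    return df


# -- model specification ----------------------------------------------------

def test_spec_term_counts(factorial):
    table, _, design = factorial
    # pick a protein with >= 3 features and keep 3
    for prot in table.proteins:
        pdata = table.protein_data(prot)
        feats = pdata["FeatureName"].unique()
        if len(feats) >= 3:
            pdata = pdata[pdata["FeatureName"].isin(feats[:3])]
            break
    spec = build_model_spec(pdata, design, interaction=True)
    _, names, _ = build_design_matrix(pdata, spec)
    count = lambda pre: sum(n.startswith(pre) for n in names)
    assert count("C[") == 7
    assert count("F[") == 2
    assert count("FC[") == 14
    assert count("S[") == 8  # J * (K - 1) nested subject dummies
    assert spec.has_subject_terms


def test_single_feature_drops_feature_terms(factorial):
    table, _, design = factorial
    pdata = table.protein_data(table.proteins[0])
    f0 = pdata["FeatureName"].iloc[0]
    spec = build_model_spec(pdata[pdata["FeatureName"] == f0], design)
    assert not spec.has_feature_terms and not spec.has_interaction


def test_interaction_off(factorial):
    table, _, design = factorial
    spec = build_model_spec(table.protein_data(table.proteins[0]), design,
                            interaction=False)
    assert spec.has_feature_terms and not spec.has_interaction


# -- reduced scope ----------------------------------------------------------

def test_noise_free_exact_recovery():
    table, truth = pl.generate_factorial(n_proteins=3, sigma_error=0.0,
                                         sigma_subject=0.0, seed=5)
    design = pl.infer_design(table)
    for prot in table.proteins:
        fit = fit_quiet(table.protein_data(prot), design)
        assert np.max(np.abs(fit.residuals)) < 1e-10
        offs = truth.feature_offsets
        mean_off = offs.loc[offs["ProteinName"] == prot, "offset"].mean()
        for cond in design.conditions:
            q = pl.quantify_condition(fit, cond)
            assert q.estimate == pytest.approx(
                truth.condition_mean(prot, cond) + mean_off, abs=1e-10)


def test_reduced_fit_matches_normal_equations_oracle():
    """100 random instances (<= 50 obs) vs explicit (X'WX)^-1 X'Wy."""
    rng = np.random.default_rng(42)
    for trial in range(100):
        df = _random_instance(
            rng, n_cond=int(rng.integers(2, 4)),
            n_feat=int(rng.integers(1, 3)), n_subj=2,
            n_tech=int(rng.integers(1, 3)),
            drop_frac=float(rng.choice([0.0, 0.15])))
        table = FeatureTable(df, log_base=2)
        design = pl.infer_design(table)
        spec = build_model_spec(df, design)
        w = rng.uniform(0.5, 2.0, df["LogIntensity"].notna().sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_reduced(df, spec, weights=w)
        X, names, obs = build_design_matrix(df, spec)
        keep = [names.index(nm) for nm in fit.params.index]
        Xk = X[:, keep]
        y = obs["LogIntensity"].to_numpy()
        beta = np.linalg.pinv(Xk.T @ (w[:, None] * Xk)) @ Xk.T @ (w * y)
        assert np.max(np.abs(beta - fit.params.to_numpy())) < 1e-8


def test_balanced_condition_mean_equals_arithmetic_mean(factorial):
    table, _, design = factorial
    for prot in table.proteins[:5]:
        pdata = table.protein_data(prot)
        fit = fit_quiet(pdata, design)
        for cond in design.conditions:
            q = pl.quantify_condition(fit, cond)
            naive = pdata.loc[pdata["Condition"] == cond, "LogIntensity"].mean()
            assert q.estimate == pytest.approx(naive, abs=1e-10)


def test_residuals_sum_to_zero_per_group(factorial):
    table, _, design = factorial
    pdata = table.protein_data(table.proteins[0])
    fit = fit_quiet(pdata, design)
    obs = pdata[pdata["LogIntensity"].notna()]
    for _, grp in obs.groupby("Condition"):
        assert fit.residuals[grp.index].sum() == pytest.approx(0.0, abs=1e-9)
    for _, grp in obs.groupby("FeatureName"):
        assert fit.residuals[grp.index].sum() == pytest.approx(0.0, abs=1e-9)


def test_fully_missing_condition_is_untestable(factorial):
    table, _, design = factorial
    pdata = table.protein_data(table.proteins[0]).copy()
    gone = design.conditions[3]
    pdata.loc[pdata["Condition"] == gone,
              ["Intensity", "LogIntensity"]] = np.nan
    fit = fit_quiet(pdata, design)
    assert gone in fit.untestable_conditions
    res = pl.test_contrast(fit, pl.ComparisonSpec(
        "x", {gone: 1.0, design.conditions[0]: -1.0}))
    assert res.status == "untestable"
    # contrasts not touching the lost condition still work
    ok = pl.test_contrast(fit, pl.ComparisonSpec(
        "y", {design.conditions[1]: 1.0, design.conditions[0]: -1.0}))
    assert ok.status == "ok" and np.isfinite(ok.p)


# -- expanded scope ---------------------------------------------------------

def test_expanded_matches_mixedlm_oracle(factorial):
    import statsmodels.api as sm

    table, _, design = factorial
    for prot in table.proteins[:3]:
        pdata = table.protein_data(prot)
        spec = build_model_spec(pdata, design, scope="expanded")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_expanded(pdata, spec)
            X, names, obs = build_design_matrix(pdata, spec,
                                                include_subject=False)
            ml = sm.MixedLM(obs["LogIntensity"].to_numpy(), X,
                            groups=obs["BioReplicate"].to_numpy()).fit(reml=True)
        assert np.max(np.abs(fit.params.to_numpy() - ml.fe_params)) < 1e-6
        assert fit.sigma2_error == pytest.approx(ml.scale, rel=1e-4)
        assert fit.sigma2_subject == pytest.approx(
            float(np.asarray(ml.cov_re)[0, 0]), abs=1e-4)


def test_expanded_equals_reduced_condition_means_on_balanced(factorial):
    table, _, design = factorial
    pdata = table.protein_data(table.proteins[1])
    red = fit_quiet(pdata, design, scope="reduced")
    exp = fit_quiet(pdata, design, scope="expanded")
    for cond in design.conditions:
        assert pl.quantify_condition(exp, cond).estimate == pytest.approx(
            pl.quantify_condition(red, cond).estimate, abs=1e-6)


def test_expanded_sigma_s_zero_truth():
    """sigma_S = 0 truth: median estimate over simulations near zero."""
    est = []
    for seed in range(40):
        table, _ = pl.generate_factorial(
            n_proteins=1, features_range=(3, 3), sigma_subject=0.0,
            sigma_error=0.3, seed=100 + seed)
        design = pl.infer_design(table)
        fit = fit_quiet(table.protein_data(table.proteins[0]), design,
                        scope="expanded")
        est.append(fit.sigma2_subject)
    assert np.median(est) < 0.01


def test_expanded_recovers_sigma_s():
    """sigma_S = 0.5, sigma_Error = 0.2, K = 10: median recovery within 20%."""
    est_s, est_e = [], []
    for seed in range(40):
        table, _ = pl.generate_factorial(
            n_proteins=1, features_range=(3, 3), K=10, L=2,
            sigma_subject=0.5, sigma_error=0.2, frac_differential=0.0,
            seed=300 + seed)
        design = pl.infer_design(table)
        fit = fit_quiet(table.protein_data(table.proteins[0]), design,
                        scope="expanded")
        est_s.append(np.sqrt(fit.sigma2_subject))
        est_e.append(np.sqrt(fit.sigma2_error))
    assert abs(np.median(est_s) - 0.5) < 0.1
    assert abs(np.median(est_e) - 0.2) < 0.04


def test_expanded_inseparable_variance_components_rejected():
    table = two_condition_table(n_per_group=1, n_features=1, L=1, seed=3)
    design = pl.infer_design(table)
    spec = build_model_spec(table.protein_data("P"), design, scope="expanded")
    with pytest.raises(ValueError):
        fit_expanded(table.protein_data("P"), spec)


# -- loess weighting --------------------------------------------------------

def test_loess_homoscedastic_weights_stay_flat():
    table, _ = pl.generate_factorial(n_proteins=1, features_range=(6, 6),
                                     sigma_error=0.3, sigma_subject=0.0,
                                     feature_sd=2.0, seed=21)
    design = pl.infer_design(table)
    pdata = table.protein_data(table.proteins[0])
    spec = build_model_spec(pdata, design)
    fit0 = fit_reduced(pdata, spec)
    fit = loess_weight_fit(pdata, spec)
    w = fit.weights.to_numpy()
    assert w.max() / w.min() < 3.0
    assert np.max(np.abs(fit.params - fit0.params)) < 0.05


def test_loess_heteroscedastic_weights_decrease_with_mean():
    table, _ = pl.generate_factorial(n_proteins=1, features_range=(8, 8),
                                     sigma_error=0.25, sigma_subject=0.0,
                                     feature_sd=2.0, error_sd_slope=0.25,
                                     seed=22)
    design = pl.infer_design(table)
    pdata = table.protein_data(table.proteins[0])
    spec = build_model_spec(pdata, design)
    fit = loess_weight_fit(pdata, spec)
    rho = stats.spearmanr(fit.fitted.to_numpy(), fit.weights.to_numpy())[0]
    assert rho < -0.3


def test_loess_tol_inf_single_refit(factorial):
    table, _, design = factorial
    pdata = table.protein_data(table.proteins[2])
    spec = build_model_spec(pdata, design)
    fit = loess_weight_fit(pdata, spec, tol=np.inf, max_iter=10)
    assert len(fit.weight_trace) == 1


# -- estimator wrapper ------------------------------------------------------

def test_protein_linear_model_estimator(factorial):
    table, _, design = factorial
    est = pl.ProteinLinearModel(scope="reduced", weighting=False)
    assert est.get_params()["scope"] == "reduced"
    est.set_params(scope="expanded")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(table.protein_data(table.proteins[0]), design)
    assert est.sigma2_subject_ is not None
    assert est.df_residual_ > 0
    res = est.test(pl.ComparisonSpec(
        "x", {design.conditions[0]: 1, design.conditions[1]: -1}))
    assert np.isfinite(res.p)
    with pytest.raises(ValueError):
        est.set_params(bogus=1)
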