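"""Contrast-based significance analysis of per-protein fits.

A biological comparison is a contrast over condition means: a map
condition -> coefficient summing to zero (e.g. +1/-1 for a pairwise
comparison, or +-1/2 to average over two levels of another factor).  Each
condition mean is itself a linear combination of the model parameters —
the condition effect plus the average over the protein's features (and,
in the reduced scope, over the observed biological replicates).  The
contrast estimate is tested with a Student t statistic:

    t = (c' b) / sqrt(c' Cov(b) c)

against the residual degrees of freedom (reduced scope) or a
Satterthwaite approximation (expanded scope), and p-values are adjusted
per comparison across proteins with the Benjamini-Hochberg step-up
procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ProteinFit, satterthwaite_df


class UntestableError(ValueError):
    """A referenced condition is not estimable in this fit."""


@dataclass
class ComparisonSpec:
    """A contrast over condition means.

    ``condition_coefficients`` must sum to zero and contain at least one
    positive and one negative coefficient.
    """

    label: str
    condition_coefficients: dict

    def __post_init__(self):
        coefs = np.array(list(self.condition_coefficients.values()), float)
        if len(coefs) < 2 or abs(coefs.sum()) > 1e-9:
            raise ValueError(
                f"comparison {self.label!r}: coefficients must sum to 0 "
                f"(got {coefs.sum():g})"
            )
        if not ((coefs > 0).any() and (coefs < 0).any()):
            raise ValueError(
                f"comparison {self.label!r}: need at least one positive and "
                "one negative coefficient"
            )


@dataclass
class ComparisonResult:
    protein: str
    label: str
    estimate: float
    se: float
    t: float
    df: float
    p: float
    adj_p: float = None
    status: str = "ok"
    flags: list = field(default_factory=list)


def condition_mean_vector(fit: ProteinFit, condition: str) -> pd.Series:
    """Linear combination giving the condition mean, averaged over the
    protein's features and (reduced scope) the observed replicates."""
    spec = fit.spec
    if condition in fit.untestable_conditions or condition not in spec.conditions:
        raise UntestableError(
            f"protein {fit.protein}: condition {condition!r} not estimable"
        )
    c = pd.Series(0.0, index=fit.params.index)
    c["Intercept"] = 1.0
    name = f"C[{condition}]"
    if name in c.index:
        c[name] = 1.0
    I = len(spec.features)
    if spec.has_feature_terms:
        for f in spec.features[1:]:
            nm = f"F[{f}]"
            if nm in c.index:
                c[nm] = 1.0 / I
            if spec.has_interaction:
                nm = f"FC[{f}|{condition}]"
                if nm in c.index:  # dropped (aliased) interactions are pinned to 0
                    c[nm] = 1.0 / I
    if spec.has_subject_terms:
        subs = spec.subjects_by_condition.get(condition, [])
        if subs:
            if spec.repeated_measures:
                for s in subs:
                    nm = f"S[{s}]"
                    if nm in c.index:
                        c[nm] = 1.0 / len(subs)
            else:
                for s in subs[1:]:
                    nm = f"S[{condition}|{s}]"
                    if nm in c.index:
                        c[nm] = 1.0 / len(subs)
    return c


def subject_mean_vector(fit: ProteinFit, subject: str) -> pd.Series:
    """Linear combination giving one biological replicate's expected
    log-abundance (condition mean with that subject's effect)."""
    spec = fit.spec
    conds = [cc for cc, subs in spec.subjects_by_condition.items() if subject in subs]
    if not conds:
        raise KeyError(f"protein {fit.protein}: unknown subject {subject!r}")
    vec = pd.Series(0.0, index=fit.params.index)
    for cond in conds:
        base = condition_mean_vector(fit, cond)
        # replace the subject average by this subject's own effect
        if spec.has_subject_terms:
            subs = spec.subjects_by_condition[cond]
            if spec.repeated_measures:
                for s in subs:
                    nm = f"S[{s}]"
                    if nm in base.index:
                        base[nm] = 0.0
                nm = f"S[{subject}]"
                if nm in base.index:
                    base[nm] = 1.0
            else:
                for s in subs[1:]:
                    nm = f"S[{cond}|{s}]"
                    if nm in base.index:
                        base[nm] = 0.0
                nm = f"S[{cond}|{subject}]"
                if nm in base.index:
                    base[nm] = 1.0
        vec = vec + base / len(conds)
    return vec


def make_contrast(comparison: ComparisonSpec, fit: ProteinFit) -> pd.Series:
    """Contrast vector over the model parameters.

    ``c' theta`` equals the requested contrast of condition means; raises
    :class:`UntestableError` when a referenced condition is aliased or
    unobserved for this protein.
    """
    c = pd.Series(0.0, index=fit.params.index)
    for cond, coef in comparison.condition_coefficients.items():
        if coef == 0:
            continue
        c = c + coef * condition_mean_vector(fit, cond)
    return c


def test_contrast(fit: ProteinFit, comparison: ComparisonSpec) -> ComparisonResult:
    """Estimate, standard error, t, df and two-sided p for one contrast."""
    try:
        c = make_contrast(comparison, fit)
    except UntestableError:
        return ComparisonResult(fit.protein, comparison.label,
                                math.nan, math.nan, math.nan, math.nan,
                                math.nan, status="untestable")
    cv = c.to_numpy()
    est = float(cv @ fit.params.to_numpy())
    var = float(cv @ fit.cov.to_numpy() @ cv)
    se = math.sqrt(max(var, 0.0))
    if fit.scope == "expanded":
        df = satterthwaite_df(fit, cv)
    else:
        df = fit.df_residual
    if se > 0 and df > 0:
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df)
        return ComparisonResult(fit.protein, comparison.label, est, se,
                                float(t), float(df), float(p))
    # noise-free / saturated degenerate case
    p = 0.0 if abs(est) > 1e-12 else 1.0
    return ComparisonResult(fit.protein, comparison.label, est, 0.0,
                            math.nan, float(df), p, status="degenerate")


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return p
    adj = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adj


def results_to_frame(results) -> pd.DataFrame:
    rows = [{
        "Protein": r.protein,
        "Label": r.label,
        "log2FC": r.estimate,
        "SE": r.se,
        "Tvalue": r.t,
        "DF": r.df,
        "pvalue": r.p,
        "adj.pvalue": r.adj_p,
        "status": ";".join([r.status] + list(r.flags)) if r.flags else r.status,
    } for r in results]
    return pd.DataFrame(rows)


def compare_proteins(fits: dict, comparisons) -> pd.DataFrame:
    """Test every comparison on every fitted protein.

    FDR is controlled separately per comparison label across proteins.
    Returns the canonical result table (one row per protein x label).
    """
    if isinstance(comparisons, ComparisonSpec):
        comparisons = [comparisons]
    results = []
    for comp in comparisons:
        batch = [test_contrast(fit, comp) for _, fit in sorted(fits.items())]
        adj = adjust_fdr([np.nan if r.status == "untestable" else r.p
                          for r in batch])
        for r, a in zip(batch, adj):
            r.adj_p = float(a) if np.isfinite(a) else math.nan
        results.extend(batch)
    return results_to_frame(results)
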