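"""Power and sample-size calculations for balanced future designs.

For a pairwise comparison of condition means in a balanced design with
I features, J conditions, K biological and L technical replicates per
condition, the minimal detectable log fold change under the reduced scope
satisfies

    delta^2 >= sigma_Error^2 / (I K L) * (t_{1-beta, df} + t_{1-alpha/2, df})^2

with df = I J K (L - 1) + (I - 1) J (K - 1), where the per-comparison
significance level alpha is derived from the target FDR q, the average
type-II error beta and the anticipated ratio of null to alternative
proteins m0/m1:

    alpha = (1 - beta) * q / (1 + (1 - q) * m0/m1)

Increasing the number of related conditions J increases df and lowers the
detectable fold change — the statistical argument for joint modeling.
The expanded-scope variant replaces the error term by
``sigma_Error^2/(IKL) + sigma_S^2/K`` with between-subject degrees of
freedom J(K-1); this is an interpretation of the supplementary variant of
the formula and is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PowerSpec:
    """Inputs of the power calculation.

    ``delta`` is the minimal detectable difference on the log scale of the
    transform (``log_base(fold change)``); leave it None when solving for
    the minimal detectable fold change at fixed K.
    """

    q: float = 0.05
    beta: float = 0.2
    delta: float = None
    m0_over_m1: float = 1.0
    sigma2_error: float = 0.09
    sigma2_subject: float = 0.0
    I: int = 2
    J: int = 2
    K: int = 2
    L: int = 1
    scope: str = "reduced"
    log_base: float = 2.0

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if self.m0_over_m1 < 0:
            raise ValueError("m0_over_m1 must be >= 0")
        if min(self.I, self.J, self.K, self.L) < 1:
            raise ValueError("I, J, K, L must be positive integers")
        if self.scope not in ("reduced", "expanded"):
            raise ValueError("scope must be 'reduced' or 'expanded'")


@dataclass
class PowerResult:
    min_detectable_delta: float = None  # log scale
    min_detectable_fc: float = None  # raw fold change
    min_K: int = None
    df: float = None
    alpha: float = None
    curve: pd.DataFrame = None


def alpha_from_fdr(q: float, beta: float, m0_over_m1: float) -> float:
    """Per-comparison significance level implied by a target FDR.

    ``alpha = (1-beta) q / (1 + (1-q) m0/m1)``; with ``m0/m1 = 0`` (all
    proteins differential) this reduces to ``(1-beta) q``.
    """
    if not 0 < q < 1 or not 0 < beta < 1 or m0_over_m1 < 0:
        raise ValueError("require 0<q<1, 0<beta<1, m0_over_m1>=0")
    return (1.0 - beta) * q / (1.0 + (1.0 - q) * m0_over_m1)


def balanced_df(I: int, J: int, K: int, L: int) -> float:
    """Residual df of the balanced reduced-scope fit: IJK(L-1)+(I-1)J(K-1)."""
    return I * J * K * (L - 1) + (I - 1) * J * (K - 1)


def _df_and_variance(spec: PowerSpec):
    if spec.scope == "expanded":
        df = spec.J * (spec.K - 1)
        var = spec.sigma2_error / (spec.I * spec.K * spec.L) \
            + spec.sigma2_subject / spec.K
    else:
        df = balanced_df(spec.I, spec.J, spec.K, spec.L)
        var = spec.sigma2_error / (spec.I * spec.K * spec.L)
    return float(df), float(var)


def min_detectable_fc(spec: PowerSpec) -> PowerResult:
    """Lower bound on the detectable log fold change for a fixed design."""
    df, var = _df_and_variance(spec)
    if df < 1:
        raise ValueError(
            f"design I={spec.I}, J={spec.J}, K={spec.K}, L={spec.L} "
            f"({spec.scope} scope) leaves {df:g} degrees of freedom (< 1)"
        )
    alpha = alpha_from_fdr(spec.q, spec.beta, spec.m0_over_m1)
    delta = math.sqrt(var) * (stats.t.ppf(1 - spec.beta, df)
                              + stats.t.ppf(1 - alpha / 2.0, df))
    return PowerResult(
        min_detectable_delta=float(delta),
        min_detectable_fc=float(spec.log_base ** delta),
        df=df,
        alpha=alpha,
    )


def min_sample_size(spec: PowerSpec, k_max: int = 1000) -> PowerResult:
    """Smallest K whose minimal detectable change is <= the target delta.

    ``spec.delta`` is the target difference on the log scale.  Also
    returns the delta-versus-K curve up to the solution (or ``k_max``).
    If no K up to ``k_max`` suffices, ``min_K`` is None and the curve is
    still returned.
    """
    if spec.delta is None or spec.delta <= 0:
        raise ValueError("spec.delta (target log fold change) must be > 0")
    rows = []
    found = None
    last = None
    for k in range(1, k_max + 1):
        trial = replace(spec, K=k, delta=None)
        try:
            res = min_detectable_fc(trial)
        except ValueError:  # df < 1 at this K
            continue
        rows.append({"K": k, "min_detectable_delta": res.min_detectable_delta,
                     "min_detectable_fc": res.min_detectable_fc,
                     "df": res.df})
        last = res
        if found is None and res.min_detectable_delta <= spec.delta + 1e-12:
            found = (k, res)
            break
    curve = pd.DataFrame(rows)
    if found is None:
        return PowerResult(min_K=None, curve=curve,
                           alpha=last.alpha if last else None)
    k, res = found
    return PowerResult(min_K=k, min_detectable_delta=res.min_detectable_delta,
                       min_detectable_fc=res.min_detectable_fc,
                       df=res.df, alpha=res.alpha, curve=curve)


def power_defaults_from_analysis(fits: dict, results: pd.DataFrame = None,
                                 q: float = 0.05) -> dict:
    """Derive data-driven power inputs from a fitted analysis.

    ``sigma2_error`` (and ``sigma2_subject``) are the median estimates
    over proteins; ``m0_over_m1`` is the observed ratio of non-significant
    to significant proteins at FDR ``q`` (floored at 1); ``I`` is the
    median feature count.
    """
    s2 = [f.sigma2_error for f in fits.values() if f.sigma2_error > 0]
    out = {
        "sigma2_error": float(np.median(s2)) if s2 else 0.0,
        "I": int(np.median([len(f.spec.features) for f in fits.values()])),
    }
    s2s = [f.sigma2_subject for f in fits.values()
           if f.sigma2_subject is not None]
    if s2s:
        out["sigma2_subject"] = float(np.median(s2s))
    if results is not None and "adj.pvalue" in results:
        adj = pd.to_numeric(results["adj.pvalue"], errors="coerce").dropna()
        n_sig = int((adj < q).sum())
        n_null = int((adj >= q).sum())
        out["m0_over_m1"] = float(max(1.0, n_null / n_sig)) if n_sig else float(len(adj))
    return out
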