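"""Model-based protein quantification with confidence intervals.

The expected log-abundance of a protein in a condition (averaged over the
protein's features and, in the reduced scope, the observed replicates) or
in a single biological replicate is a linear combination of the model
parameters; its standard error follows from the coefficient covariance
and the confidence interval uses the same Student-t degrees of freedom as
significance testing.  Estimates are on the log scale of the transform
and are comparable across conditions and samples within a protein, not
between proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CONDITION, FEATURE, LOG_INTENSITY, RUN
from .inference import UntestableError, condition_mean_vector, subject_mean_vector
from .model import ProteinFit, satterthwaite_df


@dataclass
class QuantResult:
    protein: str
    target: str
    target_type: str  # "condition" | "subject"
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    n_missing_cells: int
    status: str = "ok"


def _interval(fit: ProteinFit, cv: np.ndarray, level: float):
    est = float(cv @ fit.params.to_numpy())
    var = float(cv @ fit.cov.to_numpy() @ cv)
    se = math.sqrt(max(var, 0.0))
    if fit.scope == "expanded":
        df = satterthwaite_df(fit, cv)
    else:
        df = fit.df_residual
    if se > 0 and df > 0:
        half = stats.t.ppf(0.5 + level / 2.0, df) * se
    else:
        half = 0.0
    return est, se, est - half, est + half


def _missing_cells(fit: ProteinFit, condition: str) -> int:
    """Missing (feature, run) cells of this protein within the condition."""
    if fit.data is None:
        return 0
    d = fit.data[fit.data[CONDITION] == condition]
    runs = d[RUN].nunique()
    expected = len(fit.spec.features) * runs
    observed = int(d[LOG_INTENSITY].notna().sum())
    return max(expected - observed, 0)


def quantify_condition(fit: ProteinFit, condition: str,
                       level: float = 0.95) -> QuantResult:
    """Expected log-abundance in one condition, with a t-based CI."""
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    try:
        c = condition_mean_vector(fit, condition)
    except UntestableError:
        return QuantResult(fit.protein, condition, "condition",
                           math.nan, math.nan, math.nan, math.nan,
                           level, 0, status="untestable")
    est, se, lo, hi = _interval(fit, c.to_numpy(), level)
    return QuantResult(fit.protein, condition, "condition", est, se, lo, hi,
                       level, _missing_cells(fit, condition))


def quantify_sample(fit: ProteinFit, subject: str,
                    level: float = 0.95) -> QuantResult:
    """Expected log-abundance in one biological replicate.

    Reduced scope: the condition mean with the subject's own (fixed)
    effect.  Expanded scope: the condition mean shifted by the BLUP
    (conditional mean) of the subject's random effect; with
    ``sigma_S^2 = 0`` this collapses to the condition estimate.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    spec = fit.spec
    conds = [c for c, subs in spec.subjects_by_condition.items() if subject in subs]
    if not conds:
        raise KeyError(f"protein {fit.protein}: unknown subject {subject!r}")
    if fit.scope == "expanded":
        cv = pd.Series(0.0, index=fit.params.index)
        for cond in conds:
            cv = cv + condition_mean_vector(fit, cond) / len(conds)
        est, se, lo, hi = _interval(fit, cv.to_numpy(), level)
        shift = _blup_shift(fit, subject)
        return QuantResult(fit.protein, subject, "subject",
                           est + shift, se, lo + shift, hi + shift, level,
                           sum(_missing_cells(fit, c) for c in conds))
    cv = subject_mean_vector(fit, subject)
    est, se, lo, hi = _interval(fit, cv.to_numpy(), level)
    return QuantResult(fit.protein, subject, "subject", est, se, lo, hi,
                       level, sum(_missing_cells(fit, c) for c in conds))


def _blup_shift(fit: ProteinFit, subject: str) -> float:
    """Conditional-mean (BLUP) estimate of the subject's random effect."""
    if not fit.sigma2_subject:
        return 0.0
    from .dataio import SUBJECT

    obs = fit.data[fit.data[LOG_INTENSITY].notna()]
    rows = obs[SUBJECT].to_numpy() == subject
    n_s = int(rows.sum())
    if n_s == 0:
        return 0.0
    fixed = fit._X[rows] @ fit.params.to_numpy()
    resid = obs.loc[rows, LOG_INTENSITY].to_numpy() - fixed
    shrink = n_s * fit.sigma2_subject / (fit.sigma2_error + n_s * fit.sigma2_subject)
    return float(shrink * resid.mean())


def quantify_proteins(fits: dict, targets: str = "condition",
                      level: float = 0.95) -> pd.DataFrame:
    """Quantify every protein in every condition (or biological replicate).

    Returns the canonical TSV schema: Protein, Target, TargetType,
    Estimate, SE, CIlow, CIhigh, Level, NMissing, status.
    """
    rows = []
    for _, fit in sorted(fits.items()):
        if targets == "condition":
            items = [(quantify_condition(fit, c, level))
                     for c in fit.spec.conditions]
        elif targets == "subject":
            subs = sorted({s for ss in fit.spec.subjects_by_condition.values()
                           for s in ss})
            items = [quantify_sample(fit, s, level) for s in subs]
        else:
            raise ValueError("targets must be 'condition' or 'subject'")
        rows.extend(items)
    return pd.DataFrame([{
        "Protein": r.protein,
        "Target": r.target,
        "TargetType": r.target_type,
        "Estimate": r.estimate,
        "SE": r.se,
        "CIlow": r.ci_low,
        "CIhigh": r.ci_high,
        "Level": r.level,
        "NMissing": r.n_missing_cells,
        "status": r.status,
    } for r in rows])
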