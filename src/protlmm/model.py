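"""Per-protein linear (mixed) models for feature-level log-intensities.

One model is specified per protein.  The log-intensity of feature *i* in
condition *j*, biological replicate *k* and technical replicate *l* is
decomposed as

    y_ijkl = mu + F_i + C_j + (FxC)_ij + S(C)_k(j) + e_ijkl

with treatment (corner-point) coding: the first feature, condition and
subject are the reference cell, so the intercept is the expected
log-intensity of the first feature / first condition / first subject.
Feature terms (and the feature x condition interaction, which captures
interferences in feature profiles) are present only for proteins with at
least two features.  The subject term has two interpretations:

* reduced scope — subject effects are fixed values; conclusions are
  restricted to the observed biological replicates.  Fitted by (weighted)
  least squares.
* expanded scope — subject effects are random draws from N(0, sigma_S^2);
  conclusions generalize to the underlying population.  Fitted by REML.

In a nested (factorial) design without technical replication and with a
single feature, the subject term is confounded with the error and is
dropped; in that degenerate case the reduced-scope analysis coincides with
classical per-condition averaging.

Heteroscedastic technical variance is handled by iterative least squares:
absolute residuals are smoothed against fitted values with a loess curve
and observations are re-weighted by the inverse squared predicted absolute
residual until the coefficients stabilize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dataio import CONDITION, FEATURE, LOG_INTENSITY, PROTEIN, SUBJECT
from .design import DesignInfo

#: smallest admissible predicted absolute residual in the loess weighting
PRED_FLOOR = 1e-6
#: smallest admissible observation weight
WEIGHT_FLOOR = 1e-6


@dataclass
class ModelSpec:
    """Resolved structure of one protein's model."""

    protein: str
    scope: str  # "reduced" | "expanded"
    features: list  # observed features, first = reference
    conditions: list  # observed conditions in design order, first = reference
    subjects_by_condition: dict  # condition -> observed subjects (design order)
    subjects: list  # global observed subjects (repeated-measures coding)
    has_feature_terms: bool
    has_interaction: bool
    has_subject_terms: bool
    repeated_measures: bool
    missing_conditions: list = field(default_factory=list)

    def __post_init__(self):
        if self.scope not in ("reduced", "expanded"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.has_interaction and not self.has_feature_terms:
            raise ValueError("interaction requires feature terms")


@dataclass
class ProteinFit:
    """A fitted per-protein model.

    ``params``/``cov`` are on the log scale of the transform.  For every
    observed cell ``fitted + residual == observed``.  ``df_residual`` is
    the residual degrees of freedom of the fixed-effects fit (reduced
    scope) or ``n - p`` for the expanded scope, where contrast-specific
    Satterthwaite degrees of freedom are used instead.
    """

    protein: str
    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    sigma2_error: float
    sigma2_subject: float  # None for reduced scope
    df_residual: float
    fitted: pd.Series
    residuals: pd.Series
    weights: pd.Series
    n_obs: int
    dropped: list = field(default_factory=list)
    untestable_conditions: set = field(default_factory=set)
    data: pd.DataFrame = None
    weight_trace: list = field(default_factory=list)
    # internals for Satterthwaite / refits
    _X: np.ndarray = None
    _y: np.ndarray = None
    _groups: np.ndarray = None

    @property
    def scope(self) -> str:
        return self.spec.scope


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

def build_model_spec(protein_data: pd.DataFrame, design: DesignInfo,
                     scope: str = "reduced", interaction: bool = True,
                     feature_terms: bool = True) -> ModelSpec:
    """Resolve the model terms for one protein's data slice.

    Feature and feature x condition terms are present iff the protein has
    at least two features and they are requested; the repeated-measures
    variant replaces the nested subject term by a global subject term to
    account for between-subject heterogeneity of the changes in time.
    """
    obs = protein_data[protein_data[LOG_INTENSITY].notna()]
    if obs.empty:
        raise ValueError("protein has no observed intensities")
    protein = str(obs[PROTEIN].iloc[0])
    features = list(pd.unique(obs[FEATURE]))
    observed_conditions = set(obs[CONDITION])
    conditions = [c for c in design.conditions if c in observed_conditions]
    missing_conditions = [c for c in design.conditions if c not in observed_conditions]
    subj_by_cond = {
        c: [s for s in design.subjects_by_condition[c]
            if ((obs[CONDITION] == c) & (obs[SUBJECT] == s)).any()]
        for c in conditions
    }
    observed_subjects = set(obs[SUBJECT])
    subjects = [s for s in design.subjects if s in observed_subjects]

    has_feature = feature_terms and len(features) >= 2
    has_inter = has_feature and interaction
    max_L = max(design.tech_reps.values())
    # subject effects identifiable unless a single feature with single runs
    identifiable = design.repeated_measures or max_L >= 2 or len(features) >= 2
    has_subject = scope == "reduced" and identifiable
    if scope == "reduced" and not identifiable:
        warnings.warn(
            f"protein {protein}: subject effects confounded with error "
            "(single feature, no technical replication); subject term dropped",
            stacklevel=2,
        )
    return ModelSpec(
        protein=protein,
        scope=scope,
        features=features,
        conditions=conditions,
        subjects_by_condition=subj_by_cond,
        subjects=subjects,
        has_feature_terms=has_feature,
        has_interaction=has_inter,
        has_subject_terms=has_subject,
        repeated_measures=design.repeated_measures,
        missing_conditions=missing_conditions,
    )


def model_terms(spec: ModelSpec) -> list:
    """Ordered design-matrix column names (priority order for aliasing)."""
    names = ["Intercept"]
    names += [f"C[{c}]" for c in spec.conditions[1:]]
    if spec.has_feature_terms:
        names += [f"F[{f}]" for f in spec.features[1:]]
    if spec.has_subject_terms:
        if spec.repeated_measures:
            names += [f"S[{s}]" for s in spec.subjects[1:]]
        else:
            for c in spec.conditions:
                names += [f"S[{c}|{s}]" for s in spec.subjects_by_condition[c][1:]]
    if spec.has_interaction:
        for f in spec.features[1:]:
            for c in spec.conditions[1:]:
                names.append(f"FC[{f}|{c}]")
    return names


def build_design_matrix(protein_data: pd.DataFrame, spec: ModelSpec,
                        include_subject: bool = None):
    """Treatment-coded design matrix for the observed rows.

    Returns ``(X, names, obs)`` where ``obs`` is the protein slice
    restricted to rows with an observed log-intensity.
    """
    obs = protein_data[protein_data[LOG_INTENSITY].notna()].copy()
    cond = obs[CONDITION].to_numpy()
    feat = obs[FEATURE].to_numpy()
    subj = obs[SUBJECT].to_numpy()
    n = len(obs)
    cols, names = [np.ones(n)], ["Intercept"]
    for c in spec.conditions[1:]:
        cols.append((cond == c).astype(float))
        names.append(f"C[{c}]")
    if spec.has_feature_terms:
        for f in spec.features[1:]:
            cols.append((feat == f).astype(float))
            names.append(f"F[{f}]")
    use_subject = spec.has_subject_terms if include_subject is None else include_subject
    if use_subject:
        if spec.repeated_measures:
            for s in spec.subjects[1:]:
                cols.append((subj == s).astype(float))
                names.append(f"S[{s}]")
        else:
            for c in spec.conditions:
                for s in spec.subjects_by_condition[c][1:]:
                    cols.append(((cond == c) & (subj == s)).astype(float))
                    names.append(f"S[{c}|{s}]")
    if spec.has_interaction:
        for f in spec.features[1:]:
            for c in spec.conditions[1:]:
                cols.append(((feat == f) & (cond == c)).astype(float))
                names.append(f"FC[{f}|{c}]")
    return np.column_stack(cols), names, obs


def _drop_aliased(X: np.ndarray, names: list):
    """Greedy full-rank column subset, in the priority order of ``names``.

    Interaction columns come last in the term order, so aliasing caused by
    missing cells is resolved by dropping interaction (then subject)
    columns before anything else.
    """
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X, names, []
    keep, kept_idx = [], []
    for j in range(X.shape[1]):
        cand = kept_idx + [j]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            kept_idx.append(j)
            keep.append(names[j])
    dropped = [nm for nm in names if nm not in keep]
    return X[:, kept_idx], keep, dropped


# ---------------------------------------------------------------------------
# reduced scope: (weighted) least squares
# ---------------------------------------------------------------------------

def fit_reduced(protein_data: pd.DataFrame, spec: ModelSpec,
                weights=None) -> ProteinFit:
    """Weighted least-squares fit of the fixed-effects model.

    Coefficient covariance is ``sigma2 * (X'WX)^-1`` with
    ``sigma2 = weighted RSS / df_residual``.  Rank-deficient designs
    (after missingness) drop aliased interaction/subject columns with a
    warning; an aliased condition column marks the condition untestable.
    """
    X, names, obs = build_design_matrix(protein_data, spec)
    y = obs[LOG_INTENSITY].to_numpy(float)
    if weights is None:
        w = np.ones(len(y))
    else:
        w = np.asarray(weights, float)
        if len(w) != len(y) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per observed row")

    X, names, dropped = _drop_aliased(X, names)
    if dropped:
        warnings.warn(
            f"protein {spec.protein}: dropped aliased columns {dropped}",
            stacklevel=2,
        )
    untestable = {nm[2:-1] for nm in dropped if nm.startswith("C[")}
    untestable |= set(spec.missing_conditions)

    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    n, p = X.shape
    df = n - p
    rss = float(np.sum(w * resid**2))
    sigma2 = rss / df if df > 0 else 0.0
    xtwx = X.T @ (w[:, None] * X)
    cov = sigma2 * np.linalg.pinv(xtwx)

    idx = obs.index
    return ProteinFit(
        protein=spec.protein,
        spec=spec,
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        sigma2_error=sigma2,
        sigma2_subject=None,
        df_residual=float(df),
        fitted=pd.Series(fitted, index=idx),
        residuals=pd.Series(resid, index=idx),
        weights=pd.Series(w, index=idx),
        n_obs=n,
        dropped=dropped,
        untestable_conditions=untestable,
        data=protein_data,
        _X=X,
        _y=y,
    )


# ---------------------------------------------------------------------------
# loess variance weighting (iterative least squares)
# ---------------------------------------------------------------------------

def _loess_weights(fit: ProteinFit, span: float):
    """Observation weights 1 / (loess-predicted |residual|)^2."""
    fitted = fit.fitted.to_numpy()
    absres = np.abs(fit.residuals.to_numpy())
    if np.allclose(fitted, fitted[0]):
        pred = np.full_like(fitted, max(absres.mean(), PRED_FLOOR))
    else:
        smoothed = lowess(absres, fitted, frac=span, it=1, return_sorted=True)
        pred = np.interp(fitted, smoothed[:, 0], smoothed[:, 1])
    pred = np.maximum(pred, PRED_FLOOR)
    w = 1.0 / pred**2
    w = w / w.mean()  # scale-free: WLS estimates are invariant to rescaling
    return np.maximum(w, WEIGHT_FLOOR)


def loess_weight_fit(protein_data: pd.DataFrame, spec: ModelSpec,
                     span: float = 0.75, max_iter: int = 10,
                     tol: float = 1e-3) -> ProteinFit:
    """Iterative least squares with loess-smoothed variance weights.

    Alternates between a weighted fit and re-estimating per-observation
    weights from a loess curve of |residual| versus fitted value, stopping
    when the maximum relative coefficient change drops below ``tol`` or
    after ``max_iter`` refits.  The iteration trace is recorded on the
    returned fit.
    """
    fit = fit_reduced(protein_data, spec)
    trace = []
    for it in range(1, max_iter + 1):
        w = _loess_weights(fit, span)
        new = fit_reduced(protein_data, spec, weights=w)
        old_b, new_b = fit.params, new.params
        common = old_b.index.intersection(new_b.index)
        delta = float(np.max(np.abs(new_b[common] - old_b[common])
                             / np.maximum(np.abs(old_b[common]), 1.0)))
        trace.append({
            "iteration": it,
            "max_rel_change": delta,
            "weight_min": float(w.min()),
            "weight_max": float(w.max()),
        })
        fit = new
        if delta < tol:
            break
    fit.weight_trace = trace
    return fit


# ---------------------------------------------------------------------------
# expanded scope: REML for the random subject intercept
# ---------------------------------------------------------------------------

def _group_sums(X, y, groups):
    """Per-subject aggregates used by the closed-form REML profile."""
    uniq, codes = np.unique(groups, return_inverse=True)
    q = len(uniq)
    p = X.shape[1]
    ns = np.bincount(codes, minlength=q).astype(float)
    xbar = np.zeros((q, p))
    ybar = np.zeros(q)
    for j in range(p):
        xbar[:, j] = np.bincount(codes, weights=X[:, j], minlength=q)
    ybar = np.bincount(codes, weights=y, minlength=q)
    return ns, xbar, ybar, codes


def _profile_pieces(lam, XtX, Xty, yty, ns, xbar, ybar):
    c = lam / (1.0 + ns * lam)
    xtwx = XtX - (xbar * c[:, None]).T @ xbar
    xtwy = Xty - xbar.T @ (c * ybar)
    ytwy = yty - float(c @ ybar**2)
    beta = np.linalg.solve(xtwx, xtwy)
    rss = ytwy - float(beta @ xtwy)
    return xtwx, beta, max(rss, 1e-300)


def _neg2_reml_profile(lam, XtX, Xty, yty, ns, xbar, ybar, n, p):
    xtwx, _, rss = _profile_pieces(lam, XtX, Xty, yty, ns, xbar, ybar)
    sigma2 = rss / (n - p)
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    return ((n - p) * np.log(sigma2) + float(np.sum(np.log1p(ns * lam)))
            + logdet + (n - p))


def fit_expanded(protein_data: pd.DataFrame, spec: ModelSpec) -> ProteinFit:
    """REML fit with a random intercept per biological replicate.

    The variance ratio lambda = sigma_S^2 / sigma_Error^2 is profiled out
    in closed form (the marginal covariance is block diagonal by subject,
    so all REML quantities have per-block expressions) and maximized by a
    1-D bounded search; sigma_S^2 is floored at zero.  If the optimum sits
    at the boundary the fit degenerates to ordinary least squares on the
    fixed effects, with a warning.
    """
    if spec.scope != "expanded":
        raise ValueError("spec.scope must be 'expanded'")
    X, names, obs = build_design_matrix(protein_data, spec, include_subject=False)
    X, names, dropped = _drop_aliased(X, names)
    untestable = {nm[2:-1] for nm in dropped if nm.startswith("C[")}
    untestable |= set(spec.missing_conditions)
    y = obs[LOG_INTENSITY].to_numpy(float)
    groups = obs[SUBJECT].to_numpy()
    n, p = X.shape

    n_subjects = len(set(groups))
    if spec.repeated_measures:
        if n_subjects < 2:
            raise ValueError("expanded scope needs at least 2 subjects")
    else:
        ks = [len(s) for s in spec.subjects_by_condition.values()]
        if min(ks) < 2:
            raise ValueError(
                "expanded scope needs at least 2 subjects per condition"
            )
    ns_all = np.bincount(np.unique(groups, return_inverse=True)[1])
    if ns_all.max() < 2:
        raise ValueError(
            "variance components not separable: every subject has a single "
            "observation (no technical replicates or extra features)"
        )

    ns, xbar, ybar, codes = _group_sums(X, y, groups)
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)

    def crit_log(u):
        return _neg2_reml_profile(10.0**u, XtX, Xty, yty, ns, xbar, ybar, n, p)

    res = minimize_scalar(crit_log, bounds=(-8.0, 4.0), method="bounded",
                          options={"xatol": 1e-8})
    at_zero = _neg2_reml_profile(0.0, XtX, Xty, yty, ns, xbar, ybar, n, p)
    if res.success and res.fun < at_zero:
        lam = float(10.0**res.x)
        if lam < 1e-7:
            lam = 0.0
    else:
        lam = 0.0
    if lam == 0.0:
        warnings.warn(
            f"protein {spec.protein}: sigma_S^2 estimated at the boundary 0; "
            "expanded fit reduces to least squares on the fixed effects",
            stacklevel=2,
        )

    xtwx, beta, rss = _profile_pieces(lam, XtX, Xty, yty, ns, xbar, ybar)
    sigma2 = rss / (n - p)
    sigma2_s = lam * sigma2
    cov = sigma2 * np.linalg.inv(xtwx)

    # conditional fitted values: fixed part + BLUP of the subject effect
    fixed = X @ beta
    resid_fixed = y - fixed
    mean_resid = np.bincount(codes, weights=resid_fixed) / ns
    shrink = ns * sigma2_s / (sigma2 + ns * sigma2_s) if sigma2_s > 0 else np.zeros_like(ns)
    blup = shrink * mean_resid
    fitted = fixed + blup[codes]

    idx = obs.index
    return ProteinFit(
        protein=spec.protein,
        spec=spec,
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        sigma2_error=float(sigma2),
        sigma2_subject=float(sigma2_s),
        df_residual=float(n - p),
        fitted=pd.Series(fitted, index=idx),
        residuals=pd.Series(y - fitted, index=idx),
        weights=pd.Series(np.ones(n), index=idx),
        n_obs=n,
        dropped=dropped,
        untestable_conditions=untestable,
        data=protein_data,
        _X=X,
        _y=y,
        _groups=codes,
    )


def _neg2_reml_theta(theta, fit: ProteinFit):
    """-2 REML log-likelihood at theta = (sigma2_error, sigma2_subject)."""
    s2, s2s = theta
    if s2 <= 0 or s2s < 0:
        return np.inf
    X, y, codes = fit._X, fit._y, fit._groups
    n, p = X.shape
    ns = np.bincount(codes).astype(float)
    xbar = np.zeros((len(ns), p))
    for j in range(p):
        xbar[:, j] = np.bincount(codes, weights=X[:, j])
    ybar = np.bincount(codes, weights=y)
    lam = s2s / s2
    xtwx, beta, rss = _profile_pieces(lam, X.T @ X, X.T @ y, float(y @ y),
                                      ns, xbar, ybar)
    logdet_v = float(np.sum((ns - 1) * np.log(s2) + np.log(s2 + ns * s2s)))
    sign, logdet_x = np.linalg.slogdet(xtwx / s2)
    if sign <= 0:
        return np.inf
    return logdet_v + logdet_x + rss / s2


def satterthwaite_df(fit: ProteinFit, c: np.ndarray) -> float:
    """Satterthwaite degrees of freedom for the contrast variance c'Cov(b)c.

    Delta-method df = 2 g^2 / (grad g' A grad g) with g the contrast
    variance as a function of the variance components and A the inverse
    observed REML information (finite differences).  Falls back to the
    residual df ``n - p`` when the subject variance sits at the boundary
    or the information matrix is degenerate.
    """
    n, p = fit._X.shape
    fallback = float(n - p)
    s2, s2s = fit.sigma2_error, fit.sigma2_subject
    if not s2s or s2s <= 0:
        return fallback

    X, codes = fit._X, fit._groups
    ns = np.bincount(codes).astype(float)
    xbar = np.zeros((len(ns), p))
    for j in range(p):
        xbar[:, j] = np.bincount(codes, weights=X[:, j])

    def g(theta):
        t2, t2s = theta
        lam = t2s / t2
        cc = lam / (1.0 + ns * lam)
        xtwx = X.T @ X - (xbar * cc[:, None]).T @ xbar
        covb = t2 * np.linalg.inv(xtwx)
        return float(c @ covb @ c)

    theta = np.array([s2, s2s])
    h = np.maximum(1e-8, 1e-5 * theta)
    grad = np.array([
        (g(theta + e) - g(theta - e)) / (2 * e[i])
        for i, e in enumerate(np.diag(h))
    ])
    # observed REML information by central finite differences
    H = np.zeros((2, 2))
    f0 = _neg2_reml_theta(theta, fit)
    if not np.isfinite(f0):
        return fallback
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            fpp = _neg2_reml_theta(theta + ei + ej, fit)
            fpm = _neg2_reml_theta(theta + ei - ej, fit)
            fmp = _neg2_reml_theta(theta - ei + ej, fit)
            fmm = _neg2_reml_theta(theta - ei - ej, fit)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j]) / 2.0
    try:
        A = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return fallback
    denom = float(grad @ A @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return fallback
    df = 2.0 * g(theta) ** 2 / denom
    return float(np.clip(df, 1.0, fallback))


# ---------------------------------------------------------------------------
# convenience dispatch and sklearn-style estimator
# ---------------------------------------------------------------------------

def fit_protein(protein_data: pd.DataFrame, design: DesignInfo,
                scope: str = "reduced", interaction: bool = True,
                feature_terms: bool = True, weighting: bool = False,
                span: float = 0.75, max_iter: int = 10,
                tol: float = 1e-3) -> ProteinFit:
    """Build the model spec for one protein and fit it under ``scope``."""
    spec = build_model_spec(protein_data, design, scope=scope,
                            interaction=interaction, feature_terms=feature_terms)
    if scope == "expanded":
        try:
            return fit_expanded(protein_data, spec)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"protein {spec.protein}: expanded fit failed; "
                "falling back to reduced scope with sigma_S^2 = 0"
            )
            red = ModelSpec(**{**spec.__dict__, "scope": "reduced"})
            return fit_reduced(protein_data, red)
    if weighting:
        return loess_weight_fit(protein_data, spec, span=span,
                                max_iter=max_iter, tol=tol)
    return fit_reduced(protein_data, spec)


class ProteinLinearModel:
    """Sklearn-style estimator wrapping the per-protein model fit.

    Parameters mirror :func:`fit_protein`; after :meth:`fit` the result is
    exposed as ``fit_`` (a :class:`ProteinFit`) plus convenience
    attributes ``params_``, ``sigma2_error_``, ``sigma2_subject_`` and
    ``df_residual_``.
    """

    def __init__(self, scope="reduced", interaction=True, feature_terms=True,
                 weighting=False, span=0.75, max_iter=10, tol=1e-3):
        self.scope = scope
        self.interaction = interaction
        self.feature_terms = feature_terms
        self.weighting = weighting
        self.span = span
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("scope", "interaction", "feature_terms", "weighting",
                 "span", "max_iter", "tol")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, protein_data: pd.DataFrame, design: DesignInfo):
        self.fit_ = fit_protein(
            protein_data, design, scope=self.scope,
            interaction=self.interaction, feature_terms=self.feature_terms,
            weighting=self.weighting, span=self.span,
            max_iter=self.max_iter, tol=self.tol,
        )
        self.params_ = self.fit_.params
        self.sigma2_error_ = self.fit_.sigma2_error
        self.sigma2_subject_ = self.fit_.sigma2_subject
        self.df_residual_ = self.fit_.df_residual
        return self

    def test(self, comparison):
        from .inference import test_contrast
        return test_contrast(self.fit_, comparison)

    def quantify_condition(self, condition, level=0.95):
        from .quantify import quantify_condition
        return quantify_condition(self.fit_, condition, level=level)

    def quantify_sample(self, subject, level=0.95):
        from .quantify import quantify_sample
        return quantify_sample(self.fit_, subject, level=level)
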