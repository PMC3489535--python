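"""Reading, validation and normalization of long-format quantification tables.

The canonical input is a delimited text file with one row per quantified
LC-MS feature per run:

    ProteinName, FeatureName, <factor columns...> (or Condition),
    BioReplicate, Run, Intensity

``Intensity`` is on the raw scale and strictly positive where present;
an empty cell (or an absent row) marks a missing peak.  The condition label
of a run is the cross of its factor levels joined by ``:`` in declared
factor order.  Log transformation (default base 2, so that contrast
estimates read as log2 fold changes) and two normalizations are provided:

* constant normalization — per-run additive shift on the log scale that
  equalizes run medians (median-of-medians reference), preserving all
  within-run differences;
* quantile normalization — the r-th smallest value within each run is
  replaced by the mean of the r-th smallest values over runs; requires a
  complete table with equally sized runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: canonical column names
PROTEIN = "ProteinName"
FEATURE = "FeatureName"
CONDITION = "Condition"
SUBJECT = "BioReplicate"
RUN = "Run"
INTENSITY = "Intensity"
LOG_INTENSITY = "LogIntensity"

REQUIRED_COLUMNS = (PROTEIN, FEATURE, SUBJECT, RUN, INTENSITY)

_LOG_BASES = {2: math.log(2.0), 10: math.log(10.0), "e": 1.0, "2": math.log(2.0), "10": math.log(10.0)}


@dataclass
class FeatureTable:
    """Long-format feature-level quantification table.

    Attributes
    ----------
    data : pandas.DataFrame
        One row per (protein, feature, run); missing peaks are rows with
        NaN intensity.  Carries the canonical columns plus any factor
        columns; ``Condition`` is always present.
    factor_columns : list of str
        Names of the design-factor columns; empty when the input carried a
        single ``Condition`` column.
    log_base : int | str | None
        Base of the log transform (2, 10 or "e"); None before transform.
    normalization : str
        "none", "constant" or "quantile"; recorded for output metadata.
    """

    data: pd.DataFrame
    factor_columns: list = field(default_factory=list)
    log_base: object = None
    normalization: str = "none"

    # -- convenience ------------------------------------------------------
    @property
    def proteins(self):
        return list(pd.unique(self.data[PROTEIN]))

    @property
    def runs(self):
        return list(pd.unique(self.data[RUN]))

    @property
    def conditions(self):
        return list(pd.unique(self.data[CONDITION]))

    def protein_data(self, protein) -> pd.DataFrame:
        sub = self.data[self.data[PROTEIN] == protein]
        if sub.empty:
            raise KeyError(f"unknown protein {protein!r}")
        return sub

    def with_data(self, data: pd.DataFrame) -> "FeatureTable":
        return replace(self, data=data)

    def summary(self) -> dict:
        """Dimension report: proteins, features per protein, runs."""
        n_feat = self.data.groupby(PROTEIN, sort=False)[FEATURE].nunique()
        return {
            "n_proteins": int(self.data[PROTEIN].nunique()),
            "n_features": int(self.data.groupby([PROTEIN, FEATURE], sort=False).ngroups),
            "n_runs": int(self.data[RUN].nunique()),
            "n_conditions": int(self.data[CONDITION].nunique()),
            "features_per_protein_min": int(n_feat.min()),
            "features_per_protein_max": int(n_feat.max()),
            "n_missing_cells": int(self.data[INTENSITY].isna().sum()),
        }


def _validate(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=[PROTEIN, FEATURE, RUN])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            "duplicate (protein, feature, run) triple: "
            f"({row[PROTEIN]!r}, {row[FEATURE]!r}, {row[RUN]!r})"
        )
    bad = df[INTENSITY].notna() & (df[INTENSITY] <= 0)
    if bad.any():
        row = df.loc[bad.idxmax()]
        raise ValueError(
            f"non-positive intensity {row[INTENSITY]} for "
            f"({row[PROTEIN]!r}, {row[FEATURE]!r}, {row[RUN]!r}); "
            "intensities must be > 0 on the raw scale"
        )
    # each run must map to exactly one (condition, subject)
    per_run = df.groupby(RUN)[[CONDITION, SUBJECT]].nunique()
    multi = per_run[(per_run > 1).any(axis=1)]
    if not multi.empty:
        raise ValueError(
            f"run {multi.index[0]!r} maps to more than one condition or subject"
        )


def make_feature_table(df: pd.DataFrame, factor_columns=None, log_base=None,
                       normalization="none") -> FeatureTable:
    """Build a validated FeatureTable from an in-memory data frame."""
    df = df.copy()
    factor_columns = list(factor_columns or [])
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    if factor_columns:
        absent = [c for c in factor_columns if c not in df.columns]
        if absent:
            raise ValueError(f"factor columns not in table: {absent}")
        df[CONDITION] = df[factor_columns].astype(str).agg(":".join, axis=1)
    elif CONDITION not in df.columns:
        raise ValueError("either a Condition column or factor_columns is required")
    df[INTENSITY] = pd.to_numeric(df[INTENSITY], errors="coerce")
    for col in (PROTEIN, FEATURE, CONDITION, SUBJECT, RUN):
        df[col] = df[col].astype(str)
    _validate(df)
    return FeatureTable(df.reset_index(drop=True), factor_columns, log_base, normalization)


def read_quant_table(path, factor_columns=None) -> FeatureTable:
    """Read a delimited quantification table (CSV or TSV by extension).

    Rows with an empty intensity cell are retained as missing peaks.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df[INTENSITY] = df[INTENSITY].replace("", np.nan)
    if LOG_INTENSITY in df.columns:
        df[LOG_INTENSITY] = pd.to_numeric(df[LOG_INTENSITY].replace("", np.nan))
    return make_feature_table(df, factor_columns=factor_columns)


def write_quant_table(table: FeatureTable, path) -> None:
    """Write the table in the canonical schema (explicit empty cells)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.data.to_csv(path, sep=sep, index=False, na_rep="")


def log_transform(table: FeatureTable, base=2) -> FeatureTable:
    """Add ``LogIntensity = log_base(Intensity)``; missing stays missing."""
    if base not in _LOG_BASES:
        raise ValueError(f"unsupported log base {base!r}; use 2, 10 or 'e'")
    df = table.data.copy()
    df[LOG_INTENSITY] = np.log(df[INTENSITY].astype(float)) / _LOG_BASES[base]
    return replace(table, data=df, log_base=base)


def _require_log(table: FeatureTable) -> None:
    if LOG_INTENSITY not in table.data.columns:
        raise ValueError("table must be log-transformed first (log_transform)")


class ConstantNormalizer(BaseEstimator, TransformerMixin):
    """Per-run median (or mean) equalization on the log scale.

    Each run's log-intensities are shifted by a constant so that every run
    attains the same location, taken as the median (default) or mean of the
    per-run locations.  Shift invariance: within-run differences between
    any two cells are unchanged.

    Parameters
    ----------
    center : {"median", "mean"}
        Per-run location statistic that is equalized.

    Attributes
    ----------
    shifts_ : pandas.Series
        Additive shift applied to each run (index = run identifier).
    reference_ : float
        The common location all runs are brought to.
    """

    def __init__(self, center="median"):
        self.center = center

    def fit(self, table: FeatureTable, y=None):
        _require_log(table)
        if self.center not in ("median", "mean"):
            raise ValueError("center must be 'median' or 'mean'")
        locs = table.data.groupby(RUN, sort=False)[LOG_INTENSITY].agg(self.center)
        if locs.isna().any():
            warnings.warn(
                f"runs with all intensities missing get shift 0: "
                f"{list(locs.index[locs.isna()])}"
            )
        ref = float(getattr(locs.dropna(), self.center)()) if locs.notna().any() else 0.0
        self.reference_ = ref
        self.shifts_ = (ref - locs).fillna(0.0)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        _require_log(table)
        df = table.data.copy()
        df[LOG_INTENSITY] = df[LOG_INTENSITY] + df[RUN].map(self.shifts_).fillna(0.0).to_numpy()
        return replace(table, data=df, normalization="constant")


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization across runs on the log scale.

    Within each run the r-th smallest value is replaced by the mean over
    runs of the r-th smallest values; ranks within runs are preserved and
    ties receive the average of their reference values.  This dialect
    requires a complete table (no missing cells) with the same number of
    values in every run.

    Attributes
    ----------
    reference_ : numpy.ndarray
        Mean sorted profile (length = values per run).
    """

    def fit(self, table: FeatureTable, y=None):
        _require_log(table)
        df = table.data
        if df[LOG_INTENSITY].isna().any():
            raise ValueError("quantile normalization requires a complete table")
        counts = df.groupby(RUN, sort=False)[LOG_INTENSITY].size()
        if counts.nunique() != 1:
            raise ValueError(
                "quantile normalization requires equally sized runs; "
                f"got counts {sorted(set(counts))}"
            )
        mat = np.stack([
            np.sort(g.to_numpy()) for _, g in df.groupby(RUN, sort=False)[LOG_INTENSITY]
        ])
        self.reference_ = mat.mean(axis=0)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        _require_log(table)
        df = table.data.copy()
        ref = self.reference_

        def _map_run(vals: pd.Series) -> pd.Series:
            if len(vals) != len(ref):
                raise ValueError("run length differs from the fitted reference")
            # average rank (ties averaged), 1-based -> interpolate into ref
            ranks = vals.rank(method="average").to_numpy() - 1.0
            return pd.Series(np.interp(ranks, np.arange(len(ref)), ref), index=vals.index)

        df[LOG_INTENSITY] = df.groupby(RUN, sort=False)[LOG_INTENSITY].transform(_map_run)
        return replace(table, data=df, normalization="quantile")


def normalize_constant(table: FeatureTable, center="median") -> FeatureTable:
    """Equalize per-run medians (see :class:`ConstantNormalizer`)."""
    return ConstantNormalizer(center=center).fit(table).transform(table)


def normalize_quantile(table: FeatureTable) -> FeatureTable:
    """Quantile-normalize runs (see :class:`QuantileNormalizer`)."""
    return QuantileNormalizer().fit(table).transform(table)
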