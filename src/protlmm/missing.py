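"""Classification and treatment of missing LC-MS peaks.

The linear model tolerates scattered missing peaks as long as each
feature keeps at least one intensity in every condition.  A feature that
is missing *entirely* in one or more conditions ("condition-empty")
requires one of three treatments, applied uniformly to all affected
proteins in an analysis:

* ``impute_min`` — fill each empty (feature, condition) cell with the
  average minimum log-intensity across runs (the minimum observed
  log-intensity of each run of the experiment, averaged over runs), a
  background-abundance surrogate;
* ``no_interaction`` — keep the data but drop the feature x condition
  interaction (assume the features have no interference);
* ``remove_feature`` — drop the feature's rows entirely.

Tolerated (non-condition-empty) missing cells are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CONDITION, FEATURE, LOG_INTENSITY, PROTEIN, RUN
from .design import DesignInfo

STRATEGIES = ("impute_min", "no_interaction", "remove_feature")


@dataclass
class MissingReport:
    """Per-feature missingness pattern for one protein.

    ``counts`` maps (feature, condition) -> number of missing cells;
    ``condition_empty`` maps feature -> list of conditions in which the
    feature has no observed intensity; features absent from
    ``condition_empty`` are tolerated by the model.
    """

    protein: str
    counts: dict = field(default_factory=dict)
    condition_empty: dict = field(default_factory=dict)
    strategy: str = None

    @property
    def tolerated(self):
        feats = {f for f, _ in self.counts}
        return sorted(feats - set(self.condition_empty))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (f, c), n in sorted(self.counts.items()):
            rows.append({
                "Protein": self.protein,
                "Feature": f,
                "Condition": c,
                "NMissing": n,
                "ConditionEmpty": c in self.condition_empty.get(f, []),
            })
        return pd.DataFrame(rows)


def classify_missing(protein_data: pd.DataFrame, design: DesignInfo) -> MissingReport:
    """Label every feature tolerated or condition-empty, with counts.

    A cell is one (feature, run) slot; the expected cells of a feature in
    a condition are that condition's runs.
    """
    protein = str(protein_data[PROTEIN].iloc[0])
    runs_per_cond = {
        c: protein_data.loc[protein_data[CONDITION] == c, RUN].nunique()
        for c in design.conditions
        if (protein_data[CONDITION] == c).any()
    }
    counts, empty = {}, {}
    for f, d in protein_data.groupby(FEATURE, sort=False):
        for c, n_runs in runs_per_cond.items():
            obs = int(d.loc[d[CONDITION] == c, LOG_INTENSITY].notna().sum())
            counts[(f, c)] = max(n_runs - obs, 0)
            if obs == 0:
                empty.setdefault(f, []).append(c)
    return MissingReport(protein=protein, counts=counts, condition_empty=empty)


def min_fill_value(table_data: pd.DataFrame, pool: str = "experiment",
                   condition: str = None) -> float:
    """Average minimum log-intensity across runs.

    ``pool='experiment'`` (default) averages the per-run minima over all
    runs of the experiment; ``pool='condition'`` restricts the pool to the
    runs of ``condition``.
    """
    d = table_data[table_data[LOG_INTENSITY].notna()]
    if pool == "condition":
        if condition is None:
            raise ValueError("condition required for pool='condition'")
        d = d[d[CONDITION] == condition]
    if d.empty:
        raise ValueError("no observed intensities to derive a fill value from")
    return float(d.groupby(RUN, sort=False)[LOG_INTENSITY].min().mean())


def apply_missing_strategy(protein_data: pd.DataFrame, report: MissingReport,
                           strategy: str, table_data: pd.DataFrame = None,
                           pool: str = "experiment"):
    """Apply one treatment to the protein's condition-empty features.

    Returns ``(modified data, model flags)`` where flags is a dict with
    ``interaction`` (bool) and ``imputed`` / ``removed`` bookkeeping; the
    flags feed :func:`protlmm.model.build_model_spec`.  ``table_data``
    supplies the experiment-wide pool for the imputation value and
    defaults to the protein slice itself.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    report.strategy = strategy
    data = protein_data.copy()
    flags = {"interaction": True, "imputed_cells": 0, "removed_features": [],
             "strategy": strategy, "skip": False}
    if not report.condition_empty:
        return data, flags

    if strategy == "no_interaction":
        flags["interaction"] = False
        return data, flags

    if strategy == "remove_feature":
        bad = set(report.condition_empty)
        data = data[~data[FEATURE].isin(bad)]
        flags["removed_features"] = sorted(bad)
        if data[LOG_INTENSITY].notna().sum() == 0 or data[FEATURE].nunique() == 0:
            flags["skip"] = True
        return data, flags

    # impute_min: fill each empty (feature, condition) cell
    fill_pool = table_data if table_data is not None else protein_data
    n_filled = 0
    data["Imputed"] = False
    for f, conds in report.condition_empty.items():
        for c in conds:
            value = min_fill_value(fill_pool, pool=pool, condition=c)
            mask = (data[FEATURE] == f) & (data[CONDITION] == c) \
                & data[LOG_INTENSITY].isna()
            data.loc[mask, LOG_INTENSITY] = value
            data.loc[mask, "Imputed"] = True
            n_filled += int(mask.sum())
            # missing cells represented by absent rows: materialize them
            have = set(data.loc[(data[FEATURE] == f) & (data[CONDITION] == c), RUN])
            runs = data.loc[data[CONDITION] == c, [CONDITION, "BioReplicate", RUN]] \
                .drop_duplicates(RUN)
            new_rows = runs[~runs[RUN].isin(have)].copy()
            if not new_rows.empty:
                new_rows[PROTEIN] = report.protein
                new_rows[FEATURE] = f
                new_rows[LOG_INTENSITY] = value
                new_rows["Imputed"] = True
                data = pd.concat([data, new_rows], ignore_index=True)
                n_filled += len(new_rows)
    flags["imputed_cells"] = n_filled
    return data, flags
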