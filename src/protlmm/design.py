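"""Inference of the experimental design from a feature table.

The design is read off the run/condition/subject structure: a *nested*
(factorial) design has each biological replicate in exactly one condition,
while re-use of a subject identifier across conditions signals *repeated
measures* (a time course).  Technical replicates are the runs of one
(condition, subject) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .dataio import CONDITION, FeatureTable, INTENSITY, RUN, SUBJECT


@dataclass
class DesignInfo:
    """Structure of the experiment.

    Attributes
    ----------
    factors : dict
        Ordered map factor name -> level list (first-appearance order);
        empty when the input carried a single condition column.
    conditions : list
        The J condition labels in first-appearance order.
    subjects_by_condition : dict
        condition -> ordered list of subject identifiers observed there.
    subjects : list
        Global subject list (first appearance).
    tech_reps : dict
        (condition, subject) -> number of runs L of that sample.
    repeated_measures : bool
        True iff at least one subject occurs in >= 2 conditions.
    balanced : bool
        True iff all (condition, subject) cells have identical L and the
        table has no missing intensities.
    n_runs : int
    """

    factors: dict = field(default_factory=dict)
    conditions: list = field(default_factory=list)
    subjects_by_condition: dict = field(default_factory=dict)
    subjects: list = field(default_factory=list)
    tech_reps: dict = field(default_factory=dict)
    repeated_measures: bool = False
    balanced: bool = False
    n_runs: int = 0

    @property
    def J(self) -> int:
        return len(self.conditions)

    @property
    def K(self):
        """Biological replicates per condition (dict condition -> count)."""
        return {c: len(s) for c, s in self.subjects_by_condition.items()}

    @property
    def L(self):
        """Technical replicates, as the common value if uniform else a dict."""
        vals = set(self.tech_reps.values())
        return next(iter(vals)) if len(vals) == 1 else dict(self.tech_reps)

    def runs_per_condition(self) -> dict:
        return {
            c: sum(l for (cc, _), l in self.tech_reps.items() if cc == c)
            for c in self.conditions
        }


def infer_design(table: FeatureTable) -> DesignInfo:
    """Infer factors, conditions, subjects and replication from the table.

    Raises
    ------
    ValueError
        If only one condition is present (no comparison possible) or a
        subject identifier is missing.
    """
    df = table.data
    if df[SUBJECT].isna().any() or (df[SUBJECT] == "").any():
        raise ValueError("every row needs a biological-replicate identifier")
    conditions = list(pd.unique(df[CONDITION]))
    if len(conditions) < 2:
        raise ValueError(
            f"only {len(conditions)} condition present: no comparison possible"
        )
    factors = {
        c: list(pd.unique(df[c].astype(str))) for c in table.factor_columns
    }

    runs = df.drop_duplicates(RUN)[[RUN, CONDITION, SUBJECT]]
    subjects = list(pd.unique(runs[SUBJECT]))
    subjects_by_condition = {
        c: list(pd.unique(runs.loc[runs[CONDITION] == c, SUBJECT]))
        for c in conditions
    }
    conditions_per_subject = runs.groupby(SUBJECT, sort=False)[CONDITION].nunique()
    repeated = bool((conditions_per_subject > 1).any())

    tech = runs.groupby([CONDITION, SUBJECT], sort=False)[RUN].nunique()
    tech_reps = {idx: int(v) for idx, v in tech.items()}
    same_L = len(set(tech_reps.values())) == 1
    runs_per_cond = runs.groupby(CONDITION, sort=False)[RUN].nunique()
    balanced = (same_L and runs_per_cond.nunique() == 1
                and not df[INTENSITY].isna().any())

    if set(tech_reps.values()) == {1} and not repeated:
        warnings.warn(
            "no technical replication (L=1): under the reduced scope, "
            "biological variation is confounded with technical variation",
            stacklevel=2,
        )
    return DesignInfo(
        factors=factors,
        conditions=conditions,
        subjects_by_condition=subjects_by_condition,
        subjects=subjects,
        tech_reps=tech_reps,
        repeated_measures=repeated,
        balanced=balanced,
        n_runs=int(runs[RUN].nunique()),
    )
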