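"""Synthetic feature tables with known ground truth.

Two generators emulate the study archetypes the framework targets:

* :func:`generate_factorial` — a 2x2x2 full factorial (cell line x
  oxygen x exposure time), 2 biological replicates per condition and 3
  technical replicates per sample (8 x 2 x 3 = 48 runs), proteins with
  2-19 features;
* :func:`generate_timecourse` — repeated measures on 14 disease subjects
  over several weeks (with dropout) combined with 29 control subjects
  sampled once (43 subjects), single runs per sample, a complete
  intensity matrix with a constant noise floor standing in for absent
  peaks.

Cells are generated from the same model the package fits: condition mean
+ feature offset + subject effect + Normal error, on the log2 scale (the
raw ``Intensity`` column is ``2**LogIntensity``).  The accompanying
:class:`SimTruth` ledger records every generative component, so the
expected value of each cell is fully determined.  Error magnitudes are
not taken from any published dataset; the defaults (sigma_Error = 0.3,
sigma_S = 0.3 on the log2 scale) are chosen as realistic for desk-scale
power studies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import (CONDITION, FEATURE, INTENSITY, LOG_INTENSITY, PROTEIN,
                     RUN, SUBJECT, FeatureTable)

FACTORIAL_FACTORS = {
    "CellLine": ["low", "high"],
    "Oxygen": ["normoxia", "hypoxia"],
    "Time": ["6", "24"],
}


@dataclass
class SimTruth:
    """Ground-truth ledger of a generated table."""

    proteins: pd.DataFrame  # Protein, differential, delta, base
    condition_means: pd.DataFrame  # Protein, Condition, mean (incl. effect)
    feature_offsets: pd.DataFrame  # Protein, Feature, offset
    subject_effects: pd.DataFrame  # Protein, BioReplicate, effect
    config: dict = field(default_factory=dict)
    seed: int = None

    def condition_mean(self, protein, condition) -> float:
        cm = self.condition_means
        row = cm[(cm[PROTEIN] == protein) & (cm[CONDITION] == condition)]
        return float(row["mean"].iloc[0])

    def expected(self, protein, feature, condition, subject) -> float:
        """Expected log2 cell value (over the measurement error)."""
        off = self.feature_offsets
        sub = self.subject_effects
        val = self.condition_mean(protein, condition)
        val += float(off.loc[(off[PROTEIN] == protein)
                             & (off[FEATURE] == feature), "offset"].iloc[0])
        hit = sub[(sub[PROTEIN] == protein) & (sub[SUBJECT] == subject)]
        if not hit.empty:
            val += float(hit["effect"].iloc[0])
        return val

    def true_logfc(self, comparison) -> pd.Series:
        """True contrast value per protein for a ComparisonSpec."""
        cm = self.condition_means.pivot(index=PROTEIN, columns=CONDITION,
                                        values="mean")
        out = pd.Series(0.0, index=cm.index)
        for cond, coef in comparison.condition_coefficients.items():
            out = out + coef * cm[cond]
        return out


def _draw_protein_effects(rng, n_proteins, frac_differential, effect_sizes):
    n_diff = int(round(frac_differential * n_proteins))
    differential = np.zeros(n_proteins, bool)
    if n_diff:
        differential[rng.choice(n_proteins, size=n_diff, replace=False)] = True
    deltas = np.where(differential,
                      rng.choice(np.atleast_1d(effect_sizes), size=n_proteins),
                      0.0)
    return differential, deltas


def _error_sd(expected, base, sigma_error, slope):
    if slope == 0:
        return np.full_like(expected, sigma_error)
    return np.maximum(sigma_error * (1.0 + slope * (expected - base)), 0.02)


def generate_factorial(n_proteins: int = 100, features_range=(2, 19),
                       K: int = 2, L: int = 3,
                       sigma_error: float = 0.3, sigma_subject: float = 0.3,
                       frac_differential: float = 0.2,
                       effect_sizes=(0.5, 1.0, 2.0),
                       effect_conditions=("high:normoxia:6",),
                       baseline_mean: float = 17.0, baseline_sd: float = 1.5,
                       feature_sd: float = 2.0,
                       error_sd_slope: float = 0.0,
                       seed: int = 0):
    """Factorial-study emulator.  Returns ``(FeatureTable, SimTruth)``.

    Differential proteins receive ``+delta`` (log2) in every condition of
    ``effect_conditions``; ``error_sd_slope`` > 0 makes the error SD grow
    with the expected log-abundance (heteroscedastic option).
    """
    lo, hi = features_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid features_range {features_range}")
    if min(n_proteins, K, L) < 1:
        raise ValueError("n_proteins, K and L must be positive")
    rng = np.random.default_rng(seed)
    conditions = [":".join(levels) for levels in
                  itertools.product(*FACTORIAL_FACTORS.values())]
    bad = set(effect_conditions) - set(conditions)
    if bad:
        raise ValueError(f"unknown effect conditions {sorted(bad)}")

    subjects = {c: [f"{c}_BR{k + 1}" for k in range(K)] for c in conditions}
    runs = [(c, s, f"{s}_T{l + 1}") for c in conditions
            for s in subjects[c] for l in range(L)]

    prot_rows, cm_rows, off_rows, sub_rows, cells = [], [], [], [], []
    differential, deltas = _draw_protein_effects(
        rng, n_proteins, frac_differential, effect_sizes)
    width = len(str(n_proteins))
    for ip in range(n_proteins):
        prot = f"P{ip + 1:0{width}d}"
        base = rng.normal(baseline_mean, baseline_sd)
        n_feat = int(rng.integers(lo, hi + 1))
        feats = [f"{prot}_pep{i + 1}" for i in range(n_feat)]
        offsets = rng.normal(0.0, feature_sd, n_feat)
        sub_eff = {s: rng.normal(0.0, sigma_subject)
                   for c in conditions for s in subjects[c]}
        prot_rows.append({"Protein": prot, "differential": bool(differential[ip]),
                          "delta": float(deltas[ip]), "base": float(base)})
        for c in conditions:
            mean = base + (deltas[ip] if c in effect_conditions else 0.0)
            cm_rows.append({PROTEIN: prot, CONDITION: c, "mean": float(mean)})
        for f, o in zip(feats, offsets):
            off_rows.append({PROTEIN: prot, FEATURE: f, "offset": float(o)})
        for s, e in sub_eff.items():
            sub_rows.append({PROTEIN: prot, SUBJECT: s, "effect": float(e)})

        cond_mean = {r[CONDITION]: r["mean"] for r in cm_rows[-len(conditions):]}
        for f, o in zip(feats, offsets):
            for c, s, r in runs:
                mu = cond_mean[c] + o + sub_eff[s]
                sd = _error_sd(np.array(mu), baseline_mean, sigma_error,
                               error_sd_slope)
                val = mu + rng.normal(0.0, float(sd))
                cells.append((prot, f, c, s, r, val))

    df = pd.DataFrame(cells, columns=[PROTEIN, FEATURE, CONDITION, SUBJECT,
                                      RUN, LOG_INTENSITY])
    cl, ox, tm = zip(*(c.split(":") for c in df[CONDITION]))
    df.insert(2, "CellLine", cl)
    df.insert(3, "Oxygen", ox)
    df.insert(4, "Time", tm)
    df[INTENSITY] = 2.0 ** df[LOG_INTENSITY]
    truth = SimTruth(
        proteins=pd.DataFrame(prot_rows),
        condition_means=pd.DataFrame(cm_rows),
        feature_offsets=pd.DataFrame(off_rows),
        subject_effects=pd.DataFrame(sub_rows),
        config={"n_proteins": n_proteins, "K": K, "L": L,
                "sigma_error": sigma_error, "sigma_subject": sigma_subject,
                "frac_differential": frac_differential,
                "effect_conditions": list(effect_conditions),
                "error_sd_slope": error_sd_slope},
        seed=seed,
    )
    table = FeatureTable(df, factor_columns=["CellLine", "Oxygen", "Time"],
                         log_base=2)
    return table, truth


def generate_timecourse(n_proteins: int = 50, features_range=(2, 30),
                        n_disease: int = 14, n_controls: int = 29,
                        weeks=(0, 10, 13, 26), dropout: float = 0.2,
                        sigma_error: float = 0.3, sigma_subject: float = 0.3,
                        frac_differential: float = 0.2,
                        effect_sizes=(0.5, 1.0, 2.0),
                        effect_weeks=(13,),
                        baseline_mean: float = 17.0, baseline_sd: float = 1.5,
                        feature_sd: float = 2.0,
                        noise_floor: float = 10.0,
                        noise_floor_rate: float = 0.0,
                        seed: int = 0):
    """Time-course / group-comparison emulator.

    Disease subjects are sampled at every week in ``weeks`` (dropping
    each non-first week independently with probability ``dropout``; the
    first two disease subjects are kept complete so no week empties out);
    control subjects are sampled once.  Single runs (L = 1), no missing
    cells: with probability ``noise_floor_rate`` a cell reports the
    constant ``noise_floor`` instead of its signal, mimicking a workflow
    that reports background noise for absent peaks.
    """
    rng = np.random.default_rng(seed)
    weeks = [str(w) for w in weeks]
    effect_conds = {f"disease:{w}" for w in map(str, effect_weeks)}
    conditions = [f"disease:{w}" for w in weeks] + ["control:ctrl"]
    if not effect_conds <= set(conditions):
        raise ValueError(f"effect weeks {effect_weeks} not in weeks {weeks}")

    disease = [f"D{k + 1:02d}" for k in range(n_disease)]
    controls = [f"H{k + 1:02d}" for k in range(n_controls)]
    samples = []  # (condition, subject, run)
    for i, s in enumerate(disease):
        for w in weeks:
            if i >= 2 and w != weeks[0] and rng.random() < dropout:
                continue
            samples.append((f"disease:{w}", s, f"{s}_wk{w}"))
    for s in controls:
        samples.append(("control:ctrl", s, f"{s}_ctrl"))

    differential, deltas = _draw_protein_effects(
        rng, n_proteins, frac_differential, effect_sizes)
    lo, hi = features_range
    prot_rows, cm_rows, off_rows, sub_rows, cells = [], [], [], [], []
    width = len(str(n_proteins))
    for ip in range(n_proteins):
        prot = f"P{ip + 1:0{width}d}"
        base = rng.normal(baseline_mean, baseline_sd)
        n_feat = int(rng.integers(lo, hi + 1))
        feats = [f"{prot}_pep{i + 1}" for i in range(n_feat)]
        offsets = rng.normal(0.0, feature_sd, n_feat)
        sub_eff = {s: rng.normal(0.0, sigma_subject)
                   for s in disease + controls}
        prot_rows.append({"Protein": prot, "differential": bool(differential[ip]),
                          "delta": float(deltas[ip]), "base": float(base)})
        cond_mean = {}
        for c in conditions:
            cond_mean[c] = base + (deltas[ip] if c in effect_conds else 0.0)
            cm_rows.append({PROTEIN: prot, CONDITION: c, "mean": cond_mean[c]})
        for f, o in zip(feats, offsets):
            off_rows.append({PROTEIN: prot, FEATURE: f, "offset": float(o)})
        for s, e in sub_eff.items():
            sub_rows.append({PROTEIN: prot, SUBJECT: s, "effect": float(e)})
        for f, o in zip(feats, offsets):
            for c, s, r in samples:
                val = cond_mean[c] + o + sub_eff[s] + rng.normal(0, sigma_error)
                if noise_floor_rate > 0 and rng.random() < noise_floor_rate:
                    val = noise_floor
                cells.append((prot, f, c, s, r, val))

    df = pd.DataFrame(cells, columns=[PROTEIN, FEATURE, CONDITION, SUBJECT,
                                      RUN, LOG_INTENSITY])
    grp, wk = zip(*(c.split(":") for c in df[CONDITION]))
    df.insert(2, "Group", grp)
    df.insert(3, "Week", wk)
    df[INTENSITY] = 2.0 ** df[LOG_INTENSITY]
    truth = SimTruth(
        proteins=pd.DataFrame(prot_rows),
        condition_means=pd.DataFrame(cm_rows),
        feature_offsets=pd.DataFrame(off_rows),
        subject_effects=pd.DataFrame(sub_rows),
        config={"n_proteins": n_proteins, "weeks": weeks, "dropout": dropout,
                "sigma_error": sigma_error, "sigma_subject": sigma_subject,
                "noise_floor": noise_floor,
                "noise_floor_rate": noise_floor_rate},
        seed=seed,
    )
    table = FeatureTable(df, factor_columns=["Group", "Week"], log_base=2)
    return table, truth


def inject_missing(table: FeatureTable, mechanism: str, rate: float,
                   seed: int = 0) -> FeatureTable:
    """Blank cells of an otherwise complete table.

    ``mechanism='random'`` blanks each cell independently with
    probability ``rate``; ``mechanism='condition_empty'`` picks a
    fraction ``rate`` of (protein, feature) pairs and blanks one randomly
    chosen condition entirely for each, producing condition-empty
    features.
    """
    if mechanism not in ("random", "condition_empty"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    if rate == 0:
        return table.with_data(df)
    if mechanism == "random":
        mask = rng.random(len(df)) < rate
    else:
        pairs = df[[PROTEIN, FEATURE]].drop_duplicates().to_numpy()
        n_pick = int(round(rate * len(pairs)))
        picked = pairs[rng.choice(len(pairs), size=n_pick, replace=False)]
        mask = np.zeros(len(df), bool)
        for prot, feat in picked:
            sel = (df[PROTEIN] == prot) & (df[FEATURE] == feat)
            conds = list(pd.unique(df.loc[sel, CONDITION]))
            c = conds[rng.integers(len(conds))]
            mask |= (sel & (df[CONDITION] == c)).to_numpy()
    df.loc[mask, [INTENSITY, LOG_INTENSITY]] = np.nan
    return table.with_data(df)


def inject_interference(table: FeatureTable, n_features: int,
                        magnitude: float, seed: int = 0):
    """Distort the profile of ``n_features`` random features.

    Adds ``magnitude`` (log scale) to all cells of one randomly chosen
    condition per picked feature, emulating co-elution interference.
    Returns ``(FeatureTable, DataFrame)`` where the frame lists the
    (protein, feature, condition) targets.
    """
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    targets = []
    if magnitude != 0 and n_features > 0:
        pairs = df[[PROTEIN, FEATURE]].drop_duplicates().to_numpy()
        if n_features > len(pairs):
            raise ValueError("n_features exceeds the number of features")
        picked = pairs[rng.choice(len(pairs), size=n_features, replace=False)]
        for prot, feat in picked:
            sel = (df[PROTEIN] == prot) & (df[FEATURE] == feat)
            conds = list(pd.unique(df.loc[sel, CONDITION]))
            c = conds[rng.integers(len(conds))]
            hit = sel & (df[CONDITION] == c)
            df.loc[hit, LOG_INTENSITY] += magnitude
            df.loc[hit, INTENSITY] = 2.0 ** df.loc[hit, LOG_INTENSITY]
            targets.append({PROTEIN: prot, FEATURE: feat, CONDITION: c})
    return table.with_data(df), pd.DataFrame(targets)
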