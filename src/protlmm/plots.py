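"""Exploratory and diagnostic graphics.

Every plot writes its underlying data as a tidy TSV next to the image
(same stem, ``.tsv`` suffix), so plot content is testable without pixel
comparison.  Colors are assigned deterministically by feature order.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dataio import CONDITION, FEATURE, LOG_INTENSITY, PROTEIN, SUBJECT, FeatureTable
from .design import infer_design
from .model import ProteinFit


def _colors(features):
    cmap = plt.get_cmap("tab20")
    return {f: cmap(i % 20) for i, f in enumerate(features)}


def _sidecar(path) -> Path:
    path = Path(path)
    return path.with_suffix(".tsv")


def _finish(fig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path)
    plt.close(fig)
    return path


def profile_plot(table: FeatureTable, protein: str, path) -> Path:
    """Feature profiles across conditions (replicate-averaged), one line
    per feature; missing cells appear as gaps."""
    data = table.protein_data(protein)
    design = infer_design(table)
    prof = (data.groupby([FEATURE, CONDITION], sort=False)[LOG_INTENSITY]
            .mean().reset_index())
    features = list(pd.unique(data[FEATURE]))
    conds = design.conditions
    xpos = {c: i for i, c in enumerate(conds)}
    colors = _colors(features)

    fig, ax = plt.subplots(figsize=(1.2 * len(conds) + 2, 4))
    for f in features:
        sub = prof[prof[FEATURE] == f].set_index(CONDITION)[LOG_INTENSITY]
        ys = [sub.get(c, np.nan) for c in conds]
        ax.plot(range(len(conds)), ys, marker="o", label=f, color=colors[f])
    ax.set_xticks(range(len(conds)), conds, rotation=45, ha="right")
    ax.set_ylabel("log-intensity")
    ax.set_title(f"{protein}: feature profiles")
    fig.tight_layout()

    prof.insert(0, PROTEIN, protein)
    prof["x"] = prof[CONDITION].map(xpos)
    prof.to_csv(_sidecar(path), sep="\t", index=False)
    return _finish(fig, path)


def trellis_plot(table: FeatureTable, protein: str, path,
                 panel_by: str = "condition-factors") -> Path:
    """Feature-level trellis display.

    ``panel_by='condition-factors'`` puts the last declared factor on the
    x-axis with one panel per combination of the remaining factors;
    ``panel_by='subject'`` panels one subject each (time courses).
    """
    data = table.protein_data(protein)
    features = list(pd.unique(data[FEATURE]))
    colors = _colors(features)

    if panel_by == "subject":
        panels = list(pd.unique(data[SUBJECT]))
        panel_col, x_col = SUBJECT, CONDITION
    elif panel_by == "condition-factors":
        if len(table.factor_columns) < 2:
            raise ValueError("factor paneling needs >= 2 factor columns")
        x_col = table.factor_columns[-1]
        panel_cols = table.factor_columns[:-1]
        data = data.copy()
        data["_panel"] = data[panel_cols].agg(":".join, axis=1)
        panels = list(pd.unique(data["_panel"]))
        panel_col = "_panel"
    else:
        raise ValueError(f"unknown panel_by {panel_by!r}")

    xlevels = list(pd.unique(table.data[x_col]))
    ncol = min(len(panels), 4)
    nrow = int(np.ceil(len(panels) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow),
                             sharey=True, squeeze=False)
    rows = []
    for i, panel in enumerate(panels):
        ax = axes[i // ncol][i % ncol]
        sub = data[data[panel_col] == panel]
        prof = sub.groupby([FEATURE, x_col], sort=False)[LOG_INTENSITY].mean()
        for f in features:
            ys = [prof.get((f, x), np.nan) for x in xlevels]
            ax.plot(range(len(xlevels)), ys, marker="o", color=colors[f])
            for x, y in zip(xlevels, ys):
                rows.append({PROTEIN: protein, "panel": panel, FEATURE: f,
                             "x": x, LOG_INTENSITY: y})
        ax.set_title(str(panel), fontsize=9)
        ax.set_xticks(range(len(xlevels)), xlevels)
    for j in range(len(panels), nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.suptitle(f"{protein}: trellis by {panel_by}")
    fig.tight_layout()
    pd.DataFrame(rows).to_csv(_sidecar(path), sep="\t", index=False)
    return _finish(fig, path)


def residual_plots(fit: ProteinFit, path, span: float = 0.75) -> Path:
    """(a) residual vs fitted, per-feature colors; (b) |residual| vs
    fitted with the loess curve used for variance weighting."""
    obs = fit.data[fit.data[LOG_INTENSITY].notna()]
    feats = list(pd.unique(obs[FEATURE]))
    colors = _colors(feats)
    fitted = fit.fitted.to_numpy()
    resid = fit.residuals.to_numpy()

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for f in feats:
        m = (obs[FEATURE] == f).to_numpy()
        ax1.scatter(fitted[m], resid[m], s=12, color=colors[f])
        ax2.scatter(fitted[m], np.abs(resid[m]), s=12, color=colors[f])
    ax1.axhline(0.0, color="grey", lw=0.8)
    ax1.set_xlabel("fitted log-abundance"); ax1.set_ylabel("residual")
    smooth = None
    if len(fitted) >= 5 and not np.allclose(fitted, fitted[0]):
        smooth = lowess(np.abs(resid), fitted, frac=span, it=1,
                        return_sorted=True)
        ax2.plot(smooth[:, 0], smooth[:, 1], color="black", lw=2)
    ax2.set_xlabel("fitted log-abundance"); ax2.set_ylabel("|residual|")
    fig.suptitle(f"{fit.protein}: residual diagnostics")
    fig.tight_layout()

    out = pd.DataFrame({
        PROTEIN: fit.protein,
        FEATURE: obs[FEATURE].to_numpy(),
        "fitted": fitted,
        "residual": resid,
        "abs_residual": np.abs(resid),
    })
    if smooth is not None:
        out["loess_at_fitted"] = np.interp(fitted, smooth[:, 0], smooth[:, 1])
    out.to_csv(_sidecar(path), sep="\t", index=False)
    return _finish(fig, path)


def quant_plot(quant: pd.DataFrame, protein: str, path) -> Path:
    """Condition quantifications with their confidence intervals."""
    sub = quant[(quant["Protein"] == protein)
                & (quant["TargetType"] == "condition")
                & (quant["status"] == "ok")]
    if sub.empty:
        raise ValueError(f"no condition quantifications for {protein!r}")
    fig, ax = plt.subplots(figsize=(1.0 * len(sub) + 2, 4))
    x = np.arange(len(sub))
    ax.errorbar(x, sub["Estimate"],
                yerr=[sub["Estimate"] - sub["CIlow"],
                      sub["CIhigh"] - sub["Estimate"]],
                fmt="o", capsize=4, color="black")
    ax.set_xticks(x, sub["Target"], rotation=45, ha="right")
    ax.set_ylabel("model-based log-abundance")
    level = float(sub["Level"].iloc[0]) * 100
    ax.set_title(f"{protein}: condition quantification ({level:.0f}% CI)")
    fig.tight_layout()
    sub.to_csv(_sidecar(path), sep="\t", index=False)
    return _finish(fig, path)
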