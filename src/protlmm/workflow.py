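"""End-to-end analysis orchestration.

:func:`analyze` runs the in-memory workflow — missing-peak treatment,
per-protein model fits (with per-protein failure isolation), contrast
testing with BH FDR, quantification — and :func:`run_pipeline` wraps it
with file I/O, normalization, plotting and logging for the CLI.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dataio
from .dataio import FEATURE, PROTEIN, FeatureTable
from .design import infer_design
from .inference import ComparisonSpec, compare_proteins
from .missing import apply_missing_strategy, classify_missing
from .model import fit_protein
from .power import power_defaults_from_analysis
from .quantify import quantify_proteins

logger = logging.getLogger("protlmm")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (round-trips to YAML)."""

    input: str = None
    output_dir: str = "protlmm_out"
    factor_columns: list = None
    log_base: object = 2
    normalization: str = "none"  # none | constant | quantile
    scope: str = "reduced"
    interaction: bool = True
    feature_level: bool = False
    missing_strategy: str = None  # impute_min | no_interaction | remove_feature
    comparisons: dict = field(default_factory=dict)  # label -> {condition: coef}
    fdr_level: float = 0.05
    weighting: bool = False
    span: float = 0.75
    max_iter: int = 10
    tol: float = 1e-3
    quant_targets: str = "condition"
    ci_level: float = 0.95
    plots: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def comparisons_from_config(spec_map: dict) -> list:
    return [ComparisonSpec(label, dict(coefs))
            for label, coefs in spec_map.items()]


def analyze(table: FeatureTable, comparisons=None, scope: str = "reduced",
            interaction: bool = True, missing_strategy: str = None,
            weighting: bool = False, span: float = 0.75, max_iter: int = 10,
            tol: float = 1e-3, feature_level: bool = False,
            quant_targets: str = None, ci_level: float = 0.95) -> dict:
    """Fit every protein and derive comparisons / quantifications.

    Proteins are processed in sorted order; a failure in one protein is
    quarantined (recorded under ``failures``) and never aborts the batch.
    Returns a dict with keys ``design``, ``fits``, ``results``,
    ``quant``, ``missing``, ``flags`` and ``failures``.
    """
    if dataio.LOG_INTENSITY not in table.data.columns:
        raise ValueError("table must be log-transformed before analysis")
    design = infer_design(table)
    data = table.data
    if feature_level:
        data = data.copy()
        data[PROTEIN] = data[PROTEIN] + "|" + data[FEATURE]

    fits, reports, flag_map, failures = {}, {}, {}, {}
    for protein in sorted(data[PROTEIN].unique()):
        pdata = data[data[PROTEIN] == protein]
        try:
            report = classify_missing(pdata, design)
            reports[protein] = report
            inter = interaction
            if missing_strategy is not None:
                pdata, flags = apply_missing_strategy(
                    pdata, report, missing_strategy, table_data=data)
                flag_map[protein] = flags
                if flags["skip"]:
                    failures[protein] = "no features left after removal"
                    continue
                inter = interaction and flags["interaction"]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits[protein] = fit_protein(
                    pdata, design, scope=scope, interaction=inter,
                    feature_terms=not feature_level, weighting=weighting,
                    span=span, max_iter=max_iter, tol=tol)
            logger.debug("fitted %s", protein)
        except Exception as exc:  # per-protein quarantine
            failures[protein] = f"{type(exc).__name__}: {exc}"
            logger.warning("protein %s failed: %s", protein, failures[protein])

    out = {"design": design, "fits": fits, "missing": reports,
           "flags": flag_map, "failures": failures,
           "results": None, "quant": None}
    if comparisons:
        results = compare_proteins(fits, comparisons)
        imputed = {p for p, fl in flag_map.items() if fl.get("imputed_cells")}
        if imputed and not results.empty:
            sel = results["Protein"].isin(imputed)
            results.loc[sel, "status"] = results.loc[sel, "status"] + ";imputed"
        out["results"] = results
    if quant_targets:
        out["quant"] = quantify_proteins(fits, targets=quant_targets,
                                         level=ci_level)
    return out


def run_pipeline(config: RunConfig, table: FeatureTable = None) -> dict:
    """File-level pipeline: read, transform, normalize, analyze, write.

    Outputs under ``config.output_dir``: the normalized table, comparison
    and quantification TSVs, the missing-value report, per-protein fit
    summaries, data-driven power defaults, the resolved config and a log
    of per-protein status.  Returns the in-memory bundle from
    :func:`analyze` plus the output paths.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))

    if table is None:
        table = dataio.read_quant_table(config.input,
                                        factor_columns=config.factor_columns)
    if table.log_base is None:
        table = dataio.log_transform(table, base=config.log_base)
    if config.normalization == "constant":
        table = dataio.normalize_constant(table)
    elif config.normalization == "quantile":
        table = dataio.normalize_quantile(table)
    elif config.normalization != "none":
        raise ValueError(f"unknown normalization {config.normalization!r}")
    dataio.write_quant_table(table, outdir / "normalized.tsv")

    comparisons = comparisons_from_config(config.comparisons or {})
    bundle = analyze(
        table, comparisons=comparisons, scope=config.scope,
        interaction=config.interaction,
        missing_strategy=config.missing_strategy,
        weighting=config.weighting, span=config.span,
        max_iter=config.max_iter, tol=config.tol,
        feature_level=config.feature_level,
        quant_targets=config.quant_targets, ci_level=config.ci_level)

    if bundle["results"] is not None:
        bundle["results"].to_csv(outdir / "comparisons.tsv", sep="\t",
                                 index=False)
    if bundle["quant"] is not None:
        bundle["quant"].to_csv(outdir / "quantification.tsv", sep="\t",
                               index=False)
    missing_frames = [r.to_frame() for r in bundle["missing"].values()]
    missing_frames = [m for m in missing_frames if not m.empty]
    if missing_frames:
        pd.concat(missing_frames).to_csv(outdir / "missing_report.tsv",
                                         sep="\t", index=False)
    coef_rows = []
    for prot, fit in sorted(bundle["fits"].items()):
        for name, val in fit.params.items():
            coef_rows.append({"Protein": prot, "Term": name, "Estimate": val,
                              "Scope": fit.scope,
                              "Sigma2Error": fit.sigma2_error,
                              "Sigma2Subject": fit.sigma2_subject,
                              "DFresidual": fit.df_residual})
    pd.DataFrame(coef_rows).to_csv(outdir / "fits.tsv", sep="\t", index=False)

    defaults = power_defaults_from_analysis(bundle["fits"], bundle["results"],
                                            q=config.fdr_level)
    with open(outdir / "power_defaults.yaml", "w") as fh:
        yaml.safe_dump(defaults, fh)
    config.to_yaml(outdir / "config.yaml")

    with open(outdir / "run_log.txt", "w") as fh:
        for prot in sorted(set(bundle["fits"]) | set(bundle["failures"])):
            status = bundle["failures"].get(prot, "ok")
            fh.write(f"{prot}\t{status}\n")
        fh.write(f"# proteins fitted: {len(bundle['fits'])}\n")
        fh.write(f"# proteins failed: {len(bundle['failures'])}\n")

    if config.plots:
        from . import plots as _plots
        plot_dir = outdir / "plots"
        for prot in sorted(bundle["fits"]):
            _plots.profile_plot(table, prot, plot_dir / f"{prot}_profile.png")

    bundle["output_dir"] = str(outdir)
    bundle["table"] = table
    return bundle
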