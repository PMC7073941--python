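"""End-to-end orchestration: simulate -> quantify -> normalize -> QC -> stats.

``run_pipeline`` executes the full workflow on a synthetic study (or, through
the CLI, on user-supplied tables stage by stage), writes every intermediate
table as CSV when an output directory is given, and records a JSON manifest
with the seed, parameter echo and library versions.  Any stage failure is
re-raised as a :class:`~ccmquant.errors.PipelineStageError` naming the stage;
tables written before the failure are retained.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomass import intracellular_table, load_cell_models
from .errors import PipelineStageError, ValidationError
from .panel import MetabolitePanel, default_panel
from .qc import qc_report
from .quantify import (
    FLAG_OK,
    default_prep_factors,
    fit_all_calibrations,
    models_to_frame,
    quantify_table,
)
from .stats import (
    class_composition,
    concentration_matrix,
    group_means,
    impute_min,
    autoscale,
    magnitude_heatmap,
    pca,
    prevalence_filter,
    ttest_fdr,
)
from .synthetic import (
    GroupSpec,
    StudyConfig,
    default_study_config,
    group_cell_model_map,
    simulate_study,
)

__all__ = ["PipelineConfig", "run_pipeline", "recovery_error", "load_pipeline_config"]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    study: StudyConfig
    isotope_correction: bool = True
    dixon_alpha: float = 0.05
    prevalence_threshold: float = 0.5
    prevalence_unit: str = "groups"
    ttest_alpha: float = 0.05
    contrasts: tuple[tuple[str, str], ...] = ()
    n_components: int = 2
    ellipse_method: str = "chi2"

    @staticmethod
    def default(seed: int = 74, **overrides) -> "PipelineConfig":
        return PipelineConfig(
            study=default_study_config(seed=seed),
            contrasts=(("noceanica", "ptricornutum"), ("hek293", "nb4")),
            **overrides,
        )


def load_pipeline_config(path) -> PipelineConfig:
    """Read a flat YAML/JSON-style config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    study_doc = doc.get("study", {})
    groups = tuple(GroupSpec(**g) for g in study_doc.pop("groups", []))
    if not groups:
        raise ValidationError("config must define study.groups")
    study = StudyConfig(groups=groups, **study_doc)
    extra = {k: v for k, v in doc.items() if k != "study"}
    if "contrasts" in extra:
        extra["contrasts"] = tuple(tuple(c) for c in extra["contrasts"])
    return PipelineConfig(study=study, **extra)


def _dump(df: pd.DataFrame, outdir: Path | None, name: str, index: bool = False) -> None:
    if outdir is not None:
        df.to_csv(outdir / name, index=index)


def recovery_error(truth, matrix: pd.DataFrame) -> pd.Series:
    """Absolute relative error of recovered group-mean intracellular
    concentration vs. ground truth, one entry per quantified
    (group, metabolite) cell."""
    means = group_means(matrix)
    true_wide = truth.conc.T  # groups x metabolites
    common = means.columns.intersection(true_wide.columns)
    rel = (means[common] - true_wide.loc[means.index, common]).abs() / true_wide.loc[
        means.index, common
    ]
    return rel.stack().dropna()


def run_pipeline(config: PipelineConfig, outdir=None, panel: MetabolitePanel | None = None) -> dict:
    """Run the full pipeline on a simulated study; returns the artifact bundle.

    Keys of the returned dict: truth, biomass, raw, models, model_failures,
    extract, intracellular, qc (QCReport), matrix (post-QC concentration
    matrix), filtered/imputed/scaled matrices, pca, compositions, magnitude,
    ttests (per contrast), recovery (per-cell |relative error|), manifest.
    """
    panel = panel if panel is not None else default_panel()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineStageError(name, str(exc)) from exc

    study = config.study
    prep = default_prep_factors()
    cell_models = load_cell_models()

    sim = stage("simulate", lambda: simulate_study(study, panel, prep, cell_models))
    _dump(sim["biomass"], outdir, "biomass.csv")
    _dump(sim["raw"], outdir, "raw_peaks.csv")
    truth_long = sim["truth"].to_long()
    _dump(truth_long, outdir, "ground_truth.csv")

    models, failures = stage(
        "calibrate",
        lambda: fit_all_calibrations(
            sim["raw"], use_isotope_correction=config.isotope_correction
        ),
    )
    _dump(models_to_frame(models), outdir, "calibration_models.csv")

    extract = stage(
        "quantify",
        lambda: quantify_table(
            sim["raw"], models, prep, panel, use_isotope_correction=config.isotope_correction
        ),
    )
    extract["unit"] = "M"
    _dump(extract, outdir, "extract_concentrations.csv")

    intra = stage(
        "biomass",
        lambda: intracellular_table(
            extract.drop(columns="unit"),
            sim["biomass"],
            cell_models,
            group_cell_model_map(study),
        ),
    )
    intra["unit"] = "M"
    _dump(intra, outdir, "intracellular_concentrations.csv")

    report, cleaned = stage(
        "qc", lambda: qc_report(intra.drop(columns="unit"), alpha=config.dixon_alpha)
    )
    _dump(report.ec_table, outdir, "qc_energy_charge.csv", index=True)
    _dump(report.outlier_ledger, outdir, "qc_outliers.csv")
    if outdir is not None:
        (outdir / "qc_summary.txt").write_text(report.summary_text() + "\n")

    matrix = stage("stats", lambda: concentration_matrix(cleaned))
    filtered = stage(
        "stats",
        lambda: prevalence_filter(matrix, config.prevalence_threshold, config.prevalence_unit),
    )
    imputed = stage("stats", lambda: impute_min(filtered))
    scaled = stage("stats", lambda: autoscale(imputed))
    pca_res = stage(
        "stats",
        lambda: pca(scaled, n_components=config.n_components, ellipse_method=config.ellipse_method),
    )
    _dump(pca_res.scores, outdir, "pca_scores.csv", index=True)
    _dump(pca_res.loadings, outdir, "pca_loadings.csv", index=True)
    _dump(pca_res.ellipses, outdir, "pca_ellipses.csv")

    means = group_means(matrix)
    compositions = stage("stats", lambda: class_composition(means, panel))
    _dump(compositions, outdir, "class_composition.csv")
    magnitude = stage("stats", lambda: magnitude_heatmap(means))
    _dump(magnitude, outdir, "magnitude_heatmap.csv", index=True)

    pathway_pos = {m.metabolite_id: m.pathway_position for m in panel}
    ttests: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in config.contrasts:
        tt = stage("stats", lambda a=a, b=b: ttest_fdr(imputed, a, b, alpha=config.ttest_alpha))
        tt.insert(0, "pathway_position", tt.index.map(pathway_pos))
        ttests[(a, b)] = tt
        _dump(tt, outdir, f"ttest_{a}_vs_{b}.csv", index=True)

    recovery = stage("report", lambda: recovery_error(sim["truth"], matrix))

    manifest = {
        "package_version": __version__,
        "seed": study.seed,
        "isotope_correction": config.isotope_correction,
        "n_groups": len(study.groups),
        "n_replicates": study.n_replicates,
        "n_metabolites": len(panel),
        "noise_cv": study.noise_cv,
        "matrix_effect_sd": study.matrix_effect_sd,
        "missing_rate": study.missing_rate,
        "outlier_rate": study.outlier_rate,
        "median_abs_relative_recovery_error": float(recovery.median()),
        "min_group_energy_charge": float(report.ec_table["ec_mean"].min()),
        "calibration_failures": failures,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if outdir is not None:
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "config": config,
        "panel": panel,
        "truth": sim["truth"],
        "biomass": sim["biomass"],
        "raw": sim["raw"],
        "models": models,
        "model_failures": failures,
        "extract": extract,
        "intracellular": intra,
        "qc": report,
        "cleaned": cleaned,
        "matrix": matrix,
        "filtered": filtered,
        "imputed": imputed,
        "scaled": scaled,
        "pca": pca_res,
        "compositions": compositions,
        "magnitude": magnitude,
        "ttests": ttests,
        "recovery": recovery,
        "manifest": manifest,
    }
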