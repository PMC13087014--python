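"""End-to-end orchestration: simulate or load inputs, fit w-scores, run the
per-gene association suite and the random-forest stage, and write a report
bundle with full provenance (config hash + seeds)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import run_association_suite
from .atlas import RegionAtlas, RegionMap
from .config import AnalysisConfig
from .expression import ExpressionMatrix, gene_correlation_matrix, process_donors
from .forest import ForestConfig, fit_forest, forest_null, forest_significance
from .io import (
    read_atlas_tsv,
    read_donor_bundle,
    read_expression_csv,
    read_subjects_csv,
    write_atlas_tsv,
    write_expression_csv,
    write_json,
    write_results_tsv,
    write_subjects_csv,
)
from .synthetic import (
    GroundTruth,
    SubjectTable,
    default_atlas,
    simulate_cohort,
    simulate_expression,
)
from .wscore import average_wscores, compute_wscores, fit_normative, region_atrophy_tests

logger = logging.getLogger(__name__)


def _resolve_inputs(
    config: AnalysisConfig,
) -> tuple[RegionAtlas, SubjectTable, ExpressionMatrix, GroundTruth | None]:
    """Load inputs from configured paths, simulating whatever is missing."""
    atlas = (
        read_atlas_tsv(config.atlas_path)
        if config.atlas_path
        else default_atlas(seed=config.seed)
    )
    truth = None
    if config.expression_path:
        expression = read_expression_csv(config.expression_path, atlas)
    elif config.donor_dir:
        donors = read_donor_bundle(config.donor_dir)
        expression = process_donors(donors, atlas)
    else:
        expression = simulate_expression(
            atlas, config.gene_panel, config.length_scale, seed=config.seed + 1
        )
    if config.subjects_path:
        subjects = read_subjects_csv(config.subjects_path, atlas)
    else:
        effects = {g: 0.0 for g in expression.genes}
        effects.update(config.effect_coefficients)
        truth = GroundTruth(
            effect_coefficients=effects,
            noise_sd=config.noise_sd,
            spatial_length_scale=config.length_scale,
            seed=config.seed + 2,
        )
        subjects, truth = simulate_cohort(
            atlas,
            expression,
            truth,
            n_controls=config.n_controls,
            n_patients=config.n_patients,
        )
    return atlas, subjects, expression, truth


def validate_inputs(
    config: AnalysisConfig,
    atlas: RegionAtlas,
    subjects: SubjectTable,
    expression: ExpressionMatrix,
) -> None:
    """Fail fast, before any computation, on inconsistent inputs."""
    problems = []
    unknown = [g for g in config.gene_panel if g not in expression.genes]
    if unknown:
        problems.append(f"gene panel entries absent from expression data: {unknown}")
    if list(subjects.volumes.columns) != list(atlas.region_ids):
        extra = set(subjects.volumes.columns) - set(atlas.region_ids)
        missing = set(atlas.region_ids) - set(subjects.volumes.columns)
        problems.append(
            f"subject regions mismatch atlas (extra={sorted(extra)[:5]}, "
            f"missing={sorted(missing)[:5]})"
        )
    if expression.atlas != atlas:
        problems.append("expression region set does not match atlas")
    if len(subjects.controls().covariates) < 5:
        problems.append("need at least 5 controls")
    if problems:
        raise ValueError("invalid inputs: " + "; ".join(problems))


def _analysis_block(
    atrophy: RegionMap,
    expression: ExpressionMatrix,
    config: AnalysisConfig,
    ensembles: dict,
) -> dict:
    assoc_table, ensembles_out = run_association_suite(
        atrophy,
        expression,
        n_surrogates=config.n_surrogates_regression,
        seed=config.seed + 10,
        q=config.q,
        sided=config.sided,
        ensembles=ensembles,
    )
    ensembles.update(ensembles_out)
    fconfig = ForestConfig(
        ntree=config.ntree,
        mtry=config.mtry,
        nodesize=config.nodesize,
        seed=config.seed + 20,
    )
    empirical = fit_forest(expression, atrophy, fconfig)
    nulls = forest_null(
        expression,
        atrophy,
        ensembles,
        n_null=config.n_surrogates_forest,
        seed=config.seed + 30,
        config=fconfig,
    )
    forest_res = forest_significance(empirical, nulls)
    return {"association": assoc_table, "forest": forest_res}


def run_full_analysis(config: AnalysisConfig, out_dir) -> dict:
    """Run the complete study replica and write the report bundle.

    Returns a dict with the in-memory results plus the output paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run starting: config hash %s", config.config_hash())

    atlas, subjects, expression, truth = _resolve_inputs(config)
    validate_inputs(config, atlas, subjects, expression)
    expression = expression.subset(
        [g for g in config.gene_panel if g in expression.genes]
    )

    model = fit_normative(subjects.controls())
    panel = compute_wscores(subjects.patients(), model)
    atrophy = average_wscores(panel)
    ttests = region_atrophy_tests(panel)
    corr = gene_correlation_matrix(expression)

    ensembles: dict = {}
    main = _analysis_block(atrophy, expression, config, ensembles)

    subgroup_results = {}
    for name, ids in (config.subgroups or {}).items():
        sub_panel = compute_wscores(subjects.select(list(ids)), model)
        sub_atrophy = average_wscores(sub_panel)
        subgroup_results[name] = _analysis_block(
            sub_atrophy, expression, config, ensembles
        )

    # ---- write bundle ----
    write_atlas_tsv(atlas, out / "atlas.tsv")
    write_subjects_csv(subjects, out / "subjects.csv")
    write_expression_csv(expression, out / "expression.csv")
    panel.scores.rename_axis("subject_id").to_csv(out / "wscores.csv")
    atrophy_tbl = ttests.assign(mean_w=atrophy.values)
    write_results_tsv(atrophy_tbl, out / "atrophy_map.tsv")
    corr.rename_axis("gene").to_csv(out / "gene_correlations.csv")
    write_results_tsv(main["association"], out / "association.tsv")

    def _forest_json(res):
        return {
            "oob_mse": res.oob_mse,
            "pct_var": res.pct_var,
            "r2": res.r2,
            "p_spatial_global": res.p_spatial_global,
            "n_null": res.n_null,
            "config": {
                "ntree": res.config.ntree,
                "mtry": res.config.resolved_mtry(len(res.importance)),
                "nodesize": res.config.nodesize,
                "seed": res.config.seed,
            },
            "importance": res.importance.to_dict(orient="records"),
        }

    write_json(_forest_json(main["forest"]), out / "forest.json")
    for name, block in subgroup_results.items():
        write_results_tsv(block["association"], out / f"association_{name}.tsv")
        write_json(_forest_json(block["forest"]), out / f"forest_{name}.json")

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "ground_truth": truth.to_json() if truth is not None else None,
    }
    write_json(provenance, out / "provenance.json")
    config.to_yaml(out / "config.yaml")
    logger.info("run finished: outputs in %s", out)

    return {
        "atlas": atlas,
        "subjects": subjects,
        "expression": expression,
        "model": model,
        "wscores": panel,
        "atrophy": atrophy,
        "ttests": ttests,
        "gene_correlations": corr,
        "association": main["association"],
        "forest": main["forest"],
        "subgroups": subgroup_results,
        "out_dir": out,
    }
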