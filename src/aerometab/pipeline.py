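"""End-to-end orchestration: transform/scale -> PLS-DA + permutation
validation -> univariate models -> selection/Venn -> enrichment, per tissue.

``run_study`` operates on in-memory objects (useful from Python and for
tests); ``run_all`` is the file-based wrapper driven by a PipelineConfig.
All artifacts are CSV/JSON/plain text with stable ordering so a fixed seed
reproduces the output tree byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig
from .datatypes import MetaboliteMatrix, PathwayLibrary, StudyDesign
from .enrichment import enrich
from .io import align, handle_missing, read_abundance_table, read_design, read_gmt
from .pls import build_response, export_scores, fit_pls, permutation_validate
from .preprocess import preprocess_matrix
from .selection import SelectionRule, partition_venn, select_influential, summarize_report
from .univariate import run_univariate_suite

logger = logging.getLogger("aerometab")


def _tissue_seed(seed: int, index: int) -> int:
    return int((int(seed) * 1009 + 7919 * index) % (2 ** 31))


def analyze_tissue(matrix: MetaboliteMatrix, design: StudyDesign,
                   cfg: PipelineConfig, seed: int,
                   library: PathwayLibrary | None = None) -> dict:
    """Run every analysis stage for one tissue; return the result tables."""
    matrix, design = align(matrix, design)
    matrix = handle_missing(matrix, policy=cfg.missing_policy)
    design.require_full_factorial()

    processed, spec_table = preprocess_matrix(matrix, design, grid=cfg.grid())
    X = processed.values
    Y = build_response(design, cfg.response)
    labels = design.groups if cfg.response != "speed" else None

    model = fit_pls(X, Y, n_components=cfg.components,
                    y_coding=cfg.response,
                    predictor_ids=processed.metabolite_ids)
    perm = permutation_validate(
        X, Y, n_components=cfg.components, G=cfg.permutations,
        folds=cfg.folds, scheme=cfg.cv_scheme, seed=seed, labels=labels,
    )
    vip = pd.Series(model.vip, index=processed.metabolite_ids, name="vip")
    group_table, speed_table = run_univariate_suite(processed, design)

    joint_p = group_table.set_index("metabolite")["joint_p"]
    rule = SelectionRule(cfg.vip_threshold, cfg.p_threshold, cfg.fdr_threshold)
    selected = select_influential(vip, joint_p, rule)
    per_term_p = group_table.set_index("metabolite")[
        ["p_capacity", "p_age", "p_interaction"]
    ].rename(columns=lambda c: c.removeprefix("p_"))
    coefs = group_table.set_index("metabolite")[
        ["beta_capacity", "beta_age", "beta_interaction"]
    ].rename(columns=lambda c: c.removeprefix("beta_"))
    partition = partition_venn(selected, per_term_p, coefs,
                               p_threshold=cfg.p_threshold)
    membership, counts, text = summarize_report(partition, tissue=matrix.tissue)

    enrichment_table = None
    if library is not None:
        universe = set(processed.metabolite_ids)
        testable = {m for m in selected if m in universe}
        enrichment_table = enrich(testable, library, universe)

    summary = pd.DataFrame(
        [{
            "tissue": matrix.tissue,
            "n_samples": processed.n_samples,
            "n_metabolites": processed.n_metabolites,
            "components": model.n_components,
            "r2x": model.r2x[-1],
            "r2y": model.r2y[-1],
            "q2": perm.observed_q2,
            "q2_intercept": perm.q2_intercept,
            "r2_intercept": perm.r2_intercept,
            "permutation_p": perm.p_value,
            "n_selected": len(selected),
        }]
    )
    return {
        "matrix": processed,
        "design": design,
        "transform_spec": spec_table,
        "model": model,
        "permutation": perm,
        "pls_summary": summary,
        "vip": vip,
        "scores": export_scores(model, design) if model.n_components >= 2 else None,
        "univariate_group": group_table,
        "speed_association": speed_table,
        "selected": selected,
        "venn_membership": membership,
        "venn_counts": counts,
        "venn_text": text,
        "enrichment": enrichment_table,
    }


def _write_tissue(outdir: Path, result: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result["transform_spec"].to_csv(outdir / "transform_spec.csv", index=False)
    result["pls_summary"].to_csv(outdir / "pls_summary.csv", index=False)
    result["vip"].rename_axis("metabolite").reset_index().to_csv(
        outdir / "vip.csv", index=False)
    if result["scores"] is not None:
        result["scores"].to_csv(outdir / "scores.csv", index=False)
    result["permutation"].points_table().to_csv(
        outdir / "permutation_points.csv", index=False)
    result["univariate_group"].to_csv(outdir / "univariate_group.csv", index=False)
    result["speed_association"].to_csv(outdir / "speed_association.csv", index=False)
    result["venn_membership"].to_csv(outdir / "venn_partition.csv", index=False)
    result["venn_counts"].to_csv(outdir / "venn_counts.csv", index=False)
    (outdir / "venn_report.txt").write_text(result["venn_text"])
    if result["enrichment"] is not None:
        result["enrichment"].to_csv(outdir / "enrichment.csv", index=False)


def run_study(matrices: dict, design: StudyDesign, cfg: PipelineConfig,
              library: PathwayLibrary | None = None,
              outdir=None) -> dict:
    """Analyze every tissue; optionally write the artifact tree under outdir."""
    results = {}
    for index, (tissue, matrix) in enumerate(matrices.items()):
        logger.info("analyzing tissue %s: %d samples x %d metabolites",
                    tissue, matrix.n_samples, matrix.n_metabolites)
        results[tissue] = analyze_tissue(
            matrix, design, cfg, seed=_tissue_seed(cfg.seed, index),
            library=library,
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tissue, result in results.items():
            _write_tissue(outdir / tissue, result)
        _write_manifest(outdir, cfg)
    return results


def _write_manifest(outdir: Path, cfg: PipelineConfig) -> None:
    import pandas
    import scipy

    canonical = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "versions": {
            "aerometab": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_all(cfg: PipelineConfig) -> Path:
    """File-based pipeline: read inputs named in the config, write artifacts.

    On a stage failure a FAILED marker naming the stage is left in the output
    directory and the exception propagates.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read inputs"
    try:
        if not cfg.tissues:
            raise ValueError("config names no tissue abundance tables")
        if cfg.design is None:
            raise ValueError("config names no design file")
        design = read_design(cfg.design)
        matrices = {
            tissue: read_abundance_table(path, tissue=tissue)
            for tissue, path in cfg.tissues.items()
        }
        library = read_gmt(cfg.gmt) if cfg.gmt else None
        stage = "analysis"
        run_study(matrices, design, cfg, library=library, outdir=outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return outdir
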