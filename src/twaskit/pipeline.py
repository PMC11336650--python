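"""End-to-end orchestration: simulate -> triage -> score -> evaluate ->
drugs -> diffexp, with TSV contracts and a reproducibility manifest."""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .association import (DEFAULT_PREVALENCE, ONSET_PREVALENCE,
                          default_weight_sets, evaluate_all, best_rows)
from .config import SimConfig
from .diffexp import (classify_concordance, meta_diffexpr,
                      per_gene_case_control_correlation)
from .drugs import atc_enrichment, code_interactions, signed_drug_enrichment
from .io import ContractError, file_digest, read_table, write_table
from .scoring import (DEFAULT_THRESHOLD_GRID, FeatureCorrelation,
                      build_weight_set, compute_pts, standardize_expression)
from .simulate import (ExpressionCohort, simulate_cohorts,
                       simulate_credible_sets, simulate_drug_database,
                       simulate_feature_correlation, simulate_gene_annotation,
                       simulate_twas_sumstats)
from .triage import define_high_confidence

logger = logging.getLogger(__name__)

STAGES = ("simulate", "triage", "score", "evaluate", "drugs", "diffexp")

__all__ = ["RunManifest", "run_all", "STAGES"]


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict[str, str]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


class StageError(RuntimeError):
    pass


def _digests(paths: list[Path]) -> dict[str, str]:
    return {p.name: file_digest(p) for p in sorted(paths)}


def _read_cohorts(out: Path, config: SimConfig) -> list[ExpressionCohort]:
    cohorts = []
    for p in range(config.n_platforms):
        platform = f"platform_{p + 1}"
        expr = read_table(out / f"expression_{platform}.tsv",
                          ["gene_id"], "score").set_index("gene_id")
        pheno = read_table(out / f"phenotypes_{platform}.tsv",
                           ["sample_id", "case", "sex"],
                           "score").set_index("sample_id")
        cohorts.append(ExpressionCohort(platform, expr, pheno))
    return cohorts


def _stage_simulate(config: SimConfig, out: Path) -> list[Path]:
    annotation = simulate_gene_annotation(config)
    twas, truth = simulate_twas_sumstats(config, annotation)
    corr = simulate_feature_correlation(config, annotation)
    credsets, contained = simulate_credible_sets(config, annotation, truth)
    truth_weights = dict(zip(truth.loc[truth["is_signal"], "gene_id"],
                             truth.loc[truth["is_signal"], "true_z"]))
    cohorts = simulate_cohorts(config, annotation, truth_weights)
    interactions, drug_truth = simulate_drug_database(config, truth)

    files = []

    def emit(df: pd.DataFrame, name: str, **meta: str) -> None:
        path = out / name
        write_table(df, path, meta={"tool": f"twaskit {__version__}",
                                    "seed": str(config.seed), **meta})
        files.append(path)
        logger.info("simulate: wrote %s (%d rows)", name, len(df))

    emit(annotation[["gene_id", "chrom", "start", "end"]], "annotation.tsv",
         dialect="gene-location, 1-based inclusive")
    emit(annotation, "annotation_blocks.tsv")
    emit(twas, "twas.tsv")
    emit(corr.to_frame(), "correlation.tsv",
         window_bp=str(config.window_bp))
    emit(credsets, "credible_sets.tsv")
    emit(interactions, "drug_interactions.tsv")
    for cohort in cohorts:
        emit(cohort.expression.reset_index(names="gene_id"),
             f"expression_{cohort.platform}.tsv")
        emit(cohort.phenotypes.reset_index(),
             f"phenotypes_{cohort.platform}.tsv",
             survival_units=config.survival_units)
    truth_path = out / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump({
            "signal_genes": truth.loc[truth["is_signal"],
                                      "gene_id"].tolist(),
            "true_weights": truth_weights,
            "liability_c": cohorts[0].meta["c"],
            "contained_credible_genes": contained,
            **drug_truth,
        }, fh, indent=2, sort_keys=True)
    files.append(truth_path)
    return files


def _stage_triage(config: SimConfig, out: Path) -> list[Path]:
    twas = read_table(out / "twas.tsv",
                      ["gene_id", "method", "p", "pp3", "pp4", "heidi_p"],
                      "triage")
    annotation = read_table(out / "annotation.tsv",
                            ["gene_id", "chrom", "start", "end"], "triage")
    credsets = read_table(out / "credible_sets.tsv",
                          ["locus_id", "chrom", "pos"], "triage")
    result = define_high_confidence(twas, credsets, annotation)
    path = out / "triage.tsv"
    write_table(result, path)
    logger.info("triage: %d/%d genes high-confidence",
                int(result["high_confidence"].sum()), len(result))
    return [path]


def _stage_score(config: SimConfig, out: Path,
                 threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
                 ) -> list[Path]:
    twas = read_table(out / "twas.tsv",
                      ["gene_id", "feature", "stratum", "z", "p", "pp4"],
                      "score")
    corr = FeatureCorrelation.from_frame(
        read_table(out / "correlation.tsv",
                   ["feature_i", "feature_j", "r"], "score"),
        window_bp=config.window_bp)
    weight_sets = default_weight_sets(twas, corr,
                                      threshold_grid=threshold_grid)
    ws_rows = []
    for ws in weight_sets:
        for g, w in sorted(ws.weights.items()):
            ws_rows.append({"gene_id": g, "weight": w,
                            "threshold": ws.threshold, "stratum": ws.stratum,
                            "coloc_only": ws.coloc_only})
    files = [out / "weight_sets.tsv"]
    write_table(pd.DataFrame(ws_rows), files[0])

    cohorts = _read_cohorts(out, config)
    for cohort in cohorts:
        z = standardize_expression(cohort.expression)
        rows = []
        for ws in weight_sets:
            pts = compute_pts(z, ws)
            for sample, score in pts.scores.items():
                rows.append({"sample_id": sample, "score": score,
                             "threshold": ws.threshold,
                             "stratum": ws.stratum,
                             "coloc_only": ws.coloc_only,
                             "n_genes_used": pts.n_genes_used})
        path = out / f"pts_{cohort.platform}.tsv"
        write_table(pd.DataFrame(rows), path)
        files.append(path)
    logger.info("score: %d weight sets over %d platforms",
                len(weight_sets), len(cohorts))
    return files


def _stage_evaluate(config: SimConfig, out: Path,
                    prevalence: float = DEFAULT_PREVALENCE,
                    onset_prevalence: float = ONSET_PREVALENCE) -> list[Path]:
    twas = read_table(out / "twas.tsv",
                      ["gene_id", "feature", "stratum", "z", "p", "pp4"],
                      "evaluate")
    corr = FeatureCorrelation.from_frame(
        read_table(out / "correlation.tsv",
                   ["feature_i", "feature_j", "r"], "evaluate"),
        window_bp=config.window_bp)
    weight_sets = default_weight_sets(twas, corr)
    cohorts = _read_cohorts(out, config)
    assoc = evaluate_all(cohorts, weight_sets, prevalence=prevalence,
                         onset_prevalence=onset_prevalence)
    files = [out / "associations.tsv", out / "associations_best.tsv"]
    note = ("liability R^2 at the in-sample best threshold over the grid; "
            "optimistic, no out-of-sample correction")
    write_table(assoc, files[0], meta={"note": note})
    write_table(best_rows(assoc), files[1], meta={"note": note})
    logger.info("evaluate: %d association rows", len(assoc))
    return files


def _stage_drugs(config: SimConfig, out: Path) -> list[Path]:
    twas = read_table(out / "twas.tsv",
                      ["gene_id", "feature", "stratum", "z", "p", "pp4"],
                      "drugs")
    corr = FeatureCorrelation.from_frame(
        read_table(out / "correlation.tsv",
                   ["feature_i", "feature_j", "r"], "drugs"),
        window_bp=config.window_bp)
    interactions = code_interactions(
        read_table(out / "drug_interactions.tsv",
                   ["drug_id", "gene_id", "label", "atc3"], "drugs"))
    # clumped, threshold-free gene Z universe
    ws = build_weight_set(twas, corr, threshold=1.0)
    drug_res = signed_drug_enrichment(ws.weights, interactions)
    atc_res = atc_enrichment(drug_res,
                             interactions[["drug_id", "atc3"]])
    files = [out / "drug_enrichment.tsv", out / "atc_enrichment.tsv"]
    write_table(drug_res, files[0],
                meta={"sign": "positive z = predicted protective"})
    write_table(atc_res, files[1],
                meta={"sign": "positive median_z = predicted protective"})
    logger.info("drugs: %d drugs, %d ATC classes tested",
                len(drug_res), len(atc_res))
    return files


def _stage_diffexp(config: SimConfig, out: Path) -> list[Path]:
    twas = read_table(out / "twas.tsv", ["gene_id", "z"], "diffexp")
    cohorts = _read_cohorts(out, config)
    per_platform = [per_gene_case_control_correlation(c) for c in cohorts]
    meta = meta_diffexpr(per_platform)
    twas_mean_z = twas.groupby("gene_id")["z"].mean().to_dict()
    calls, summary = classify_concordance(twas_mean_z, meta)
    files = []
    for df, name in zip(per_platform,
                        [f"diffexp_{c.platform}.tsv" for c in cohorts]):
        path = out / name
        write_table(df, path)
        files.append(path)
    write_table(meta, out / "diffexp_meta.tsv")
    write_table(calls, out / "concordance.tsv",
                meta={k: str(v) for k, v in summary.items()})
    files += [out / "diffexp_meta.tsv", out / "concordance.tsv"]
    logger.info("diffexp: %s", summary)
    return files


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "triage": _stage_triage,
    "score": _stage_score,
    "evaluate": _stage_evaluate,
    "drugs": _stage_drugs,
    "diffexp": _stage_diffexp,
}


def run_all(config: SimConfig, out_dir: str | Path,
            stages: Sequence[str] | None = None) -> RunManifest:
    """Execute the pipeline stages in order and write a run manifest.

    ``stages`` restricts execution (inputs of skipped stages must already
    exist in ``out_dir``).  A stage failure halts the run, naming the
    stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    selected = list(stages) if stages else list(STAGES)
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = RunManifest(config.digest(), config.seed, __version__, {})
    for stage in STAGES:
        if stage not in selected:
            continue
        try:
            files = _STAGE_FUNCS[stage](config, out)
        except (ContractError, FileNotFoundError) as exc:
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
        manifest.stages[stage] = _digests(files)
    manifest.to_json(out / "manifest.json")
    return manifest
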