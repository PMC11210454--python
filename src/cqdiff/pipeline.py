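"""End-to-end orchestration: QC -> exclusions -> normalization ->
differential testing -> classification, with a reproducible run manifest."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import __version__
from .differential import run_differential
from .io import AnalysisConfig, CqMatrix, SampleMetadata, validate_dataset, write_results
from .normalization import NormalizedMatrix, normalize_expression
from .qc import QCReport, apply_manual_exclusions, apply_missingness_filter, build_qc_report


@dataclass
class PipelineResult:
    diff_table: pd.DataFrame
    qc_report: QCReport
    normalized: NormalizedMatrix | None
    manifest: dict


def run_pipeline(
    cq: CqMatrix,
    metadata: SampleMetadata,
    config: AnalysisConfig | None = None,
    manual_exclusions=(),
    drop_hemolyzed: bool = False,
    drop_reference_outliers: bool = True,
) -> PipelineResult:
    """Run the full Cq-to-classification analysis.

    Stage order: spike-in report and hemolysis flags on all samples;
    reference-outlier samples dropped (they carry too little material);
    optionally hemolysis-flagged samples dropped; manual exclusions applied;
    assay missingness filter on the retained samples; reference
    normalization; per-assay permutation Yuen-Welch tests with BH adjustment
    and up/down classification. The manifest records counts at every gate.
    """
    cfg = config or AnalysisConfig()
    validate_dataset(cq, metadata)

    pre_excluded = list(metadata.table.index[metadata.table["excluded"]])
    work = cq.subset(samples=[s for s in cq.sample_ids if s not in pre_excluded]) if pre_excluded else cq

    qc_report = build_qc_report(
        work,
        hemolysis_pair=cfg.hemolysis_pair,
        hemolysis_threshold=cfg.hemolysis_threshold,
        reference_assays=list(cfg.reference_assays),
        spike_window=cfg.spike_window,
        missingness_threshold=cfg.missingness_threshold,
        outlier_rule=cfg.outlier_rule,
        outlier_cutoff=cfg.outlier_cutoff,
        outlier_gap=cfg.outlier_gap,
    )

    sample_exclusions: list[tuple] = []
    if drop_reference_outliers:
        flagged = qc_report.samples.index[qc_report.samples["reference_outlier_flag"].fillna(False)]
        sample_exclusions += [(s, "sample", qc_report.samples.loc[s, "outlier_reason"] or "reference_outlier")
                              for s in flagged]
    if drop_hemolyzed:
        flagged = qc_report.samples.index[
            qc_report.samples["hemolysis_flag"].astype("boolean").fillna(False)
        ]
        sample_exclusions += [(s, "sample", "hemolysis") for s in flagged]

    work, log1 = apply_manual_exclusions(work, sample_exclusions)
    work, log2 = apply_manual_exclusions(
        work, manual_exclusions, already_excluded={r["id"]: r for _, r in log1.iterrows()}
    )
    exclusion_log = pd.concat([log1, log2], ignore_index=True)

    # missingness denominators use currently retained samples
    retained_assays, excluded_assays, assay_table = apply_missingness_filter(
        work, cfg.missingness_threshold
    )
    qc_report.assays = assay_table
    for _, row in exclusion_log[exclusion_log["kind"] == "assay"].iterrows():
        if row["id"] in qc_report.assays.index:
            qc_report.assays.loc[row["id"], ["excluded", "exclusion_reason"]] = [True, row["reason"]]
    work = work.subset(assays=[a for a in work.assay_ids if a not in excluded_assays])

    groups = metadata.groups.reindex(work.sample_ids)
    normalized = normalize_expression(work, reference_assays=list(cfg.reference_assays))
    diff = run_differential(normalized, groups, cfg)

    n_tested = int((diff["class"] != "excluded").sum()) if len(diff) else 0
    manifest = {
        "software": {"name": "cqdiff", "version": __version__},
        "config": cfg.to_dict(),
        "seed": cfg.rng_seed,
        "counts": {
            "samples_in": len(cq.sample_ids),
            "samples_pre_excluded": len(pre_excluded),
            "samples_excluded": {
                reason: int((exclusion_log.loc[exclusion_log["kind"] == "sample", "reason"] == reason).sum())
                for reason in exclusion_log.loc[exclusion_log["kind"] == "sample", "reason"].unique()
            },
            "samples_analyzed": len(work.sample_ids),
            "assays_in": len(cq.assay_ids),
            "assays_excluded": {
                "missingness": len(excluded_assays),
                **{
                    reason: int((exclusion_log.loc[exclusion_log["kind"] == "assay", "reason"] == reason).sum())
                    for reason in exclusion_log.loc[exclusion_log["kind"] == "assay", "reason"].unique()
                },
            },
            "assays_tested": n_tested,
            "assays_not_evaluable": int((diff["class"] == "excluded").sum()) if len(diff) else 0,
            "hemolysis_flagged": int(
                qc_report.samples["hemolysis_flag"].astype("boolean").fillna(False).sum()
            ),
            "up": int((diff["class"] == "up").sum()) if len(diff) else 0,
            "down": int((diff["class"] == "down").sum()) if len(diff) else 0,
        },
        "exclusion_log": exclusion_log.to_dict(orient="records"),
    }
    return PipelineResult(diff_table=diff, qc_report=qc_report, normalized=normalized, manifest=manifest)


def run_and_write(cq, metadata, out_dir, config=None, **kwargs) -> PipelineResult:
    """Run the pipeline and persist diff_table.tsv, qc_report.tsv, manifest.json."""
    result = run_pipeline(cq, metadata, config=config, **kwargs)
    write_results(result.diff_table, result.qc_report, out_dir, manifest=result.manifest)
    if result.normalized is not None:
        expr = result.normalized.expr.copy()
        expr.index.name = "sample_id"
        expr.to_csv(f"{out_dir}/normalized_expression.tsv", sep="\t", float_format="%.10g")
    return result
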