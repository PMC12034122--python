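"""End-to-end orchestration: characterization -> origin classification ->
differential expression -> target prediction (significant piRNAs only) ->
biomarker statistics, with a consolidated JSON report.

Every stochastic step is seeded through the config, so re-running with an
identical config and inputs produces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .biomarker_stats import biomarker_panel
from .characterization import (
    compare_groups,
    chromosome_profile,
    length_profile,
    position_base_profile,
)
from .diffexpr import results_to_frame, run_de, size_factors
from .io_core import (
    AnnotationInterval,
    CountMatrix,
    PiRNARecord,
    SampleMeta,
    write_json,
)
from .origin_classify import calls_to_frame, classify_all
from .target_predict import ScoringScheme, predict_targets


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Stage toggles and parameters; thresholds default to the published gates."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    positions: tuple[int, ...] = (1, 10)
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    min_overlap_fraction: float = 0.5
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    top_n_targets: int = 25
    window: int = 80
    step: int = 40
    n_boot: int = 2000
    covariates: tuple[str, ...] | None = None
    targets_significant_only: bool = True
    run_characterization: bool = True
    run_origins: bool = True
    run_de: bool = True
    run_targets: bool = True
    run_biomarkers: bool = True


def run_pipeline(
    cfg: PipelineConfig,
    counts: CountMatrix,
    meta: Sequence[SampleMeta],
    records: Sequence[PiRNARecord],
    annotations: Sequence[AnnotationInterval] = (),
    transcripts: Sequence[tuple[str, str]] = (),
) -> dict:
    """Execute the enabled stages in order; write TSVs, report and MANIFEST."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "lfc_threshold": cfg.lfc_threshold,
            "alpha": cfg.alpha,
            "score_threshold": cfg.scheme.score_threshold,
            "energy_threshold": cfg.scheme.energy_threshold,
            "min_primary_run": cfg.scheme.min_primary_run,
            "min_secondary_run": cfg.scheme.min_secondary_run,
            "top_n_targets": cfg.top_n_targets,
            "min_overlap_fraction": cfg.min_overlap_fraction,
        },
    }
    manifest: list[str] = []
    groups = {m.sample_id: m.group for m in meta}

    def finish_stage(name: str) -> None:
        manifest.append(name)
        (out / "MANIFEST").write_text("\n".join(manifest) + "\n")

    sf = size_factors(counts)

    if cfg.run_characterization:
        try:
            block: dict = {}
            for pos in cfg.positions:
                prof = position_base_profile(counts, records, pos)
                prof.fractions.to_csv(out / f"position_{pos}_bias.tsv", sep="\t")
                tests = {}
                for base in "ACGU":
                    res = compare_groups(prof.fractions[base], groups)
                    tests[base] = {"U": res.statistic, "p": res.p_value}
                block[f"position_{pos}"] = tests
            lp = length_profile(counts, records)
            lp.fractions.to_csv(out / "length_profile.tsv", sep="\t")
            modal = lp.fractions.mean(axis=0).idxmax()
            block["modal_length"] = int(modal)
            chrom = chromosome_profile(counts, records, dict(zip(counts.sample_ids, sf)))
            chrom.to_csv(out / "chromosome_profile.tsv", sep="\t")
            block["top_chromosomes"] = (
                chrom.drop(index="unplaced", errors="ignore").sum(axis=1).nlargest(5).index.tolist()
            )
            report["characterization"] = block
            finish_stage("characterization")
        except Exception as exc:  # noqa: BLE001
            raise StageError("characterization", exc) from exc

    if cfg.run_origins:
        try:
            calls, summary = classify_all(
                records, annotations, counts, min_overlap_fraction=cfg.min_overlap_fraction
            )
            calls_to_frame(calls).to_csv(out / "origin_calls.tsv", sep="\t", index=False)
            summary.klass_fractions.to_csv(out / "origin_fractions.tsv", sep="\t")
            report["origins"] = {
                "repeat_fraction_mean": float(summary.repeat_fraction.mean()),
                "nonrepeat_fraction_mean": float(summary.nonrepeat_fraction.mean()),
                "rollup_mean": {
                    k: float(v) for k, v in summary.rollup().mean(axis=1).items()
                },
            }
            finish_stage("origins")
        except Exception as exc:  # noqa: BLE001
            raise StageError("origins", exc) from exc

    de_results = None
    if cfg.run_de:
        try:
            de_results, de_summary = run_de(
                counts, meta, lfc_threshold=cfg.lfc_threshold, alpha=cfg.alpha
            )
            results_to_frame(de_results).to_csv(out / "de_table.tsv", sep="\t", index=False)
            report["differential_expression"] = de_summary
            finish_stage("differential_expression")
        except Exception as exc:  # noqa: BLE001
            raise StageError("differential_expression", exc) from exc

    if cfg.run_targets:
        try:
            if cfg.targets_significant_only:
                if de_results is None:
                    raise ValueError(
                        "target stage restricted to significant piRNAs but the "
                        "differential-expression stage did not run"
                    )
                keep = {r.pirna_id for r in de_results if r.significant}
                query = [r for r in records if r.pirna_id in keep]
            else:
                query = list(records)
            if query and transcripts:
                ts = predict_targets(
                    query,
                    list(transcripts),
                    cfg.scheme,
                    window=cfg.window,
                    step=cfg.step,
                    top_n=cfg.top_n_targets,
                )
                ts.to_frame().to_csv(out / "targets.tsv", sep="\t", index=False)
                report["targets"] = {
                    "n_query_pirnas": len(query),
                    "n_transcripts": len(transcripts),
                    "n_pirnas_with_targets": sum(1 for v in ts.targets.values() if v),
                    "n_target_pairs": sum(len(v) for v in ts.targets.values()),
                }
            else:
                report["targets"] = {
                    "n_query_pirnas": len(query),
                    "n_transcripts": len(transcripts),
                    "n_pirnas_with_targets": 0,
                    "n_target_pairs": 0,
                }
            finish_stage("targets")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("targets", exc) from exc

    if cfg.run_biomarkers:
        try:
            if de_results is None:
                raise ValueError(
                    "biomarker stage requires differential-expression results"
                )
            roc_df, corr_df = biomarker_panel(
                counts,
                meta,
                de_results,
                covariates=list(cfg.covariates) if cfg.covariates else None,
                seed=cfg.seed,
                n_boot=cfg.n_boot,
            )
            roc_df.to_csv(out / "biomarker_roc.tsv", sep="\t", index=False)
            corr_df.to_csv(out / "biomarker_correlations.tsv", sep="\t", index=False)
            report["biomarkers"] = {
                "n_markers": int(len(roc_df)),
                "auc_min": float(roc_df["auc"].min()) if len(roc_df) else None,
                "auc_max": float(roc_df["auc"].max()) if len(roc_df) else None,
                "n_auc_ge_0.7": int((roc_df["auc"] >= 0.7).sum()) if len(roc_df) else 0,
            }
            finish_stage("biomarkers")
        except Exception as exc:  # noqa: BLE001
            raise StageError("biomarkers", exc) from exc

    write_json(report, out / "report.json")
    return report
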