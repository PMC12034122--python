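#!/usr/bin/env python
"""Diagnostic statistics for the gate-passing piRNAs: per-marker ROC/AUC
(tie-averaged rank formula, stratified-bootstrap CI, Mann-Whitney p) and
Spearman correlations against the clinical covariates, with the planted
biomarker and covariate links checked against truth.  Reads
results/cohort/ and results/de/, writes results/biomarkers/."""

import argparse
from pathlib import Path

import pandas as pd

from pirnascope.biomarker_stats import biomarker_panel
from pirnascope.diffexpr import gate_precomputed
from pirnascope.io_core import read_count_matrix, read_sample_meta, write_json


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--de", type=Path, default=Path("results/de"))
    ap.add_argument("--out", type=Path, default=Path("results/biomarkers"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    counts = read_count_matrix(args.cohort / "counts.tsv")
    meta = read_sample_meta(args.cohort / "meta.tsv")
    de = pd.read_csv(args.de / "de_table.tsv", sep="\t").dropna(subset=["padj"])
    results, _ = gate_precomputed(de.rename(columns={"log2FC": "log2fc"}))
    roc_df, corr_df = biomarker_panel(counts, meta, results, seed=args.seed)
    roc_df.to_csv(args.out / "biomarker_roc.tsv", sep="\t", index=False)
    corr_df.to_csv(args.out / "biomarker_correlations.tsv", sep="\t", index=False)

    truth = pd.read_csv(args.cohort / "truth_pirnas.tsv", sep="\t")
    links = pd.read_csv(args.cohort / "truth_covariates.tsv", sep="\t")
    bm = truth.loc[truth.is_biomarker, "pirna_id"].iloc[0]
    bm_auc = float(roc_df.loc[roc_df.pirna_id == bm, "auc"].iloc[0])

    link_rows = corr_df.merge(links, on=["pirna_id", "covariate"])
    write_json(
        {
            "n_markers": int(len(roc_df)),
            "auc_min": float(roc_df.auc.min()),
            "auc_max": float(roc_df.auc.max()),
            "planted_biomarker": {"pirna_id": bm, "auc": bm_auc},
            "planted_covariate_r": {
                f"{r.covariate}:{r.pirna_id}": float(r.r) for r in link_rows.itertuples()
            },
        },
        args.out / "biomarkers.json",
    )
    print(f"{len(roc_df)} markers; AUC range {roc_df.auc.min():.4f}-{roc_df.auc.max():.4f}")
    print(f"planted biomarker {bm}: AUC {bm_auc:.4f}")
    for r in link_rows.itertuples():
        print(f"planted link {r.covariate} ~ {r.pirna_id}: rho = {r.r:.3f} (p = {r.p_value:.4g})")
    print(f"outputs written to {args.out}")


if __name__ == "__main__":
    main()
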