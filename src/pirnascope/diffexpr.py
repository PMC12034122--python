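"""Negative-binomial differential expression between case and control.

A deliberately transparent re-implementation of the standard bulk count
workflow: median-of-ratios size factors, gene-wise method-of-moments
dispersion on normalized counts, a two-group NB GLM (log link, log size
factors as offsets) fitted by iteratively reweighted least squares, a Wald
test on the group coefficient, and Benjamini-Hochberg adjustment.  No
dispersion shrinkage, outlier refitting or independent filtering is
performed; significance gates are |log2FC| >= 1 and BH-adjusted p <= 0.05
by default.

The model for piRNA i in sample j with size factor s_j and group indicator
x_j (1 = case) is

    K_ij ~ NB(mu_ij, alpha_i),   mu_ij = s_j * exp(beta0_i + beta1_i x_j)

with Var(K) = mu + alpha mu^2; log2FC = beta1 / ln 2 (case relative to
control) and the Wald statistic is beta1 / SE(beta1) with a two-sided
normal p-value.

``load_published_de_table`` ships the published differential-expression
profile of 34 circulating piRNAs in Wilms tumor serum versus healthy
controls (piRBase identifiers with log2 fold change, p and BH-adjusted p),
so the gate arithmetic can be run on the published profile directly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import CountMatrix, SampleMeta

DISPERSION_FLOOR = 1e-8
MAX_IRLS_ITER = 100
IRLS_TOL = 1e-8


@dataclass
class DEResult:
    pirna_id: str
    base_mean: float
    log2fc: float
    se: float
    p_value: float
    padj: float | None
    significant: bool
    direction: str  # "up" | "down" | "none"
    flag: str = ""  # "", "all_zero", "not_converged"


def size_factors(
    counts: CountMatrix | np.ndarray, pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios normalization factors, one per sample.

    The reference for each piRNA is the geometric mean of its counts across
    samples; a sample's factor is the median ratio of its counts to the
    reference, over piRNAs with all-positive counts.  With
    ``pseudo_reference=True`` the reference is computed over positive
    entries of rows detected in at least half the samples (for sparse
    matrices without any all-positive row).
    """
    arr = counts.values if isinstance(counts, CountMatrix) else np.asarray(counts)
    arr = arr.astype(float)
    if pseudo_reference:
        rows = arr[(arr > 0).sum(axis=1) >= arr.shape[1] / 2]
        if rows.size == 0:
            raise ValueError("no piRNA detected in at least half the samples")
        logref = np.array([np.log(r[r > 0]).mean() for r in rows])
        with np.errstate(divide="ignore"):
            logratio = np.where(rows > 0, np.log(rows), np.nan) - logref[:, None]
        sf = np.exp(np.nanmedian(logratio, axis=0))
    else:
        allpos = (arr > 0).all(axis=1)
        if not allpos.any():
            raise ValueError(
                "no piRNA with positive counts in every sample; "
                "rerun with pseudo_reference=True"
            )
        rows = arr[allpos]
        logref = np.log(rows).mean(axis=1)
        sf = np.exp(np.median(np.log(rows) - logref[:, None], axis=0))
    return sf


def normalized_counts(counts: CountMatrix, sf: np.ndarray | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(counts)
    return counts.df / np.asarray(sf, dtype=float)[None, :]


def dispersion_mom(norm: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Gene-wise method-of-moments dispersion from normalized counts.

    Uses the within-group (pooled) sample variance so planted mean
    differences between groups do not inflate the estimate:
    alpha = (pooled_var - mean) / mean^2, floored at ``DISPERSION_FLOOR``.
    """
    norm = np.asarray(norm, dtype=float)
    groups = [norm[:, case_mask], norm[:, ~case_mask]]
    n_tot = sum(g.shape[1] for g in groups)
    ss = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups)
    pooled_var = ss / max(n_tot - 2, 1)
    mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def _case_mask(counts: CountMatrix, meta: Sequence[SampleMeta]) -> np.ndarray:
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in counts.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {', '.join(missing)}")
    mask = np.array([by_id[s].group == "case" for s in counts.sample_ids])
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    return mask


def nb_wald_test(
    counts: CountMatrix,
    meta: Sequence[SampleMeta],
    sf: np.ndarray | None = None,
) -> list[DEResult]:
    """Per-piRNA NB GLM Wald test of case vs control (unadjusted p).

    The two-group GLM is fitted by IRLS, vectorized across piRNAs: with
    design (intercept, case indicator) the working-response update and the
    weighted normal equations have closed per-group forms.  Wald
    z = beta1/SE with SE from the expected Fisher information using weights
    w = mu / (1 + alpha mu).  Because the dispersion is estimated from the
    same small sample, the two-sided p-value is taken from a t reference
    with n - 2 degrees of freedom rather than the normal: the plug-in
    normal Wald test is anticonservative at cohort-scale n, and the t
    reference restores type-I control without shrinkage machinery.
    """
    mask = _case_mask(counts, meta)
    if sf is None:
        sf = size_factors(counts)
    sf = np.asarray(sf, dtype=float)
    y = counts.values.astype(float)  # genes x samples
    n_genes, n_samples = y.shape
    norm = y / sf[None, :]
    alpha = dispersion_mom(norm, mask)
    base_mean = norm.mean(axis=1)

    # Parameters per gene: b0 (log control mean), b1 (log case/control ratio).
    all_zero = (y.sum(axis=1) == 0)
    ctrl, case = ~mask, mask
    # Initialize from group means of normalized counts (plus a small pseudo
    # count so log is defined for rows with an all-zero group).
    m_ctrl = norm[:, ctrl].mean(axis=1)
    m_case = norm[:, case].mean(axis=1)
    eps = 1e-8
    b0 = np.log(m_ctrl + eps)
    b1 = np.log(m_case + eps) - b0

    converged = np.zeros(n_genes, dtype=bool)
    prev_dev = np.full(n_genes, np.inf)
    for _ in range(MAX_IRLS_ITER):
        eta = b0[:, None] + b1[:, None] * mask[None, :] + np.log(sf)[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - np.log(sf)[None, :] + (y - mu) / mu
        # Weighted least squares for design [1, x]: closed form via group sums.
        sw_c = w[:, ctrl].sum(axis=1)
        sw_t = w[:, case].sum(axis=1)
        szw_c = (w[:, ctrl] * z[:, ctrl]).sum(axis=1)
        szw_t = (w[:, case] * z[:, case]).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            new_b0 = szw_c / sw_c
            new_b1 = szw_t / sw_t - new_b0
        upd = ~all_zero & np.isfinite(new_b0) & np.isfinite(new_b1)
        b0 = np.where(upd, new_b0, b0)
        b1 = np.where(upd, new_b1, b1)
        # NB deviance-like objective: track change in quasi-deviance.
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2.0 * np.where(
                y > 0, y * (np.log(y) - np.log(mu)), 0.0
            ).sum(axis=1) - 2.0 * ((y - mu) / (1.0 + alpha[:, None] * mu)).sum(axis=1)
        newly = np.abs(dev - prev_dev) < IRLS_TOL * (np.abs(dev) + 1.0)
        converged |= newly
        prev_dev = dev
        if converged[~all_zero].all():
            break

    eta = b0[:, None] + b1[:, None] * mask[None, :] + np.log(sf)[None, :]
    eta = np.clip(eta, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    sw_c = w[:, ctrl].sum(axis=1)
    sw_t = w[:, case].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = 1.0 / sw_c + 1.0 / sw_t  # (X'WX)^{-1}[1,1] for [1, x] design
        se = np.sqrt(var_b1) / np.log(2)  # on the log2 scale
        log2fc = b1 / np.log(2)
        zstat = b1 / np.sqrt(var_b1)
    p = 2.0 * stats.t.sf(np.abs(zstat), df=n_samples - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    results = []
    for i, pid in enumerate(counts.pirna_ids):
        if all_zero[i]:
            results.append(
                DEResult(
                    pirna_id=pid,
                    base_mean=0.0,
                    log2fc=0.0,
                    se=float("nan"),
                    p_value=1.0,
                    padj=None,
                    significant=False,
                    direction="none",
                    flag="all_zero",
                )
            )
            continue
        flag = "" if converged[i] else "not_converged"
        results.append(
            DEResult(
                pirna_id=pid,
                base_mean=float(base_mean[i]),
                log2fc=float(log2fc[i]),
                se=float(se[i]),
                p_value=float(p[i]),
                padj=None,
                significant=False,
                direction="none",
                flag=flag,
            )
        )
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_de_gates(
    results: Sequence[DEResult],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> tuple[list[DEResult], dict]:
    """Apply the fold-change and adjusted-p significance gates.

    A piRNA is significant iff |log2FC| >= ``lfc_threshold`` and
    padj <= ``alpha``.  Returns the significant subset plus a summary with
    total/up/down counts and log2FC extrema per direction.
    """
    gated: list[DEResult] = []
    for r in results:
        if r.padj is None:
            raise ValueError(f"{r.pirna_id}: padj not populated; run bh_adjust first")
        sig = abs(r.log2fc) >= lfc_threshold and r.padj <= alpha
        r.significant = sig
        r.direction = ("up" if r.log2fc > 0 else "down") if sig else "none"
        if sig:
            gated.append(r)
    up = [r.log2fc for r in gated if r.direction == "up"]
    down = [r.log2fc for r in gated if r.direction == "down"]
    summary = {
        "n_total": len(gated),
        "n_up": len(up),
        "n_down": len(down),
        "up_log2fc_min": min(up) if up else None,
        "up_log2fc_max": max(up) if up else None,
        "down_log2fc_min": min(down) if down else None,
        "down_log2fc_max": max(down) if down else None,
    }
    return gated, summary


def run_de(
    counts: CountMatrix,
    meta: Sequence[SampleMeta],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    pseudo_reference: bool = False,
) -> tuple[list[DEResult], dict]:
    """Full pipeline: size factors -> NB Wald -> BH -> gates."""
    sf = size_factors(counts, pseudo_reference=pseudo_reference)
    results = nb_wald_test(counts, meta, sf)
    testable = [r for r in results if r.flag != "all_zero"]
    padj = bh_adjust([r.p_value for r in testable])
    for r, q in zip(testable, padj):
        r.padj = float(q)
    for r in results:
        if r.flag == "all_zero":
            r.padj = 1.0
    _, summary = apply_de_gates(results, lfc_threshold, alpha)
    return results, summary


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pirna_id": [r.pirna_id for r in results],
            "baseMean": [r.base_mean for r in results],
            "log2FC": [r.log2fc for r in results],
            "se": [r.se for r in results],
            "pvalue": [r.p_value for r in results],
            "padj": [r.padj for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction for r in results],
            "flag": [r.flag for r in results],
        }
    )


def gate_precomputed(
    table: pd.DataFrame, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> tuple[list[DEResult], dict]:
    """Run only the significance gates on a precomputed log2FC/padj table.

    Expects columns ``pirna_id``, ``log2fc`` (or ``log2FC``) and ``padj``;
    ``pvalue`` is optional.
    """
    cols = {c.lower(): c for c in table.columns}
    lfc_col = cols.get("log2fc")
    if lfc_col is None or "padj" not in cols:
        raise ValueError("table must have log2fc and padj columns")
    results = []
    for _, row in table.iterrows():
        results.append(
            DEResult(
                pirna_id=str(row[cols.get("pirna_id", table.columns[0])]),
                base_mean=float("nan"),
                log2fc=float(row[lfc_col]),
                se=float("nan"),
                p_value=float(row[cols["pvalue"]]) if "pvalue" in cols else float("nan"),
                padj=float(row[cols["padj"]]),
                significant=False,
                direction="none",
            )
        )
    return apply_de_gates(results, lfc_threshold, alpha)


def load_published_de_table() -> pd.DataFrame:
    """The published serum Wilms-tumor vs healthy-control DE profile.

    34 circulating piRNAs (piRBase identifiers) with log2 fold change
    (case relative to control), raw p and BH-adjusted p, as reported for
    the 27-patient / 10-control serum cohort.
    """
    ref = importlib.resources.files("pirnascope.data") / "wt_serum_depirna.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
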