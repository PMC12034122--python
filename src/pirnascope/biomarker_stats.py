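"""Diagnostic ROC/AUC and clinicopathological correlation statistics.

AUC is computed with the tie-averaged Mann-Whitney rank formula
(AUC = U / (n1 n2), the probability a random case outranks a random
control), with the same rank test supplying the p-value; confidence
intervals come from a seeded stratified bootstrap.  Direction-aware mode
(the default) flips the reported AUC to 1 - AUC when it falls below 0.5
and records the orientation, so both up- and down-regulated markers are
reported on the discriminative scale.

Spearman correlations against clinicopathological covariates are Pearson
correlations on tie-averaged ranks; for n <= 7 an exact permutation
p-value is computed by full enumeration, otherwise the usual
t-approximation with n - 2 degrees of freedom.  Binary covariates
(metastasis, anaplasia, bilaterality) enter as 0/1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult, bh_adjust, size_factors
from .io_core import CountMatrix, SampleMeta


@dataclass
class ROCResult:
    pirna_id: str
    auc: float
    orientation: str  # "higher_in_case" | "lower_in_case"
    p_value: float
    ci95: tuple[float, float]
    curve: list[tuple[float, float]] = field(default_factory=list)  # (fpr, tpr)


@dataclass
class CorrelationResult:
    pirna_id: str
    covariate: str
    r: float
    p_value: float
    n: int
    flag: str = ""  # "" | "zero_variance"


def _rank_auc(case: np.ndarray, control: np.ndarray) -> float:
    """Tie-averaged AUC for orientation higher-in-case."""
    pooled = np.concatenate([case, control])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: case.size].sum()
    u1 = r1 - case.size * (case.size + 1) / 2.0
    return u1 / (case.size * control.size)


def roc_curve_points(case: np.ndarray, control: np.ndarray) -> list[tuple[float, float]]:
    """ROC points (fpr, tpr) over all distinct thresholds, higher-in-case.

    Starts at (0, 0), ends at (1, 1); both coordinates non-decreasing.
    Tied values move diagonally, so the trapezoid area equals the
    tie-averaged rank AUC.
    """
    thresholds = np.unique(np.concatenate([case, control]))[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float((case >= t).mean())
        fpr = float((control >= t).mean())
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def roc_auc(
    values: Sequence[float],
    labels: Sequence[str] | Sequence[int],
    pirna_id: str = "",
    direction_aware: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """ROC analysis of one marker; labels are 'case'/'control' or 1/0."""
    values = np.asarray(values, dtype=float)
    lab = np.asarray([1 if l in ("case", 1, True) else 0 for l in labels])
    case = values[lab == 1]
    control = values[lab == 0]
    if case.size == 0 or control.size == 0:
        raise ValueError("need at least one case and one control")
    auc = _rank_auc(case, control)
    orientation = "higher_in_case"
    if direction_aware and auc < 0.5:
        auc = 1.0 - auc
        orientation = "lower_in_case"
        case, control = -case, -control
    mw = stats.mannwhitneyu(case, control, alternative="two-sided", method="asymptotic")
    p = min(max(float(mw.pvalue), np.finfo(float).tiny), 1.0)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bc = case[rng.integers(0, case.size, case.size)]
        bk = control[rng.integers(0, control.size, control.size)]
        boot[b] = _rank_auc(bc, bk)
    lo, hi = np.quantile(boot, [0.025, 0.975])
    return ROCResult(
        pirna_id=pirna_id,
        auc=float(auc),
        orientation=orientation,
        p_value=p,
        ci95=(float(lo), float(hi)),
        curve=roc_curve_points(case, control),
    )


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    pirna_id: str = "",
    covariate: str = "",
    exact_max_n: int = 7,
) -> CorrelationResult:
    """Spearman rank correlation with exact permutation p for small n.

    For n <= ``exact_max_n`` the two-sided p-value is the fraction of all
    n! orderings of y with |rho| >= |rho_observed| (within numerical
    tolerance); otherwise the t-approximation with n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(
            pirna_id=pirna_id,
            covariate=covariate,
            r=float("nan"),
            p_value=1.0,
            n=int(x.size),
            flag="zero_variance",
        )
    r = _spearman_r(x, y)
    n = x.size
    if n <= exact_max_n:
        tol = 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rp = _spearman_r(x, y[list(perm)])
            if abs(rp) >= abs(r) - tol:
                count += 1
            total += 1
        p = count / total
    else:
        t = r * np.sqrt((n - 2) / max(1.0 - r**2, np.finfo(float).tiny))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    p = min(max(float(p), np.finfo(float).tiny), 1.0)
    return CorrelationResult(
        pirna_id=pirna_id, covariate=covariate, r=r, p_value=p, n=int(n)
    )


def biomarker_panel(
    counts: CountMatrix,
    meta: Sequence[SampleMeta],
    de_results: Sequence[DEResult],
    covariates: Sequence[str] | None = None,
    seed: int = 0,
    n_boot: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROC and covariate correlations for every gate-passing piRNA.

    Expression enters as log2(normalized count + 1) (monotone, so AUC and
    Spearman are unchanged by the transform; it is recorded for plotting).
    Covariates missing for more than half the samples are skipped.  BH
    correction is applied across the whole covariate-correlation family.
    Returns (roc_table, correlation_table), both sorted for determinism.
    """
    by_id = {m.sample_id: m for m in meta}
    sf = size_factors(counts)
    norm = counts.values / np.asarray(sf)[None, :]
    expr = np.log2(norm + 1.0)
    sample_ids = counts.sample_ids
    labels = [by_id[s].group for s in sample_ids]
    sig = [r for r in de_results if r.significant]
    if covariates is None:
        covariates = sorted({c for m in meta for c in m.covariates})

    roc_rows = []
    corr_results: list[CorrelationResult] = []
    pid_to_row = {p: i for i, p in enumerate(counts.pirna_ids)}
    for k, r in enumerate(sorted(sig, key=lambda r: r.pirna_id)):
        if r.pirna_id not in pid_to_row:
            continue
        vals = expr[pid_to_row[r.pirna_id]]
        roc = roc_auc(
            vals, labels, pirna_id=r.pirna_id, seed=seed + k, n_boot=n_boot
        )
        roc_rows.append(
            {
                "pirna_id": r.pirna_id,
                "direction": r.direction,
                "auc": roc.auc,
                "orientation": roc.orientation,
                "p_value": roc.p_value,
                "ci95_lo": roc.ci95[0],
                "ci95_hi": roc.ci95[1],
            }
        )
        for cov in covariates:
            pairs = [
                (vals[i], by_id[s].covariates[cov])
                for i, s in enumerate(sample_ids)
                if cov in by_id[s].covariates
            ]
            if len(pairs) < max(3, len(sample_ids) // 2):
                continue
            xv = [p[0] for p in pairs]
            yv = [p[1] for p in pairs]
            corr_results.append(
                spearman(xv, yv, pirna_id=r.pirna_id, covariate=cov)
            )

    corr_rows = []
    testable = [c for c in corr_results if not c.flag]
    if testable:
        padj = bh_adjust([c.p_value for c in testable])
    else:
        padj = []
    padj_iter = iter(padj)
    for c in corr_results:
        corr_rows.append(
            {
                "pirna_id": c.pirna_id,
                "covariate": c.covariate,
                "r": c.r,
                "p_value": c.p_value,
                "padj": float(next(padj_iter)) if not c.flag else float("nan"),
                "n": c.n,
                "flag": c.flag,
            }
        )
    roc_df = pd.DataFrame(
        roc_rows,
        columns=[
            "pirna_id",
            "direction",
            "auc",
            "orientation",
            "p_value",
            "ci95_lo",
            "ci95_hi",
        ],
    )
    if not roc_df.empty:
        roc_df = roc_df.sort_values(["auc", "pirna_id"], ascending=[False, True]).reset_index(
            drop=True
        )
    corr_df = pd.DataFrame(
        corr_rows,
        columns=["pirna_id", "covariate", "r", "p_value", "padj", "n", "flag"],
    )
    return roc_df, corr_df
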