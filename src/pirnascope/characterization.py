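"""Positional nucleotide bias, read-length and chromosomal profiling.

Primary piRNAs carry a 1U bias (uridine at the 5' first position) and
ping-pong-derived secondary piRNAs a 10A bias; profiling base composition at
positions 1 and 10 of the expressed pool, read-length spectra (24-34 nt,
typically peaking near 31 nt in serum), and the chromosomal distribution of
expression are the standard first-pass characterization of a piRNA-ome.
Group differences are assessed per sample with the Mann-Whitney U test:
each sample contributes one fraction, so samples (not reads) are the unit
of replication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CountMatrix, PiRNARecord

BASES = ("A", "C", "G", "U")

Weighting = Literal["read_weighted", "unique_pirna"]


@dataclass
class PositionBiasProfile:
    """Per-sample base fractions at a fixed 1-based position from the 5' end.

    ``fractions`` is a DataFrame (rows = samples, columns = A/C/G/U) that
    sums to 1 per sample; ``coverage`` gives, per sample, the fraction of
    (weighted) reads long enough to cover the position.  Samples with no
    covering reads have NaN fractions (flagged, not zero).
    """

    position: int
    fractions: pd.DataFrame
    coverage: pd.Series


@dataclass
class LengthProfile:
    """Per-sample read-weighted length fractions (rows = samples, cols = nt)."""

    fractions: pd.DataFrame


@dataclass
class GroupTestResult:
    """Two-sided Mann-Whitney U comparison of two groups of per-sample values."""

    statistic: float
    p_value: float
    group_medians: tuple[float, float]
    method: str  # "exact" | "normal_approx"


def _sequence_table(
    counts: CountMatrix, seqs: Sequence[PiRNARecord]
) -> dict[str, PiRNARecord]:
    by_id = {rec.pirna_id: rec for rec in seqs}
    missing = [p for p in counts.pirna_ids if p not in by_id]
    if missing:
        raise ValueError(
            f"piRNAs in count matrix without sequence: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else "")
        )
    return by_id


def position_base_profile(
    counts: CountMatrix,
    seqs: Sequence[PiRNARecord],
    position: int,
    weighting: Weighting = "read_weighted",
) -> PositionBiasProfile:
    """Base composition at a 1-based 5' position, per sample.

    With ``read_weighted`` each piRNA contributes its per-sample read count
    to the base found at ``position`` of its sequence; with ``unique_pirna``
    every expressed piRNA (count > 0) votes once.  piRNAs shorter than
    ``position`` contribute to no base; their weight is tracked via the
    coverage fraction instead.
    """
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    by_id = _sequence_table(counts, seqs)
    arr = counts.values.astype(float)
    if weighting == "unique_pirna":
        arr = (arr > 0).astype(float)
    elif weighting != "read_weighted":
        raise ValueError(f"unknown weighting {weighting!r}")

    base_at_pos = []
    for pid in counts.pirna_ids:
        seq = by_id[pid].sequence
        base_at_pos.append(seq[position - 1] if len(seq) >= position else None)

    n_samples = len(counts.sample_ids)
    tallies = np.zeros((n_samples, 4))
    covered = np.zeros(n_samples)
    total = arr.sum(axis=0)
    for i, base in enumerate(base_at_pos):
        if base is None:
            continue
        j = BASES.index(base)
        tallies[:, j] += arr[i]
        covered += arr[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = tallies / covered[:, None]
        coverage = np.where(total > 0, covered / np.where(total > 0, total, 1), np.nan)
    fractions = pd.DataFrame(fracs, index=counts.sample_ids, columns=list(BASES))
    return PositionBiasProfile(
        position=position,
        fractions=fractions,
        coverage=pd.Series(coverage, index=counts.sample_ids),
    )


def length_profile(counts: CountMatrix, seqs: Sequence[PiRNARecord]) -> LengthProfile:
    """Per-sample read-weighted fractions over observed sequence lengths."""
    by_id = _sequence_table(counts, seqs)
    lengths = np.array([len(by_id[p].sequence) for p in counts.pirna_ids])
    uniq = np.sort(np.unique(lengths))
    arr = counts.values.astype(float)
    tallies = np.zeros((len(counts.sample_ids), len(uniq)))
    for k, L in enumerate(uniq):
        tallies[:, k] = arr[lengths == L].sum(axis=0)
    total = tallies.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = tallies / total[:, None]
    return LengthProfile(
        fractions=pd.DataFrame(fracs, index=counts.sample_ids, columns=[int(x) for x in uniq])
    )


def chromosome_profile(
    counts: CountMatrix,
    seqs: Sequence[PiRNARecord],
    size_factors: Mapping[str, float] | Sequence[float],
) -> pd.DataFrame:
    """Normalized expression per chromosome, per sample.

    Each piRNA's normalized count (count / size factor) is assigned to the
    chromosome(s) of its loci; a piRNA mapped to k loci is split 1/k across
    them.  piRNAs with no locus accumulate under ``unplaced``.
    """
    if not isinstance(size_factors, Mapping):
        size_factors = dict(zip(counts.sample_ids, size_factors))
    sf = np.array([float(size_factors[s]) for s in counts.sample_ids])
    if (sf <= 0).any():
        raise ValueError("size factors must be strictly positive")
    by_id = _sequence_table(counts, seqs)
    norm = counts.values.astype(float) / sf[None, :]

    contrib: dict[str, np.ndarray] = {}
    for i, pid in enumerate(counts.pirna_ids):
        loci = by_id[pid].loci
        if not loci:
            targets = ["unplaced"]
        else:
            targets = [loc.chrom for loc in loci]
        w = 1.0 / len(targets)
        for chrom in targets:
            contrib.setdefault(chrom, np.zeros(len(counts.sample_ids)))
            contrib[chrom] += w * norm[i]
    chroms = sorted(contrib)
    return pd.DataFrame(
        {c: contrib[c] for c in chroms}, index=counts.sample_ids
    ).T  # rows = chromosome, cols = sample


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> GroupTestResult:
    """Two-sided Mann-Whitney U test on two groups of per-sample values.

    Uses the exact null distribution when n1 + n2 <= 12 and there are no
    ties; otherwise the normal approximation with tie and continuity
    correction.  The reported U is U1 (for ``group_a``); p is clamped to
    (0, 1].
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "normal_approx"
    res = stats.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    p = min(max(float(res.pvalue), np.finfo(float).tiny), 1.0)
    return GroupTestResult(
        statistic=float(res.statistic),
        p_value=p,
        group_medians=(float(np.median(a)), float(np.median(b))),
        method=method,
    )


def compare_groups(
    per_sample_values: pd.Series | Mapping[str, float],
    groups: Mapping[str, str],
) -> GroupTestResult:
    """Mann-Whitney case-vs-control comparison of one per-sample quantity."""
    values = pd.Series(per_sample_values).dropna()
    case = [v for s, v in values.items() if groups[s] == "case"]
    control = [v for s, v in values.items() if groups[s] == "control"]
    return mann_whitney(case, control)
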