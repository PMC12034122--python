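"""Genomic-origin classification of piRNA loci by annotation overlap.

Somatic and circulating piRNAs derive not only from transposable elements
but also, predominantly, from fragments of translation-machinery RNAs
(tRNA, rRNA, snRNA) and from genic/intergenic loci.  A locus is classified
by the annotation interval covering at least ``min_overlap_fraction`` of
its length; when several qualify, a fixed priority order decides
(repeat classes first, then structural RNAs, then genic features).  A
piRNA is repeat-related iff its class is a transposable element or simple
repeat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_core import (
    ANNOTATION_CLASSES,
    REPEAT_CLASSES,
    TRANSLATION_MACHINERY_CLASSES,
    AnnotationInterval,
    CountMatrix,
    GenomicLocus,
    PiRNARecord,
)

#: Precedence when several annotations cover a locus: simple repeats and
#: transposable elements outrank structural RNAs, which outrank genic
#: features; intron is last so that any overlapping exonic/ncRNA feature
#: wins over the host intron.
CLASS_PRIORITY = (
    "simple_repeat",
    "LINE",
    "SINE",
    "LTR",
    "DNA_repeat",
    "tRNA",
    "rRNA",
    "snRNA",
    "miRNA",
    "lncRNA",
    "pseudogene",
    "CDS",
    "UTR5",
    "UTR3",
    "intron",
)

#: Classes for which overlap must be on the same strand (gene-derived
#: fragments are sense-derived by default); repeat overlap is strand-agnostic.
STRANDED_CLASSES = frozenset(ANNOTATION_CLASSES) - REPEAT_CLASSES


@dataclass
class OriginCall:
    """Classification of one piRNA locus."""

    pirna_id: str
    locus: GenomicLocus
    klass: str  # annotation vocabulary + "intergenic"
    repeat_related: bool
    overlap_fraction: float


@dataclass
class OriginSummary:
    """Per-sample read totals and fractions per origin class.

    ``klass_reads``/``klass_fractions``: rows = class (including intergenic),
    columns = samples.  Fractions are over classified + intergenic reads;
    unplaced piRNAs (no locus) are reported separately and excluded.
    """

    klass_reads: pd.DataFrame
    klass_fractions: pd.DataFrame
    repeat_fraction: pd.Series
    nonrepeat_fraction: pd.Series
    unplaced_reads: pd.Series

    def rollup(self) -> pd.DataFrame:
        """Aggregate fractions: repeat, translation machinery, genic, intronic/intergenic."""
        f = self.klass_fractions
        groups = {
            "repeat": sorted(REPEAT_CLASSES & set(f.index)),
            "translation_machinery": sorted(TRANSLATION_MACHINERY_CLASSES & set(f.index)),
            "intron_intergenic": sorted({"intron", "intergenic"} & set(f.index)),
        }
        other = sorted(
            set(f.index) - set(sum(groups.values(), []))
        )
        groups["other_genic"] = other
        rows = {name: f.loc[classes].sum(axis=0) if classes else 0.0 for name, classes in groups.items()}
        return pd.DataFrame(rows).T


class AnnotationIndex:
    """Per-chromosome interval index over annotation intervals."""

    def __init__(self, annotations: Sequence[AnnotationInterval]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for iv in annotations:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def overlapping(self, locus: GenomicLocus) -> list[AnnotationInterval]:
        tree = self._trees.get(locus.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(locus.start, locus.end)]


def classify_locus(
    locus: GenomicLocus,
    index: AnnotationIndex,
    pirna_id: str = "",
    min_overlap_fraction: float = 0.5,
    stranded_genic: bool = True,
) -> OriginCall:
    """Classify one locus by best qualifying annotation overlap.

    Among intervals overlapping at least ``min_overlap_fraction`` of the
    locus length, the highest-priority class wins; ties within a class go
    to the larger overlap, then lexicographic interval name, so the result
    is independent of annotation input order.  No qualifying overlap means
    intergenic.
    """
    candidates = []
    for iv in index.overlapping(locus):
        if stranded_genic and iv.klass in STRANDED_CLASSES and iv.strand != locus.strand:
            continue
        ov = min(locus.end, iv.end) - max(locus.start, iv.start)
        frac = ov / len(locus)
        if frac >= min_overlap_fraction:
            candidates.append((CLASS_PRIORITY.index(iv.klass), -frac, iv.name, iv))
    if not candidates:
        return OriginCall(
            pirna_id=pirna_id,
            locus=locus,
            klass="intergenic",
            repeat_related=False,
            overlap_fraction=0.0,
        )
    candidates.sort()
    prio, negfrac, _, best = candidates[0]
    return OriginCall(
        pirna_id=pirna_id,
        locus=locus,
        klass=best.klass,
        repeat_related=best.klass in REPEAT_CLASSES,
        overlap_fraction=-negfrac,
    )


def classify_all(
    records: Sequence[PiRNARecord],
    annotations: Sequence[AnnotationInterval] | AnnotationIndex,
    counts: CountMatrix,
    min_overlap_fraction: float = 0.5,
    stranded_genic: bool = True,
) -> tuple[list[OriginCall], OriginSummary]:
    """Classify every locus and summarize per-sample read fractions by class.

    A piRNA mapped to k loci contributes count/k reads to each locus's
    class.  piRNAs without loci are tallied as unplaced and excluded from
    fractions.
    """
    index = (
        annotations
        if isinstance(annotations, AnnotationIndex)
        else AnnotationIndex(annotations)
    )
    by_id = {rec.pirna_id: rec for rec in records}
    missing = [p for p in counts.pirna_ids if p not in by_id]
    if missing:
        raise ValueError(f"piRNAs in count matrix without record: {', '.join(missing[:10])}")

    calls: list[OriginCall] = []
    n_samples = len(counts.sample_ids)
    klass_reads: dict[str, np.ndarray] = {}
    unplaced = np.zeros(n_samples)
    arr = counts.values.astype(float)
    for i, pid in enumerate(counts.pirna_ids):
        rec = by_id[pid]
        if not rec.loci:
            calls.append(
                OriginCall(
                    pirna_id=pid,
                    locus=GenomicLocus("unplaced", 0, 1),
                    klass="unplaced",
                    repeat_related=False,
                    overlap_fraction=0.0,
                )
            )
            unplaced += arr[i]
            continue
        w = 1.0 / len(rec.loci)
        for locus in rec.loci:
            call = classify_locus(
                locus,
                index,
                pirna_id=pid,
                min_overlap_fraction=min_overlap_fraction,
                stranded_genic=stranded_genic,
            )
            calls.append(call)
            klass_reads.setdefault(call.klass, np.zeros(n_samples))
            klass_reads[call.klass] += w * arr[i]

    order = list(CLASS_PRIORITY) + ["intergenic"]
    present = [k for k in order if k in klass_reads]
    reads_df = pd.DataFrame(
        {s: [klass_reads[k][j] for k in present] for j, s in enumerate(counts.sample_ids)},
        index=present,
    )
    totals = reads_df.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = reads_df / totals
    repeat_rows = [k for k in present if k in REPEAT_CLASSES]
    repeat_frac = fractions.loc[repeat_rows].sum(axis=0) if repeat_rows else pd.Series(0.0, index=counts.sample_ids)
    summary = OriginSummary(
        klass_reads=reads_df,
        klass_fractions=fractions,
        repeat_fraction=repeat_frac,
        nonrepeat_fraction=1.0 - repeat_frac,
        unplaced_reads=pd.Series(unplaced, index=counts.sample_ids),
    )
    return calls, summary


def calls_to_frame(calls: Sequence[OriginCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pirna_id": [c.pirna_id for c in calls],
            "chrom": [c.locus.chrom for c in calls],
            "start": [c.locus.start for c in calls],
            "end": [c.locus.end for c in calls],
            "strand": [c.locus.strand for c in calls],
            "klass": [c.klass for c in calls],
            "repeat_related": [c.repeat_related for c in calls],
            "overlap_fraction": [c.overlap_fraction for c in calls],
        }
    )
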