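"""Domain types and readers/writers for the formats every pipeline stage touches.

All genomic coordinates are 0-based half-open (BED convention) everywhere in
the package; 1-based numbers appear only in user-facing formatting.  DNA
input is normalized to the RNA alphabet (T -> U) at ingest so downstream
pairing logic is defined on {A, C, G, U} only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: Closed vocabulary of annotation classes.  Repeat-derived classes first
#: (transposable elements and simple repeats), then small structural RNAs of
#: the translation machinery, then genic features.
ANNOTATION_CLASSES = (
    "LINE",
    "SINE",
    "LTR",
    "DNA_repeat",
    "simple_repeat",
    "tRNA",
    "rRNA",
    "snRNA",
    "lncRNA",
    "miRNA",
    "pseudogene",
    "CDS",
    "UTR5",
    "UTR3",
    "intron",
)

#: Classes whose genomic source is a transposable element or simple repeat.
REPEAT_CLASSES = frozenset({"LINE", "SINE", "LTR", "DNA_repeat", "simple_repeat"})

#: Small RNAs of the translation machinery (used in origin roll-ups).
TRANSLATION_MACHINERY_CLASSES = frozenset({"tRNA", "rRNA", "snRNA"})

GROUPS = ("case", "control")
HISTOLOGIES = ("favorable", "unfavorable", "none")


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


@dataclass(frozen=True)
class GenomicLocus:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"locus {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotationInterval:
    """A labeled genomic interval drawn from the closed annotation vocabulary."""

    chrom: str
    start: int
    end: int
    strand: str
    klass: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.klass not in ANNOTATION_CLASSES:
            raise ValueError(
                f"unknown annotation class {self.klass!r}; "
                f"allowed: {', '.join(ANNOTATION_CLASSES)}"
            )

    @property
    def repeat_related(self) -> bool:
        return self.klass in REPEAT_CLASSES

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PiRNARecord:
    """One piRNA: identifier, RNA sequence, and zero or more genomic loci.

    Mature piRNAs are 24-31 nt; the 15-45 nt bound here is a hard sanity
    check on inputs, not a biological claim.
    """

    pirna_id: str
    sequence: str
    loci: list[GenomicLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if not seq:
            raise ValueError(f"piRNA {self.pirna_id}: empty sequence")
        for pos, base in enumerate(seq, start=1):
            if base not in RNA_ALPHABET:
                raise ValueError(
                    f"piRNA {self.pirna_id}: illegal character {base!r} at position {pos}"
                )
        if not 15 <= len(seq) <= 45:
            raise ValueError(
                f"piRNA {self.pirna_id}: length {len(seq)} outside sanity bound [15, 45]"
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SampleMeta:
    """Per-sample metadata: disease group, histology stratum and covariates."""

    sample_id: str
    group: str
    histology: str = "none"
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.histology not in HISTOLOGIES:
            raise ValueError(
                f"histology must be one of {HISTOLOGIES}, got {self.histology!r}"
            )


class CountMatrix:
    """Integer read counts, rows = piRNAs, columns = samples.

    Wraps a pandas DataFrame with invariant enforcement: unique row and
    column identifiers and non-negative integer entries.
    """

    def __init__(
        self,
        counts: np.ndarray | pd.DataFrame,
        pirna_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> None:
        if isinstance(counts, pd.DataFrame):
            df = counts.copy()
        else:
            if pirna_ids is None or sample_ids is None:
                raise ValueError("pirna_ids and sample_ids required for array input")
            df = pd.DataFrame(np.asarray(counts), index=list(pirna_ids), columns=list(sample_ids))
        dup_rows = df.index[df.index.duplicated()].unique().tolist()
        if dup_rows:
            raise FormatError(f"duplicate piRNA ID: {', '.join(map(str, dup_rows))}")
        dup_cols = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_cols:
            raise FormatError(f"duplicate sample ID: {', '.join(map(str, dup_cols))}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.issubdtype(arr.dtype, np.number) or not np.all(
                np.asarray(arr, dtype=float) == np.floor(np.asarray(arr, dtype=float))
            ):
                bad = np.argwhere(~np.isclose(arr.astype(float) % 1, 0))
                r, c = bad[0]
                raise FormatError(
                    f"non-integer count at row {df.index[r]!r}, column {df.columns[c]!r}"
                )
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        self._df = pd.DataFrame(arr.astype(np.int64), index=df.index, columns=df.columns)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def pirna_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self._df[list(sample_ids)])

    def subset_pirnas(self, pirna_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self._df.loc[list(pirna_ids)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self._df.equals(other._df)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column piRNA IDs, header row sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric count cell ({exc})") from exc
    return CountMatrix(numeric)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="pirna_id")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV: sample_id, group, histology, then covariates."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise FormatError(f"duplicate sample ID in metadata: {', '.join(dup)}")
    covar_cols = [c for c in df.columns if c not in ("sample_id", "group", "histology")]
    out = []
    for _, row in df.iterrows():
        covars = {}
        for c in covar_cols:
            val = row[c]
            if pd.isna(val):
                continue
            covars[c] = float(val)
        out.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                histology=str(row.get("histology", "none")) if "histology" in df.columns else "none",
                covariates=covars,
            )
        )
    return out


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    covar_names = sorted({name for m in meta for name in m.covariates})
    rows = []
    for m in meta:
        row = {"sample_id": m.sample_id, "group": m.group, "histology": m.histology}
        for name in covar_names:
            row[name] = m.covariates.get(name, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def join_meta(matrix: CountMatrix, meta: Sequence[SampleMeta]) -> dict[str, SampleMeta]:
    """Map every sample in `matrix` to exactly one metadata row, or fail."""
    by_id: dict[str, SampleMeta] = {}
    for m in meta:
        by_id[m.sample_id] = m
    missing = [s for s in matrix.sample_ids if s not in by_id]
    if missing:
        raise FormatError(f"samples without metadata: {', '.join(missing)}")
    return {s: by_id[s] for s in matrix.sample_ids}


def read_fasta(path: str | Path, as_records: bool = True):
    """Read FASTA sequences.

    With ``as_records=True`` returns a list of :class:`PiRNARecord` with
    sequences uppercased and T normalized to U; otherwise returns a list of
    ``(id, sequence)`` tuples with the same normalization (for transcripts).
    Order is preserved.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        for pos, base in enumerate(seq, start=1):
            if base not in RNA_ALPHABET:
                raise FormatError(
                    f"{path}: record {rec.id!r}: illegal character {base!r} at position {pos}"
                )
        if as_records:
            out.append(PiRNARecord(pirna_id=rec.id, sequence=seq))
        else:
            out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable, path: str | Path) -> None:
    """Write PiRNARecord objects or (id, seq) tuples as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, PiRNARecord):
                fh.write(f">{rec.pirna_id}\n{rec.sequence}\n")
            else:
                name, seq = rec
                fh.write(f">{name}\n{seq}\n")


def read_bed(path: str | Path) -> list[AnnotationInterval]:
    """Read BED6 annotation intervals; class carried in the name as 'klass:name'."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
            chrom, start_s, end_s, name_field, _score, strand = fields[:6]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            klass, _, name = name_field.partition(":")
            if klass not in ANNOTATION_CLASSES:
                raise FormatError(
                    f"{path}:{lineno}: unknown annotation class {klass!r}; "
                    f"allowed: {', '.join(ANNOTATION_CLASSES)}"
                )
            out.append(
                AnnotationInterval(
                    chrom=chrom, start=start, end=end, strand=strand, klass=klass, name=name
                )
            )
    return out


def write_bed(intervals: Sequence[AnnotationInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = f"{iv.klass}:{iv.name}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_loci_bed(path: str | Path) -> dict[str, list[GenomicLocus]]:
    """Read piRNA loci from BED6 (name field = piRNA ID); returns id -> loci."""
    loci: dict[str, list[GenomicLocus]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            loci.setdefault(name, []).append(
                GenomicLocus(chrom=chrom, start=start, end=end, strand=strand)
            )
    return loci


def write_loci_bed(records: Sequence[PiRNARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            for locus in rec.loci:
                fh.write(
                    f"{locus.chrom}\t{locus.start}\t{locus.end}\t{rec.pirna_id}\t0\t{locus.strand}\n"
                )


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON output (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
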