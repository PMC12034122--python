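"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the structure of a serum small-RNA cohort: 27 tumor
cases (14 favorable / 13 unfavorable histology) and 10 healthy controls
over ~307 piRNAs, per-sample library sizes spanning roughly 7k-370k reads,
negative-binomially dispersed counts with a spiked differentially
expressed subset, 24-34 nt sequence pools peaking at 31 nt with
controllable base composition at positions 1 and 10, an annotation
landscape in which repeat-derived classes carry ~4% of reads and
translation-machinery RNAs ~79%, transcripts with planted binding sites,
and clinical covariates with planted monotone associations.

Every generator draws from its own named RNG stream (a ``SeedSequence``
spawned with a fixed per-generator key), so adding one generator never
perturbs another's output under the same seed, and emits a truth table
consumed only by tests and closed-loop checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import (
    AnnotationInterval,
    CountMatrix,
    GenomicLocus,
    PiRNARecord,
    SampleMeta,
)
from .target_predict import ScoringScheme

BASES = np.array(["A", "C", "G", "U"])
RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Named RNG stream keys, one per generator.
_STREAMS = {
    "counts": 1,
    "sequences": 2,
    "annotation": 3,
    "targets": 4,
    "clinical": 5,
    "bias_cohort": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Cohort shape, library-size range and piRNA count mirror the serum
    cohort the pipeline was designed around (27 cases / 10 controls, 307
    piRNAs, 6,958-369,956 reads per sample); the DE spike holds 12
    up-regulated and 22 down-regulated piRNAs at |log2FC| = 2, a
    representative central effect for a circulating piRNA profile whose
    published fold changes span ~1.0-5.3.  Origin read-fraction targets
    put ~4% of reads on repeat classes and ~79.2% on translation-machinery
    RNAs, with tRNA fragments dominating.
    """

    n_case: int = 27
    n_control: int = 10
    n_favorable: int = 14  # favorable-histology cases; rest unfavorable
    n_pirnas: int = 307
    library_size_range: tuple[int, int] = (6_958, 369_956)
    dispersion: float = 0.2
    baseline_log_sd: float = 1.0
    n_up: int = 12
    n_down: int = 22
    lfc_up: float = 2.0
    lfc_down: float = 2.0  # magnitude; applied with negative sign

    # Base-probability vectors (A, C, G, U) at positions 1 and 10, per group.
    # Controls show the canonical 1U predominance; cases an elevated 1C and
    # 10U, the serum-tumor pattern the characterization stage is meant to
    # detect.  No 10A (ping-pong) bias in either group.
    pos1_control: tuple[float, ...] = (0.15, 0.15, 0.10, 0.60)
    pos1_case: tuple[float, ...] = (0.15, 0.35, 0.10, 0.40)
    pos10_control: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    pos10_case: tuple[float, ...] = (0.20, 0.25, 0.20, 0.35)

    lengths: tuple[int, ...] = tuple(range(24, 35))
    length_probs: tuple[float, ...] = (
        0.02, 0.03, 0.04, 0.06, 0.08, 0.12, 0.15, 0.25, 0.12, 0.08, 0.05,
    )

    # Target read fractions per origin class (sums to 1).
    origin_fractions: dict = field(
        default_factory=lambda: {
            "LINE": 0.016,
            "SINE": 0.010,
            "LTR": 0.006,
            "DNA_repeat": 0.004,
            "simple_repeat": 0.004,
            "tRNA": 0.450,
            "rRNA": 0.200,
            "snRNA": 0.142,
            "intron": 0.100,
            "intergenic": 0.068,
        }
    )
    chrom_names: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)
    #: chromosomes carrying most piRNA expression in serum profiles
    dominant_chroms: tuple[str, ...] = ("chr1", "chr6", "chr11", "chr16", "chr17")
    dominant_weight: float = 2.5
    genome_length: int = 2_000_000  # per chromosome

    # Clinical covariates: name -> (rank of linked down-regulated piRNA,
    # logistic slope on standardized expression).  Negative slope = low
    # expression raises event probability, the direction reported for
    # serum piRNA markers.
    covariate_links: dict = field(
        default_factory=lambda: {
            "metastasis": (0, -2.5),
            "anaplasia": (1, -2.5),
            "bilateral": (2, -2.5),
        }
    )

    def __post_init__(self) -> None:
        for vec in (self.pos1_control, self.pos1_case, self.pos10_control, self.pos10_case):
            if abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0:
                raise ValueError(f"base probabilities must be a distribution, got {vec}")
        if abs(sum(self.length_probs) - 1.0) > 1e-9:
            raise ValueError("length probabilities must sum to 1")
        if abs(sum(self.origin_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("origin fractions must sum to 1")
        if self.n_up + self.n_down > self.n_pirnas:
            raise ValueError("more DE piRNAs than piRNAs")
        if self.dispersion <= 0 or self.n_case < 2 or self.n_control < 2:
            raise ValueError("invalid cohort parameters")


@dataclass
class TruthTable:
    """Ground truth per simulated entity; consumed only by tests."""

    pirnas: pd.DataFrame  # pirna_id, is_de, true_lfc, klass, is_biomarker
    transcripts: pd.DataFrame | None = None
    covariates: pd.DataFrame | None = None


def _sample_ids(cfg: SimConfig) -> tuple[list[str], list[str]]:
    cases = [f"WT{i+1:02d}" for i in range(cfg.n_case)]
    controls = [f"HC{i+1:02d}" for i in range(cfg.n_control)]
    return cases, controls


def gen_counts(cfg: SimConfig, seed: int = 0) -> tuple[CountMatrix, list[SampleMeta], TruthTable]:
    """NB-distributed counts with a spiked DE subset.

    Counts for piRNA i in sample j follow NB with mean
    ``p_i * L_j * 2^(lfc_i * case_j)`` (baseline proportion p_i from a
    normalized log-normal, library size L_j log-uniform over the
    configured range) and the configured dispersion.
    """
    rng = _rng(seed, "counts")
    cases, controls = _sample_ids(cfg)
    samples = cases + controls
    is_case = np.array([1] * cfg.n_case + [0] * cfg.n_control)

    lo, hi = cfg.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))

    props = np.exp(rng.normal(0.0, cfg.baseline_log_sd, size=cfg.n_pirnas))
    props /= props.sum()

    ids = [f"piR-sim-{i+1:04d}" for i in range(cfg.n_pirnas)]
    de_idx = rng.choice(cfg.n_pirnas, size=cfg.n_up + cfg.n_down, replace=False)
    up_idx = np.sort(de_idx[: cfg.n_up])
    down_idx = np.sort(de_idx[cfg.n_up :])
    lfc = np.zeros(cfg.n_pirnas)
    lfc[up_idx] = cfg.lfc_up
    lfc[down_idx] = -cfg.lfc_down

    mu = props[:, None] * lib[None, :] * np.power(2.0, lfc[:, None] * is_case[None, :])
    r = 1.0 / cfg.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    matrix = CountMatrix(counts, pirna_ids=ids, sample_ids=samples)

    meta = []
    for k, s in enumerate(cases):
        hist = "favorable" if k < cfg.n_favorable else "unfavorable"
        meta.append(SampleMeta(sample_id=s, group="case", histology=hist))
    for s in controls:
        meta.append(SampleMeta(sample_id=s, group="control", histology="none"))

    truth = TruthTable(
        pirnas=pd.DataFrame(
            {
                "pirna_id": ids,
                "is_de": lfc != 0,
                "true_lfc": lfc,
                "is_biomarker": [i == (up_idx[0] if len(up_idx) else -1) for i in range(cfg.n_pirnas)],
            }
        )
    )
    return matrix, meta, truth


def _draw_position_bases(rng: np.random.Generator, n: int, probs: Sequence[float]) -> np.ndarray:
    return rng.choice(BASES, size=n, p=np.asarray(probs, dtype=float))


def gen_sequences(
    cfg: SimConfig,
    seed: int = 0,
    ids: Sequence[str] | None = None,
    group: str = "control",
) -> list[PiRNARecord]:
    """Sequence pool with group-controlled composition at positions 1 and 10.

    Lengths follow the configured 24-34 nt distribution; bases at positions
    1 and 10 follow the group's probability vectors and all other positions
    are uniform.
    """
    rng = _rng(seed, "sequences")
    if ids is None:
        ids = [f"piR-sim-{i+1:04d}" for i in range(cfg.n_pirnas)]
    n = len(ids)
    lengths = rng.choice(cfg.lengths, size=n, p=np.asarray(cfg.length_probs))
    maxlen = max(cfg.lengths)
    body = BASES[rng.integers(0, 4, size=(n, maxlen))]
    pos1 = cfg.pos1_case if group == "case" else cfg.pos1_control
    pos10 = cfg.pos10_case if group == "case" else cfg.pos10_control
    body[:, 0] = _draw_position_bases(rng, n, pos1)
    body[:, 9] = _draw_position_bases(rng, n, pos10)
    return [
        PiRNARecord(pirna_id=pid, sequence="".join(body[i, : lengths[i]]))
        for i, pid in enumerate(ids)
    ]


def gen_base_bias_cohort(cfg: SimConfig, seed: int = 0) -> pd.DataFrame:
    """Per-sample base fractions at positions 1 and 10 for a full cohort.

    Each sample gets its own uniformly-weighted pool of ``n_pirnas``
    sequences drawn with its group's composition vectors; returns a frame
    with one row per sample (columns ``group``, ``p1_A..p1_U``,
    ``p10_A..p10_U``).  This is the per-sample granularity on which the
    case-vs-control Mann-Whitney comparison of composition operates.
    """
    rng = _rng(seed, "bias_cohort")
    cases, controls = _sample_ids(cfg)
    rows = []
    for sample, group in [(s, "case") for s in cases] + [(s, "control") for s in controls]:
        p1 = cfg.pos1_case if group == "case" else cfg.pos1_control
        p10 = cfg.pos10_case if group == "case" else cfg.pos10_control
        b1 = _draw_position_bases(rng, cfg.n_pirnas, p1)
        b10 = _draw_position_bases(rng, cfg.n_pirnas, p10)
        row = {"sample_id": sample, "group": group}
        for base in BASES:
            row[f"p1_{base}"] = float((b1 == base).mean())
            row[f"p10_{base}"] = float((b10 == base).mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def gen_annotation_landscape(
    cfg: SimConfig,
    records: Sequence[PiRNARecord],
    shares: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[list[AnnotationInterval], list[PiRNARecord], TruthTable]:
    """Non-overlapping annotations with each locus planted in its true class.

    Every piRNA receives exactly one locus, wholly inside a dedicated
    annotation interval of its assigned class (or in an unannotated gap for
    intergenic truth).  Classes are assigned by a deterministic greedy
    balance on expression shares so realized read fractions track the
    configured targets: piRNAs are visited in descending share order and
    each goes to the class with the largest remaining share deficit.
    """
    rng = _rng(seed, "annotation")
    n = len(records)
    if shares is None:
        shares_arr = np.full(n, 1.0 / n)
    else:
        shares_arr = np.asarray(shares, dtype=float)
        shares_arr = shares_arr / shares_arr.sum()

    classes = list(cfg.origin_fractions)
    targets = np.array([cfg.origin_fractions[k] for k in classes])
    deficit = targets.copy()
    assigned = [""] * n
    for i in np.argsort(-shares_arr, kind="stable"):
        k = int(np.argmax(deficit))
        assigned[i] = classes[k]
        deficit[k] -= shares_arr[i]

    chrom_w = np.array(
        [cfg.dominant_weight if c in cfg.dominant_chroms else 1.0 for c in cfg.chrom_names]
    )
    chrom_w = chrom_w / chrom_w.sum()
    cursors = {c: 0 for c in cfg.chrom_names}

    annotations: list[AnnotationInterval] = []
    out_records: list[PiRNARecord] = []
    for i, rec in enumerate(records):
        klass = assigned[i]
        chrom = str(rng.choice(np.array(cfg.chrom_names), p=chrom_w))
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(100, 500))
        locus_len = len(rec.sequence)
        start_region = cursors[chrom] + gap
        if klass == "intergenic":
            locus = GenomicLocus(chrom, start_region, start_region + locus_len, strand)
            cursors[chrom] = locus.end
        else:
            pad_l = int(rng.integers(20, 200))
            pad_r = int(rng.integers(20, 200))
            iv = AnnotationInterval(
                chrom=chrom,
                start=start_region,
                end=start_region + pad_l + locus_len + pad_r,
                strand=strand,
                klass=klass,
                name=f"{klass}_{i+1}",
            )
            annotations.append(iv)
            locus = GenomicLocus(chrom, iv.start + pad_l, iv.start + pad_l + locus_len, strand)
            cursors[chrom] = iv.end
        if cursors[chrom] > cfg.genome_length:
            raise ValueError(
                f"genome length {cfg.genome_length} too small to place intervals on {chrom}"
            )
        out_records.append(PiRNARecord(rec.pirna_id, rec.sequence, loci=[locus]))

    truth = TruthTable(
        pirnas=pd.DataFrame(
            {"pirna_id": [r.pirna_id for r in records], "klass": assigned}
        )
    )
    return annotations, out_records, truth


def _revcomp_rna(seq: str) -> str:
    return "".join(RNA_COMPLEMENT[b] for b in reversed(seq))


def _wobble_partner(base: str) -> str | None:
    return {"G": "U", "U": "G"}.get(base)


def gen_target_fixtures(
    records: Sequence[PiRNARecord],
    seed: int = 0,
    flank: int = 40,
    scheme: ScoringScheme | None = None,
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Transcripts with planted binding sites and known filter verdicts.

    Per piRNA, four transcripts embedded in random flanks:

    * ``perfect``   - exact reverse complement (passes all filters for
      piRNAs long enough that a perfect duplex clears the score threshold,
      i.e. >= 27 nt under the default scheme);
    * ``primary_broken``  - mismatch at piRNA position 8, capping the
      primary-seed WC run at 6 (fail);
    * ``secondary_broken`` - mismatch at position 17, capping the
      secondary-seed run at 5 (fail);
    * ``wobble_seed`` - a G:U wobble inside the primary seed (first G/U at
      piRNA positions 5-8; mismatch fallback if none), which breaks the WC
      run despite costing little score (fail).
    """
    rng = _rng(seed, "targets")
    scheme = scheme or ScoringScheme()
    transcripts: list[tuple[str, str]] = []
    rows = []

    def flanks() -> tuple[str, str]:
        return (
            "".join(rng.choice(BASES, size=flank)),
            "".join(rng.choice(BASES, size=flank)),
        )

    for rec in records:
        seq = rec.sequence
        L = len(seq)
        site = _revcomp_rna(seq)  # site[k] pairs piRNA position L - k
        perfect_sc = sum(
            scheme.wc_match * (scheme.seed_weight if scheme.seed_span[0] <= p <= scheme.seed_span[1] else 1.0)
            for p in range(1, L + 1)
        )

        def emit(kind: str, site_seq: str, exp_primary: int, exp_secondary: int, exp_sc: float):
            left, right = flanks()
            tid = f"{rec.pirna_id}_{kind}"
            transcripts.append((tid, left + site_seq + right))
            exp_pass = (
                exp_primary >= scheme.min_primary_run
                and exp_secondary >= scheme.min_secondary_run
                and exp_sc >= scheme.score_threshold
            )
            rows.append(
                {
                    "transcript_id": tid,
                    "pirna_id": rec.pirna_id,
                    "kind": kind,
                    "expected_pass": exp_pass,
                    "expected_primary_run": exp_primary,
                    "expected_secondary_run": exp_secondary,
                }
            )

        # (a) perfect reverse complement
        emit("perfect", site, min(10, L - 1), min(10, max(L - 11, 0)), perfect_sc)

        # (b) primary seed broken: mismatch at position 8 (self-pair is
        # never WC or wobble)
        pos = 8
        s = list(site)
        s[L - pos] = seq[pos - 1]
        delta = scheme.seed_weight * (scheme.wc_match - scheme.mismatch)
        emit("primary_broken", "".join(s), 6, min(10, max(L - 11, 0)), perfect_sc - delta)

        # (c) secondary seed broken: mismatch at position 17
        pos = 17
        s = list(site)
        s[L - pos] = seq[pos - 1]
        emit("secondary_broken", "".join(s), 10, 5, perfect_sc - (scheme.wc_match - scheme.mismatch))

        # (d) wobble in the primary seed
        wob_pos = next((p for p in range(5, 9) if _wobble_partner(seq[p - 1])), None)
        s = list(site)
        if wob_pos is not None:
            s[L - wob_pos] = _wobble_partner(seq[wob_pos - 1])
            exp_primary = max(wob_pos - 2, 11 - wob_pos)
            d = scheme.seed_weight * (scheme.wc_match - scheme.wobble)
        else:  # no wobble-capable base in 5-8: fall back to a mismatch
            wob_pos = 8
            s[L - wob_pos] = seq[wob_pos - 1]
            exp_primary = 6
            d = scheme.seed_weight * (scheme.wc_match - scheme.mismatch)
        emit("wobble_seed", "".join(s), exp_primary, min(10, max(L - 11, 0)), perfect_sc - d)

    truth = TruthTable(pirnas=pd.DataFrame(), transcripts=pd.DataFrame(rows))
    return transcripts, truth


def gen_clinical(
    cfg: SimConfig,
    counts: CountMatrix,
    meta: Sequence[SampleMeta],
    truth: TruthTable,
    seed: int = 0,
) -> tuple[list[SampleMeta], TruthTable]:
    """Plant monotone covariate associations into case metadata.

    Each configured binary covariate is linked to one down-regulated piRNA:
    the event probability is ``sigmoid(slope * z)`` with z the standardized
    log2 normalized expression across cases.  A negative slope means low
    expression raises the event probability.  Nuisance covariates (stage,
    age in months, sex) carry no planted effect.  Controls receive no
    tumor covariates.
    """
    rng = _rng(seed, "clinical")
    tp = truth.pirnas
    down_ids = tp.loc[tp["true_lfc"] < 0, "pirna_id"].tolist()
    lib = counts.values.sum(axis=0).astype(float)
    expr = np.log2(counts.values / lib[None, :] * 1e6 + 1.0)  # CPM scale
    case_cols = [i for i, m in enumerate(meta) if m.group == "case"]
    pid_row = {p: i for i, p in enumerate(counts.pirna_ids)}

    link_rows = []
    planted: dict[str, np.ndarray] = {}
    for cov, (rank, slope) in cfg.covariate_links.items():
        if rank >= len(down_ids):
            raise ValueError(f"covariate {cov}: no down-regulated piRNA at rank {rank}")
        pid = down_ids[rank]
        z = expr[pid_row[pid], case_cols]
        z = (z - z.mean()) / (z.std() or 1.0)
        prob = 1.0 / (1.0 + np.exp(-(slope * z)))
        planted[cov] = (rng.random(len(case_cols)) < prob).astype(float)
        link_rows.append({"covariate": cov, "pirna_id": pid, "slope": slope})

    out = []
    ci = 0
    for m in meta:
        if m.group != "case":
            out.append(SampleMeta(m.sample_id, m.group, m.histology, dict(m.covariates)))
            continue
        covars = dict(m.covariates)
        for cov in cfg.covariate_links:
            covars[cov] = float(planted[cov][ci])
        covars["stage"] = float(rng.integers(1, 5))
        covars["age_months"] = float(np.clip(rng.normal(42.0, 18.0), 6.0, None).round(1))
        covars["sex"] = float(rng.integers(0, 2))
        out.append(SampleMeta(m.sample_id, m.group, m.histology, covars))
        ci += 1
    truth_out = TruthTable(
        pirnas=truth.pirnas, transcripts=truth.transcripts, covariates=pd.DataFrame(link_rows)
    )
    return out, truth_out


@dataclass
class SimulatedCohort:
    """Everything a full pipeline run consumes, plus the merged truth."""

    counts: CountMatrix
    meta: list[SampleMeta]
    records: list[PiRNARecord]
    annotations: list[AnnotationInterval]
    transcripts: list[tuple[str, str]]
    truth: TruthTable


def simulate_cohort(
    cfg: SimConfig | None = None,
    seed: int = 0,
    with_targets: bool = True,
    n_target_pirnas: int = 10,
) -> SimulatedCohort:
    """Run every generator and merge the truth tables.

    Target fixtures are built for the first ``n_target_pirnas`` DE piRNAs
    (restricted to sequences of >= 28 nt so a perfect duplex clears the
    score threshold; shorter DE piRNAs are re-sequenced to 28-31 nt for
    fixture purposes only would distort truth, so they are simply not used
    as fixture anchors).
    """
    cfg = cfg or SimConfig()
    counts, meta, truth_counts = gen_counts(cfg, seed)
    records = gen_sequences(cfg, seed, ids=counts.pirna_ids)
    shares = counts.values.sum(axis=1).astype(float)
    annotations, records, truth_ann = gen_annotation_landscape(cfg, records, shares, seed)
    truth_p = truth_counts.pirnas.merge(truth_ann.pirnas, on="pirna_id")
    truth = TruthTable(pirnas=truth_p)
    meta, truth = gen_clinical(
        cfg, counts, meta, TruthTable(pirnas=truth_p), seed
    )

    transcripts: list[tuple[str, str]] = []
    if with_targets:
        de_ids = truth.pirnas.loc[truth.pirnas["is_de"], "pirna_id"].tolist()
        by_id = {r.pirna_id: r for r in records}
        anchors = [by_id[p] for p in de_ids if len(by_id[p]) >= 28][:n_target_pirnas]
        transcripts, truth_tx = gen_target_fixtures(anchors, seed)
        truth = TruthTable(
            pirnas=truth.pirnas, transcripts=truth_tx.transcripts, covariates=truth.covariates
        )
    return SimulatedCohort(
        counts=counts,
        meta=meta,
        records=records,
        annotations=annotations,
        transcripts=transcripts,
        truth=truth,
    )
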