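"""piRNA -> transcript duplex alignment, seed filtration and target ranking.

A piRNA is aligned 5'->3' against the reverse of a transcript window so
that antiparallel base pairing can be scored positionally: Watson-Crick
pairs (A:U, U:A, G:C, C:G) score +5, G:U wobbles +1, mismatches -3, with
affine gap penalties (-9 open, -4 extend) and pair scores doubled at piRNA
positions 2-8 (the classic guide-seed weighting).  The optimal local
alignment is found by dynamic programming with affine gap states.

Candidate duplexes are gated three ways:

* alignment score sc >= 170,
* an additive per-pair binding-energy proxy en <= -20.0 kcal/mol
  (G:C -2.2, A:U -1.1, wobble -0.6 per paired position; this is a
  deliberately simple non-thermodynamic model, not nearest-neighbor
  stacking), and
* seed complementarity: the primary seed site (piRNA positions 2-11) must
  contain a run of >= 7 consecutive Watson-Crick pairs, the secondary seed
  site (positions 12-21) a run of >= 6.  Wobbles are not Watson-Crick and
  break a run.

Per piRNA, passing transcripts are ranked by score (ties: lower energy,
then lexicographic transcript id) and capped at the top 25.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

#: Per-pair stacking-free energy proxy (kcal/mol).
ENERGY_PER_PAIR = {"GC": -2.2, "AU": -1.1, "WOBBLE": -0.6}

MASK_SYMBOLS = {"WC": "|", "WOBBLE": ":", "MISMATCH": "x", "GAP": "-", "UNALIGNED": "."}

PRIMARY_SEED = (2, 11)  # 1-based inclusive piRNA positions
SECONDARY_SEED = (12, 21)
NEG_INF = -1e18


@dataclass(frozen=True)
class ScoringScheme:
    wc_match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0  # first gapped position
    gap_extend: float = -4.0  # each additional gapped position
    seed_weight: float = 2.0  # multiplier on pair scores at piRNA positions 2-8
    seed_span: tuple[int, int] = (2, 8)  # 1-based inclusive
    score_threshold: float = 170.0
    energy_threshold: float = -20.0
    min_primary_run: int = 7
    min_secondary_run: int = 6

    def __post_init__(self) -> None:
        if not (self.wc_match > self.wobble > 0 > self.mismatch):
            raise ValueError("require wc_match > wobble > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")

    def pair_score(self, pirna_pos: int, b1: str, b2: str) -> float:
        """Score of pairing piRNA base b1 (1-based position) with target base b2."""
        if (b1, b2) in WC_PAIRS:
            s = self.wc_match
        elif (b1, b2) in WOBBLE_PAIRS:
            s = self.wobble
        else:
            s = self.mismatch
        if self.seed_span[0] <= pirna_pos <= self.seed_span[1]:
            s *= self.seed_weight
        return s

    def gap_cost(self, length: int) -> float:
        return 0.0 if length == 0 else self.gap_open + self.gap_extend * (length - 1)


def pair_type(b1: str, b2: str) -> str:
    if (b1, b2) in WC_PAIRS:
        return "WC"
    if (b1, b2) in WOBBLE_PAIRS:
        return "WOBBLE"
    return "MISMATCH"


@dataclass
class DuplexHit:
    """One piRNA <-> transcript-window alignment.

    ``mask`` holds one state per piRNA position (1..L):
    WC/WOBBLE/MISMATCH/GAP/UNALIGNED.  ``columns`` is the full alignment
    column list as (piRNA position | None, reversed-window position | None)
    1-based pairs; target-only gap columns appear here but not in the mask.
    """

    pirna_id: str
    transcript_id: str
    pirna_seq: str
    window_seq: str  # transcript window, 5'->3'
    window_offset: int  # start of window within the transcript (0-based)
    sc: float
    en: float
    mask: list[str] = field(default_factory=list)
    columns: list[tuple[int | None, int | None]] = field(default_factory=list)
    primary_run: int = 0
    secondary_run: int = 0
    passes_filters: bool = False

    @property
    def mask_string(self) -> str:
        return "".join(MASK_SYMBOLS[m] for m in self.mask)

    @property
    def tx_span(self) -> tuple[int, int]:
        """Aligned span in transcript coordinates (0-based half-open)."""
        js = [j for _, j in self.columns if j is not None]
        if not js:
            return (self.window_offset, self.window_offset)
        n = len(self.window_seq)
        # reversed-window position j (1-based) maps to window index n - j
        idx = [n - j for j in js]
        return (self.window_offset + min(idx), self.window_offset + max(idx) + 1)


def align_duplex(
    pirna_seq: str,
    window: str,
    scheme: ScoringScheme | None = None,
    pirna_id: str = "",
    transcript_id: str = "",
    window_offset: int = 0,
) -> DuplexHit:
    """Optimal local duplex alignment of a piRNA against a transcript window.

    The window is reversed internally so columns pair the piRNA 5'->3' with
    the target 3'->5' (antiparallel).  Affine-gap Smith-Waterman with three
    states (pair, gap-in-target, gap-in-piRNA); adjacent opposite gaps are
    allowed.  Ties are broken toward the first-reached cell (row-major), so
    output is deterministic.
    """
    scheme = scheme or ScoringScheme()
    if not pirna_seq or not window:
        raise ValueError("empty sequence")
    if len(window) > 200:
        raise ValueError(f"window length {len(window)} exceeds 200")
    s1 = pirna_seq.upper().replace("T", "U")
    s2 = window.upper().replace("T", "U")[::-1]
    m, n = len(s1), len(s2)
    go, ge = scheme.gap_open, scheme.gap_extend

    # Pair-score matrix (m x n), seed weighting on piRNA rows.
    a2 = np.frombuffer(s2.encode(), dtype="S1")
    P = np.empty((m, n))
    for i in range(m):
        b1 = s1[i]
        row = np.full(n, scheme.mismatch)
        for b2, sc_val in _pair_row(b1, scheme):
            row[a2 == b2.encode()] = sc_val
        if scheme.seed_span[0] <= i + 1 <= scheme.seed_span[1]:
            row = row * scheme.seed_weight
        P[i] = row

    M = np.full((m + 1, n + 1), NEG_INF)
    Ix = np.full((m + 1, n + 1), NEG_INF)  # gap consuming piRNA (s1)
    Iy = np.full((m + 1, n + 1), NEG_INF)  # gap consuming target (s2)
    M[0, :] = NEG_INF
    for i in range(1, m + 1):
        prevM, prevIx, prevIy = M[i - 1], Ix[i - 1], Iy[i - 1]
        # M: pair s1[i-1] with s2[j-1]
        best_prev = np.maximum.reduce(
            [np.zeros(n), prevM[:-1], prevIx[:-1], prevIy[:-1]]
        )
        M[i, 1:] = P[i - 1] + best_prev
        # Ix: vertical gap (piRNA base unpaired)
        Ix[i, :] = np.maximum.reduce([prevM + go, prevIx + ge, prevIy + go])
        # Iy: horizontal gap; expand recurrence via running max:
        # Iy[i,j] = ge*j + max_{k<j}( max(M,Ix)[i,k] + go - ge*(k+1) )
        base = np.maximum(M[i], Ix[i])
        q = base + go - ge * (np.arange(n + 1) + 1)
        run = np.maximum.accumulate(q)
        Iy[i, 1:] = ge * (np.arange(1, n + 1)) + run[:-1]

    flat = int(np.argmax(M[1:, 1:]))
    bi, bj = divmod(flat, n)
    bi, bj = bi + 1, bj + 1
    score = float(M[bi, bj])
    if score <= 0:
        hit = DuplexHit(
            pirna_id=pirna_id,
            transcript_id=transcript_id,
            pirna_seq=s1,
            window_seq=window.upper().replace("T", "U"),
            window_offset=window_offset,
            sc=max(score, 0.0),
            en=0.0,
            mask=["UNALIGNED"] * m,
        )
        return hit

    columns = _traceback(M, Ix, Iy, P, bi, bj, go, ge)
    mask = ["UNALIGNED"] * m
    for ci, cj in columns:
        if ci is not None and cj is not None:
            mask[ci - 1] = pair_type(s1[ci - 1], s2[cj - 1])
        elif ci is not None:
            mask[ci - 1] = "GAP"
    hit = DuplexHit(
        pirna_id=pirna_id,
        transcript_id=transcript_id,
        pirna_seq=s1,
        window_seq=window.upper().replace("T", "U"),
        window_offset=window_offset,
        sc=score,
        en=0.0,
        mask=mask,
        columns=columns,
    )
    hit.en = duplex_energy(hit)
    hit.primary_run, hit.secondary_run, seed_ok = seed_filter(hit, scheme)
    hit.passes_filters = (
        seed_ok
        and hit.sc >= scheme.score_threshold
        and hit.en <= scheme.energy_threshold
    )
    return hit


def _pair_row(b1: str, scheme: ScoringScheme):
    out = []
    for b2 in "ACGU":
        if (b1, b2) in WC_PAIRS:
            out.append((b2, scheme.wc_match))
        elif (b1, b2) in WOBBLE_PAIRS:
            out.append((b2, scheme.wobble))
    return out


def _traceback(M, Ix, Iy, P, bi, bj, go, ge):
    """Recover alignment columns from the DP matrices (1-based indices)."""
    cols: list[tuple[int | None, int | None]] = []
    state = "M"
    i, j = bi, bj
    tol = 1e-6
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                break
            cols.append((i, j))
            rest = M[i, j] - P[i - 1, j - 1]
            if abs(rest) <= tol:
                break  # local alignment start
            if abs(rest - M[i - 1, j - 1]) <= tol:
                state = "M"
            elif abs(rest - Ix[i - 1, j - 1]) <= tol:
                state = "Ix"
            elif abs(rest - Iy[i - 1, j - 1]) <= tol:
                state = "Iy"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failure in M state")
            i, j = i - 1, j - 1
        elif state == "Ix":
            cols.append((i, None))
            val = Ix[i, j]
            if abs(val - (M[i - 1, j] + go)) <= tol:
                state = "M"
            elif abs(val - (Ix[i - 1, j] + ge)) <= tol:
                state = "Ix"
            elif abs(val - (Iy[i - 1, j] + go)) <= tol:
                state = "Iy"
            else:  # pragma: no cover
                raise AssertionError("traceback failure in Ix state")
            i = i - 1
        else:  # Iy
            cols.append((None, j))
            val = Iy[i, j]
            if abs(val - (M[i, j - 1] + go)) <= tol:
                state = "M"
            elif abs(val - (Ix[i, j - 1] + go)) <= tol:
                state = "Ix"
            elif abs(val - (Iy[i, j - 1] + ge)) <= tol:
                state = "Iy"
            else:  # pragma: no cover
                raise AssertionError("traceback failure in Iy state")
            j = j - 1
    cols.reverse()
    return cols


def rescore_hit(hit: DuplexHit, scheme: ScoringScheme | None = None) -> float:
    """Recompute the alignment score from the stored columns.

    Used as a self-consistency check: the DP score must equal the sum of
    pair scores plus affine gap costs over the emitted alignment.
    """
    scheme = scheme or ScoringScheme()
    s1, s2 = hit.pirna_seq, hit.window_seq[::-1]
    total = 0.0
    gap_run_x = gap_run_y = 0
    for ci, cj in hit.columns:
        if ci is not None and cj is not None:
            total += scheme.gap_cost(gap_run_x) + scheme.gap_cost(gap_run_y)
            gap_run_x = gap_run_y = 0
            total += scheme.pair_score(ci, s1[ci - 1], s2[cj - 1])
        elif ci is not None:
            gap_run_x += 1
        else:
            gap_run_y += 1
    total += scheme.gap_cost(gap_run_x) + scheme.gap_cost(gap_run_y)
    return total


def duplex_energy(hit: DuplexHit) -> float:
    """Additive binding-energy proxy over paired positions (kcal/mol).

    G:C or C:G pairs contribute -2.2, A:U or U:A -1.1, wobbles -0.6;
    mismatches, gaps and unaligned positions contribute nothing.
    """
    s1, s2 = hit.pirna_seq, hit.window_seq[::-1]
    en = 0.0
    for ci, cj in hit.columns:
        if ci is None or cj is None:
            continue
        b1, b2 = s1[ci - 1], s2[cj - 1]
        if (b1, b2) in WC_PAIRS:
            en += ENERGY_PER_PAIR["GC"] if {b1, b2} == {"G", "C"} else ENERGY_PER_PAIR["AU"]
        elif (b1, b2) in WOBBLE_PAIRS:
            en += ENERGY_PER_PAIR["WOBBLE"]
    return round(en, 10)


def longest_wc_run(mask: Sequence[str], lo: int, hi: int) -> int:
    """Longest run of consecutive WC states within 1-based positions [lo, hi]."""
    best = run = 0
    for pos in range(lo, min(hi, len(mask)) + 1):
        if mask[pos - 1] == "WC":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def seed_filter(
    hit: DuplexHit, scheme: ScoringScheme | None = None
) -> tuple[int, int, bool]:
    """Consecutive-WC seed-run filtration.

    Returns (primary_run, secondary_run, seed_pass): longest consecutive
    Watson-Crick runs within piRNA positions 2-11 and 12-21 (truncated for
    short piRNAs); anything that is not a WC pair breaks a run.  seed_pass
    requires primary >= 7 and secondary >= 6 by default.
    """
    scheme = scheme or ScoringScheme()
    primary = longest_wc_run(hit.mask, *PRIMARY_SEED)
    secondary = longest_wc_run(hit.mask, *SECONDARY_SEED)
    ok = primary >= scheme.min_primary_run and secondary >= scheme.min_secondary_run
    return primary, secondary, ok


def scan_transcript(
    pirna_seq: str,
    transcript_id: str,
    transcript_seq: str,
    scheme: ScoringScheme | None = None,
    pirna_id: str = "",
    window: int = 80,
    step: int = 40,
) -> DuplexHit:
    """Best duplex of one piRNA over sliding windows of one transcript.

    Windows of ``window`` nt advance by ``step``; the best-scoring hit
    (ties: lower energy, then smaller window offset) is returned.
    """
    scheme = scheme or ScoringScheme()
    L = len(transcript_seq)
    starts = list(range(0, max(L - window, 0) + 1, step))
    if not starts or starts[-1] + window < L:
        starts.append(max(L - window, 0))
    best: DuplexHit | None = None
    seen = set()
    for s in starts:
        if s in seen:
            continue
        seen.add(s)
        hit = align_duplex(
            pirna_seq,
            transcript_seq[s : s + window],
            scheme,
            pirna_id=pirna_id,
            transcript_id=transcript_id,
            window_offset=s,
        )
        key = (hit.sc, -hit.en, -hit.window_offset)
        if best is None or key > (best.sc, -best.en, -best.window_offset):
            best = hit
    assert best is not None
    return best


@dataclass
class TargetSet:
    """Ranked passing targets per piRNA (score desc, energy asc, id lex)."""

    targets: dict[str, list[DuplexHit]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.targets):
            for rank, hit in enumerate(self.targets[pid], start=1):
                rows.append(
                    {
                        "pirna_id": pid,
                        "rank": rank,
                        "transcript_id": hit.transcript_id,
                        "sc": hit.sc,
                        "en": hit.en,
                        "primary_run": hit.primary_run,
                        "secondary_run": hit.secondary_run,
                        "tx_start": hit.tx_span[0],
                        "tx_end": hit.tx_span[1],
                        "mask": hit.mask_string,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "pirna_id",
                "rank",
                "transcript_id",
                "sc",
                "en",
                "primary_run",
                "secondary_run",
                "tx_start",
                "tx_end",
                "mask",
            ],
        )


def predict_targets(
    pirnas: Sequence,
    transcripts: Sequence[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    window: int = 80,
    step: int = 40,
    top_n: int = 25,
    keep_all_hits: bool = False,
) -> TargetSet | tuple[TargetSet, list[DuplexHit]]:
    """Scan every piRNA against every transcript and rank passing targets.

    ``pirnas`` may be PiRNARecord objects or (id, seq) tuples; transcripts
    are (id, seq) tuples.  Per piRNA the best hit per transcript is gated
    by the score/energy/seed filters and the top ``top_n`` passing
    transcripts are kept.
    """
    scheme = scheme or ScoringScheme()
    if not pirnas or not transcripts:
        raise ValueError("pirnas and transcripts must be non-empty")
    norm_pirnas = []
    for rec in pirnas:
        if hasattr(rec, "pirna_id"):
            norm_pirnas.append((rec.pirna_id, rec.sequence))
        else:
            norm_pirnas.append(tuple(rec))
    targets: dict[str, list[DuplexHit]] = {}
    all_hits: list[DuplexHit] = []
    for pid, pseq in norm_pirnas:
        hits = []
        for tid, tseq in transcripts:
            hit = scan_transcript(
                pseq, tid, tseq, scheme, pirna_id=pid, window=window, step=step
            )
            all_hits.append(hit)
            if hit.passes_filters:
                hits.append(hit)
        hits.sort(key=lambda h: (-h.sc, h.en, h.transcript_id))
        targets[pid] = hits[:top_n]
    ts = TargetSet(targets=targets)
    if keep_all_hits:
        return ts, all_hits
    return ts
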