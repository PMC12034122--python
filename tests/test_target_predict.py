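import itertools
import re

import numpy as np
import pytest

from pirnascope.synthetic_data import _revcomp_rna, gen_target_fixtures
from pirnascope.io_core import PiRNARecord
from pirnascope.target_predict import (
    DuplexHit,
    ScoringScheme,
    align_duplex,
    duplex_energy,
    longest_wc_run,
    predict_targets,
    rescore_hit,
    scan_transcript,
    seed_filter,
)


def brute_force_local(s1: str, s2: str, scheme: ScoringScheme) -> float:
    """Independent oracle: max score over all monotone matchings.

    Skipped positions between consecutive aligned pairs are charged as one
    grouped affine gap per side; unaligned ends are free (local alignment).
    """
    m, n = len(s1), len(s2)
    best = 0.0
    for k in range(1, min(m, n) + 1):
        for c1 in itertools.combinations(range(m), k):
            for c2 in itertools.combinations(range(n), k):
                sc = 0.0
                for t in range(k):
                    sc += scheme.pair_score(c1[t] + 1, s1[c1[t]], s2[c2[t]])
                    if t:
                        sc += scheme.gap_cost(c1[t] - c1[t - 1] - 1)
                        sc += scheme.gap_cost(c2[t] - c2[t - 1] - 1)
                best = max(best, sc)
    return best


def naive_runs(mask, lo, hi):
    """Oracle for seed runs: regex over the windowed mask string."""
    s = "".join("W" if m == "WC" else "." for m in mask[lo - 1 : min(hi, len(mask))])
    return max((len(x) for x in re.findall(r"W+", s)), default=0)


class TestAlignDuplex:
    def test_perfect_duplex_score_and_mask(self, rna_factory):
        rng = np.random.default_rng(0)
        p = rna_factory(rng, 30)
        hit = align_duplex(p, "AAUU" + _revcomp_rna(p) + "CCGG")
        assert hit.sc == 185.0  # 7 seed positions x 10 + 23 x 5
        assert hit.mask == ["WC"] * 30
        assert hit.passes_filters

    def test_single_mismatch_at_position_15(self, rna_factory):
        rng = np.random.default_rng(1)
        p = rna_factory(rng, 30)
        site = list(_revcomp_rna(p))
        site[30 - 15] = p[14]  # self-pair is neither WC nor wobble
        hit = align_duplex(p, "AAUU" + "".join(site) + "CCGG")
        assert hit.sc == 177.0  # 185 - 5 - 3
        assert hit.mask[14] == "MISMATCH"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_duplex("", "ACGU")

    def test_window_cap(self):
        with pytest.raises(ValueError, match="200"):
            align_duplex("ACGU", "A" * 201)

    def test_dp_equals_brute_force_small(self, rna_factory):
        scheme = ScoringScheme()
        rng = np.random.default_rng(42)
        for _ in range(60):
            s1 = rna_factory(rng, int(rng.integers(2, 9)))
            s2 = rna_factory(rng, int(rng.integers(2, 9)))
            hit = align_duplex(s1, s2[::-1], scheme)  # reverse so internal target == s2
            assert hit.sc == pytest.approx(brute_force_local(s1, s2, scheme))

    def test_score_self_consistency(self, rna_factory):
        rng = np.random.default_rng(7)
        for _ in range(30):
            p = rna_factory(rng, int(rng.integers(20, 35)))
            w = rna_factory(rng, 80)
            hit = align_duplex(p, w)
            if hit.columns:
                assert rescore_hit(hit) == pytest.approx(hit.sc)


class TestEnergy:
    def _hit_from_pairs(self, pairs):
        """Build an all-aligned hit from explicit (pirna_base, target_base) pairs."""
        s1 = "".join(b1 for b1, _ in pairs)
        s2 = "".join(b2 for _, b2 in pairs)
        return DuplexHit(
            pirna_id="p",
            transcript_id="t",
            pirna_seq=s1,
            window_seq=s2[::-1],
            window_offset=0,
            sc=0.0,
            en=0.0,
            mask=["WC"] * len(pairs),
            columns=[(i + 1, i + 1) for i in range(len(pairs))],
        )

    def test_all_gc_duplex(self):
        hit = self._hit_from_pairs([("G", "C")] * 15 + [("C", "G")] * 15)
        assert duplex_energy(hit) == pytest.approx(-66.0)

    def test_no_paired_positions(self):
        hit = self._hit_from_pairs([("A", "U")])
        hit.columns = []
        assert duplex_energy(hit) == 0.0

    def test_mixed_hand_sum(self):
        pairs = [("G", "C")] * 10 + [("A", "U")] * 5 + [("G", "U")] * 2
        hit = self._hit_from_pairs(pairs)
        assert duplex_energy(hit) == pytest.approx(-28.7)


class TestSeedFilter:
    def _hit_with_mask(self, mask):
        L = len(mask)
        return DuplexHit(
            pirna_id="p",
            transcript_id="t",
            pirna_seq="A" * L,
            window_seq="U" * L,
            window_offset=0,
            sc=0.0,
            en=0.0,
            mask=list(mask),
        )

    def test_full_wc_passes(self):
        p, s, ok = seed_filter(self._hit_with_mask(["WC"] * 30))
        assert (p, s, ok) == (10, 10, True)

    def test_run_of_six_fails_primary(self):
        mask = ["WC"] * 7 + ["MISMATCH"] * 23  # WC at 1-7 -> positions 2-7 = run 6
        p, s, ok = seed_filter(self._hit_with_mask(mask))
        assert p == 6 and not ok

    def test_wobble_breaks_run(self):
        mask = ["WC"] * 30
        mask[7] = "WOBBLE"  # position 8
        p, s, ok = seed_filter(self._hit_with_mask(mask))
        assert p == 6 and not ok

    def test_matches_naive_scanner_on_random_masks(self):
        rng = np.random.default_rng(9)
        states = np.array(["WC", "WOBBLE", "MISMATCH", "GAP", "UNALIGNED"])
        for _ in range(2000):
            mask = list(rng.choice(states, size=int(rng.integers(15, 32)), p=[0.6, 0.1, 0.15, 0.05, 0.1]))
            assert longest_wc_run(mask, 2, 11) == naive_runs(mask, 2, 11)
            assert longest_wc_run(mask, 12, 21) == naive_runs(mask, 12, 21)

    def test_short_pirna_truncates_secondary_window(self):
        p, s, _ = seed_filter(self._hit_with_mask(["WC"] * 16))
        assert p == 10 and s == 5  # positions 12-16 only


class TestMonotonicity:
    def test_wc_conversion_never_hurts(self, rna_factory):
        """Converting one non-WC position of a fixed alignment to Watson-Crick
        raises sc, lowers en and never shrinks a seed run, so it can never
        flip pass -> fail for that alignment."""
        import copy

        rng = np.random.default_rng(21)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        checked = 0
        for _ in range(60):
            p = rna_factory(rng, 28)
            site = list(_revcomp_rna(p))
            for i in sorted(rng.choice(28, size=4, replace=False)):
                site[28 - (i + 1)] = p[i]  # self-pair = mismatch at position i+1
            base = align_duplex(p, "".join(site))
            non_wc = [
                (ci, cj)
                for ci, cj in base.columns
                if ci is not None and cj is not None and base.mask[ci - 1] != "WC"
            ]
            if not non_wc:
                continue
            ci, cj = non_wc[0]
            better = copy.deepcopy(base)
            # mutate the paired window base to the complement, keeping the
            # alignment columns fixed
            w = list(better.window_seq)
            w[len(w) - cj] = comp[p[ci - 1]]
            better.window_seq = "".join(w)
            better.mask[ci - 1] = "WC"
            assert rescore_hit(better) >= rescore_hit(base)
            assert duplex_energy(better) <= duplex_energy(base)
            for lo, hi in ((2, 11), (12, 21)):
                assert longest_wc_run(better.mask, lo, hi) >= longest_wc_run(base.mask, lo, hi)
            checked += 1
        assert checked >= 30


class TestPredictTargets:
    def test_planted_site_ranked_first(self, rna_factory):
        rng = np.random.default_rng(3)
        p = rna_factory(rng, 30)
        planted = rna_factory(rng, 50) + _revcomp_rna(p) + rna_factory(rng, 50)
        decoy = rna_factory(rng, 130)
        ts = predict_targets([("q", p)], [("decoy", decoy), ("planted", planted)])
        hits = ts.targets["q"]
        assert hits and hits[0].transcript_id == "planted"
        assert hits[0].passes_filters

    def test_top_25_cap(self, rna_factory):
        rng = np.random.default_rng(4)
        p = rna_factory(rng, 30)
        txs = [
            (f"t{i:02d}", rna_factory(rng, 30) + _revcomp_rna(p) + rna_factory(rng, 30))
            for i in range(30)
        ]
        ts = predict_targets([("q", p)], txs)
        assert len(ts.targets["q"]) == 25

    def test_wobble_decoys_excluded_by_seed_filter(self):
        recs = [PiRNARecord(f"p{i}", seq) for i, seq in enumerate(
            ["GGAUGGCAUCGAUGCAUGCAUCGAUGGCAUC", "CCGAUGGCCAUGGCAUCCGGAUGCAUGGCC"]
        )]
        txs, truth = gen_target_fixtures(recs, seed=11)
        wob = truth.transcripts[truth.transcripts.kind == "wobble_seed"]
        tx_by_id = dict(txs)
        for _, row in wob.iterrows():
            rec = next(r for r in recs if r.pirna_id == row.pirna_id)
            hit = scan_transcript(rec.sequence, row.transcript_id, tx_by_id[row.transcript_id])
            assert hit.sc >= 170.0  # wobble is cheap in score...
            assert not hit.passes_filters  # ...but breaks the WC seed run

    def test_deterministic_output(self, rna_factory):
        rng = np.random.default_rng(5)
        p = rna_factory(rng, 29)
        txs = [(f"t{i}", rna_factory(rng, 40) + _revcomp_rna(p) + rna_factory(rng, 40)) for i in range(4)]
        out1 = predict_targets([("q", p)], txs).to_frame().to_csv(index=False)
        out2 = predict_targets([("q", p)], txs).to_frame().to_csv(index=False)
        assert out1 == out2

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            predict_targets([], [("t", "ACGU")])
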