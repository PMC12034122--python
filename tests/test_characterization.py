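import itertools

import numpy as np
import pytest
from scipy import stats

from pirnascope.characterization import (
    chromosome_profile,
    compare_groups,
    length_profile,
    mann_whitney,
    position_base_profile,
)
from pirnascope.io_core import CountMatrix, GenomicLocus, PiRNARecord
from pirnascope.synthetic_data import SimConfig, gen_base_bias_cohort


class TestPositionBias:
    def test_hand_tally_read_weighted(self, tiny_counts, tiny_records):
        # s1: pU count 3, pC count 1 -> U 0.75, C 0.25 at position 1
        prof = position_base_profile(tiny_counts, tiny_records, 1)
        assert prof.fractions.loc["s1", "U"] == pytest.approx(0.75)
        assert prof.fractions.loc["s1", "C"] == pytest.approx(0.25)

    def test_hand_tally_unique_pirna(self, tiny_counts, tiny_records):
        prof = position_base_profile(tiny_counts, tiny_records, 1, weighting="unique_pirna")
        assert prof.fractions.loc["s1", "U"] == pytest.approx(0.5)
        assert prof.fractions.loc["s1", "C"] == pytest.approx(0.5)

    def test_degenerate_composition(self):
        recs = [PiRNARecord(f"p{i}", "C" + "A" * 25) for i in range(3)]
        cm = CountMatrix(
            np.array([[7], [1], [4]]), [r.pirna_id for r in recs], ["s"]
        )
        prof = position_base_profile(cm, recs, 1)
        assert prof.fractions.loc["s", "C"] == pytest.approx(1.0)

    def test_fractions_sum_to_one_per_sample(self, tiny_counts, tiny_records):
        for pos in (1, 10):
            prof = position_base_profile(tiny_counts, tiny_records, pos)
            assert np.allclose(prof.fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_short_pirnas_reduce_coverage_not_zero_fraction(self):
        recs = [PiRNARecord("long", "A" * 30), PiRNARecord("short", "G" * 20)]
        cm = CountMatrix(np.array([[6], [2]]), ["long", "short"], ["s"])
        prof = position_base_profile(cm, recs, 25)
        assert prof.fractions.loc["s", "A"] == pytest.approx(1.0)
        assert prof.coverage.loc["s"] == pytest.approx(6 / 8)

    @pytest.mark.parametrize("pos", [0, -3])
    def test_position_must_be_positive(self, tiny_counts, tiny_records, pos):
        with pytest.raises(ValueError, match="position"):
            position_base_profile(tiny_counts, tiny_records, pos)

    def test_missing_sequence_lists_ids(self, tiny_counts, tiny_records):
        with pytest.raises(ValueError, match="pC"):
            position_base_profile(tiny_counts, tiny_records[:1], 1)


class TestLengthProfile:
    @pytest.mark.parametrize(
        "lengths,counts,expected",
        [
            ((31,), [[5]], {31: 1.0}),
            ((29, 31), [[4], [4]], {29: 0.5, 31: 0.5}),
            ((24, 30), [[1], [3]], {24: 0.25, 30: 0.75}),
        ],
    )
    def test_hand_tallies(self, lengths, counts, expected):
        recs = [PiRNARecord(f"p{i}", "A" * L) for i, L in enumerate(lengths)]
        cm = CountMatrix(np.array(counts), [r.pirna_id for r in recs], ["s"])
        prof = length_profile(cm, recs)
        for L, frac in expected.items():
            assert prof.fractions.loc["s", L] == pytest.approx(frac)
        assert prof.fractions.loc["s"].sum() == pytest.approx(1.0)


class TestChromosomeProfile:
    def test_hand_tally_and_multilocus_split(self):
        recs = [
            PiRNARecord("a", "A" * 28, loci=[GenomicLocus("chr6", 0, 28)]),
            PiRNARecord("b", "A" * 28, loci=[GenomicLocus("chr11", 0, 28)]),
            PiRNARecord("c", "A" * 28, loci=[GenomicLocus("chr1", 0, 28), GenomicLocus("chr2", 0, 28)]),
            PiRNARecord("d", "A" * 28),
        ]
        cm = CountMatrix(np.array([[10], [30], [8], [5]]), list("abcd"), ["s"])
        prof = chromosome_profile(cm, recs, {"s": 1.0})
        assert prof.loc["chr6", "s"] == pytest.approx(10)
        assert prof.loc["chr11", "s"] == pytest.approx(30)
        placed = prof.drop(index="unplaced")
        assert prof.loc["chr6", "s"] / placed["s"].sum() == pytest.approx(10 / 48)
        # 1/k split across 2 loci
        assert prof.loc["chr1", "s"] == pytest.approx(4)
        assert prof.loc["chr2", "s"] == pytest.approx(4)
        assert prof.loc["unplaced", "s"] == pytest.approx(5)

    def test_size_factor_normalization(self):
        recs = [PiRNARecord("a", "A" * 28, loci=[GenomicLocus("chr1", 0, 28)])]
        cm = CountMatrix(np.array([[10, 20]]), ["a"], ["s1", "s2"])
        prof = chromosome_profile(cm, recs, {"s1": 1.0, "s2": 2.0})
        assert prof.loc["chr1", "s1"] == prof.loc["chr1", "s2"] == pytest.approx(10.0)

    def test_rejects_nonpositive_size_factor(self):
        recs = [PiRNARecord("a", "A" * 28)]
        cm = CountMatrix(np.array([[1]]), ["a"], ["s"])
        with pytest.raises(ValueError, match="positive"):
            chromosome_profile(cm, recs, {"s": 0.0})


def exact_mw_p(a, b):
    """Independent oracle: two-sided p by full enumeration of labelings."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(b)
    dist = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        dist.append(u)
    dist = np.asarray(dist)
    d_obs = min(u_obs, n1n2 - u_obs)
    d = np.minimum(dist, n1n2 - dist)
    return (d <= d_obs + 1e-9).mean()


class TestMannWhitney:
    @pytest.mark.parametrize(
        "a,b,u,p,method",
        [
            ([1, 2], [1, 2], 2.0, 1.0, "normal_approx"),  # ties route to approx
            ([1, 2, 3], [4, 5, 6], 0.0, 0.1, "exact"),
            ([10], [1], 1.0, 1.0, "exact"),
        ],
    )
    def test_reference_cases(self, a, b, u, p, method):
        res = mann_whitney(a, b)
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p)
        assert res.method == method

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=5), rng.normal(size=4)
        r1, r2 = mann_whitney(a, b), mann_whitney(b, a)
        assert r1.statistic + r2.statistic == pytest.approx(len(a) * len(b))
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n1, n2 = rng.integers(1, 7), rng.integers(1, 7)
            a = rng.permutation(np.arange(1.0, 13.0))[:n1]
            b = rng.permutation(np.arange(20.0, 32.0))[:n2]
            vals = rng.permutation(np.concatenate([a, b]))
            a, b = vals[:n1], vals[n1:]
            res = mann_whitney(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_mw_p(a, b))

    def test_normal_approx_close_to_exact_at_6_plus_6(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vals = rng.permutation(np.arange(12.0))
            a, b = vals[:6], vals[6:]
            p_exact = exact_mw_p(a, b)
            p_approx = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            assert abs(p_approx - p_exact) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])


class TestCompositionPower:
    def test_case_control_c_bias_detected_with_power(self):
        """Elevated position-1 C in cases is detected per sample at alpha=0.05
        with power >= 0.8 over 200 replicates at the generator defaults."""
        cfg = SimConfig()
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            cohort = gen_base_bias_cohort(cfg, seed=1000 + rep)
            groups = cohort["group"].to_dict()
            res = compare_groups(cohort["p1_C"], groups)
            rejections += res.p_value < 0.05
        assert rejections / n_rep >= 0.8
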