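import numpy as np
import pytest

from pirnascope.characterization import position_base_profile
from pirnascope.io_core import CountMatrix
from pirnascope.synthetic_data import (
    SimConfig,
    gen_annotation_landscape,
    gen_base_bias_cohort,
    gen_clinical,
    gen_counts,
    gen_sequences,
    gen_target_fixtures,
    simulate_cohort,
)
from pirnascope.target_predict import scan_transcript


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pos1_control": (0.5, 0.5, 0.5, 0.5)},
            {"length_probs": (1.0,) * 11},
            {"n_up": 200, "n_down": 200},
            {"dispersion": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestGenCounts:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(n_pirnas=50)
        c1, m1, t1 = gen_counts(cfg, seed=9)
        c2, m2, t2 = gen_counts(cfg, seed=9)
        assert (c1.values == c2.values).all()
        assert t1.pirnas.equals(t2.pirnas)

    def test_zero_spike_has_no_de_truth(self):
        cfg = SimConfig(n_pirnas=40, n_up=0, n_down=0)
        _, _, truth = gen_counts(cfg, seed=0)
        assert not truth.pirnas.is_de.any()

    def test_cohort_shape_and_histology(self):
        counts, meta, _ = gen_counts(SimConfig(), seed=0)
        assert counts.shape == (307, 37)
        assert sum(m.group == "case" for m in meta) == 27
        assert sum(m.histology == "favorable" for m in meta) == 14
        assert sum(m.histology == "unfavorable" for m in meta) == 13

    def test_spiked_ratio_matches_lfc(self):
        """Empirical case/control mean ratio ~ 2^lfc over many genes.

        Library sizes are held constant so the spike is visible in raw
        counts rather than being absorbed into per-sample totals."""
        cfg = SimConfig(
            n_pirnas=500, n_up=500, n_down=0, lfc_up=2.0, dispersion=0.1,
            baseline_log_sd=0.0, library_size_range=(50_000, 50_000),
        )
        counts, meta, truth = gen_counts(cfg, seed=3)
        assert truth.pirnas.is_de.all()
        case = np.array([m.group == "case" for m in meta])
        raw = counts.values.astype(float)
        assert raw[:, case].mean() / raw[:, ~case].mean() == pytest.approx(4.0, rel=0.1)


class TestGenSequences:
    def test_point_mass_composition_and_length(self):
        cfg = SimConfig(
            pos1_control=(0.0, 1.0, 0.0, 0.0),
            length_probs=(0, 0, 0, 0, 0, 0, 0, 1.0, 0, 0, 0),
        )
        recs = gen_sequences(cfg, seed=0, ids=[f"p{i}" for i in range(100)])
        assert all(r.sequence[0] == "C" for r in recs)
        assert all(len(r) == 31 for r in recs)

    def test_pos1_frequency_tracks_probability(self):
        cfg = SimConfig(pos1_control=(0.2, 0.4, 0.2, 0.2))
        recs = gen_sequences(cfg, seed=1, ids=[f"p{i}" for i in range(2000)])
        freq_c = np.mean([r.sequence[0] == "C" for r in recs])
        assert freq_c == pytest.approx(0.4, abs=0.03)

    def test_group_vector_selection(self):
        cfg = SimConfig(pos1_case=(0.0, 1.0, 0.0, 0.0), pos1_control=(0.0, 0.0, 0.0, 1.0))
        case = gen_sequences(cfg, seed=2, ids=["a", "b"], group="case")
        ctrl = gen_sequences(cfg, seed=2, ids=["a", "b"], group="control")
        assert all(r.sequence[0] == "C" for r in case)
        assert all(r.sequence[0] == "U" for r in ctrl)

    def test_bias_cohort_matches_profile_computation(self):
        """The cohort helper's fractions equal position_base_profile on an
        equivalent uniformly-counted pool."""
        cfg = SimConfig(n_pirnas=300)
        recs = gen_sequences(cfg, seed=5, ids=[f"p{i}" for i in range(300)], group="case")
        cm = CountMatrix(
            np.ones((300, 1), dtype=int), [r.pirna_id for r in recs], ["s"]
        )
        prof = position_base_profile(cm, recs, 1)
        direct = {b: np.mean([r.sequence[0] == b for r in recs]) for b in "ACGU"}
        for b in "ACGU":
            assert prof.fractions.loc["s", b] == pytest.approx(direct[b])

    def test_bias_cohort_frame_shape(self):
        cohort = gen_base_bias_cohort(SimConfig(n_pirnas=50), seed=0)
        assert len(cohort) == 37
        assert np.allclose(cohort[[f"p1_{b}" for b in "ACGU"]].sum(axis=1), 1.0)


class TestAnnotationLandscape:
    def test_annotations_disjoint_and_loci_contained(self):
        cfg = SimConfig(n_pirnas=150)
        recs = gen_sequences(cfg, seed=6, ids=[f"p{i}" for i in range(150)])
        anns, recs, truth = gen_annotation_landscape(cfg, recs, seed=6)
        by_chrom: dict = {}
        for iv in anns:
            by_chrom.setdefault((iv.chrom,), []).append((iv.start, iv.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
        klass = dict(zip(truth.pirnas.pirna_id, truth.pirnas.klass))
        ann_lookup = {(iv.chrom, iv.start, iv.end): iv for iv in anns}
        for rec in recs:
            (locus,) = rec.loci
            if klass[rec.pirna_id] == "intergenic":
                assert not any(
                    iv.chrom == locus.chrom and iv.start < locus.end and locus.start < iv.end
                    for iv in anns
                )
            else:
                host = [
                    iv
                    for iv in anns
                    if iv.chrom == locus.chrom and iv.start <= locus.start and locus.end <= iv.end
                ]
                assert len(host) == 1 and host[0].klass == klass[rec.pirna_id]
                assert host[0].strand == locus.strand

    def test_read_fraction_targets_hit(self):
        cfg = SimConfig()
        counts, _, _ = gen_counts(cfg, seed=7)
        recs = gen_sequences(cfg, seed=7, ids=counts.pirna_ids)
        shares = counts.values.sum(axis=1).astype(float)
        anns, recs, truth = gen_annotation_landscape(cfg, recs, shares, seed=7)
        klass = dict(zip(truth.pirnas.pirna_id, truth.pirnas.klass))
        repeat = {"LINE", "SINE", "LTR", "DNA_repeat", "simple_repeat"}
        rep_share = sum(
            shares[i] for i, p in enumerate(counts.pirna_ids) if klass[p] in repeat
        ) / shares.sum()
        assert rep_share == pytest.approx(0.04, abs=0.01)

    def test_genome_too_small_errors(self):
        cfg = SimConfig(n_pirnas=100, genome_length=500)
        recs = gen_sequences(cfg, seed=8, ids=[f"p{i}" for i in range(100)])
        with pytest.raises(ValueError, match="too small"):
            gen_annotation_landscape(cfg, recs, seed=8)


class TestTargetFixtures:
    def test_fixture_verdicts_by_construction(self, rna_factory):
        rng = np.random.default_rng(10)
        cfg = SimConfig(length_probs=(0, 0, 0, 0, 0, 0, 0, 1.0, 0, 0, 0))  # all 31 nt
        recs = gen_sequences(cfg, seed=10, ids=[f"p{i}" for i in range(6)])
        txs, truth = gen_target_fixtures(recs, seed=10)
        assert len(txs) == 24
        tx_by_id = dict(txs)
        by_id = {r.pirna_id: r for r in recs}
        for _, row in truth.transcripts.iterrows():
            rec = by_id[row.pirna_id]
            hit = scan_transcript(
                rec.sequence, row.transcript_id, tx_by_id[row.transcript_id], pirna_id=rec.pirna_id
            )
            assert hit.passes_filters == row.expected_pass, row.transcript_id
            assert hit.primary_run == row.expected_primary_run, row.transcript_id
            assert hit.secondary_run == row.expected_secondary_run, row.transcript_id
        kinds = truth.transcripts.groupby("kind").expected_pass.agg("any")
        assert kinds["perfect"] and not kinds[["primary_broken", "secondary_broken", "wobble_seed"]].any()


class TestClinical:
    def _setup(self, cfg, seed):
        counts, meta, truth = gen_counts(cfg, seed=seed)
        return counts, *gen_clinical(cfg, counts, meta, truth, seed=seed)

    def test_null_slope_gives_weak_correlation(self):
        from pirnascope.biomarker_stats import spearman

        cfg = SimConfig(n_pirnas=60, n_up=3, n_down=5,
                        covariate_links={"metastasis": (0, 0.0)})
        weak = 0
        n_rep = 30
        for seed in range(n_rep):
            counts, meta, truth = self._setup(cfg, seed)
            pid = truth.covariates.iloc[0].pirna_id
            i = counts.pirna_ids.index(pid)
            lib = counts.values.sum(axis=0)
            cases = [m for m in meta if m.group == "case"]
            x = [counts.values[i, counts.sample_ids.index(m.sample_id)] / lib[counts.sample_ids.index(m.sample_id)] for m in cases]
            y = [m.covariates["metastasis"] for m in cases]
            if len(set(y)) == 1:
                weak += 1
                continue
            weak += abs(spearman(x, y).r) < 0.4
        assert weak / n_rep >= 0.9

    def test_controls_carry_no_tumor_covariates(self):
        cfg = SimConfig(n_pirnas=60, n_up=3, n_down=5)
        _, meta, _ = self._setup(cfg, 0)
        for m in meta:
            if m.group == "control":
                assert "metastasis" not in m.covariates


class TestFullCohort:
    def test_simulate_cohort_is_deterministic(self):
        s1 = simulate_cohort(seed=12, n_target_pirnas=3)
        s2 = simulate_cohort(seed=12, n_target_pirnas=3)
        assert (s1.counts.values == s2.counts.values).all()
        assert [r.sequence for r in s1.records] == [r.sequence for r in s2.records]
        assert s1.transcripts == s2.transcripts
        assert s1.truth.pirnas.equals(s2.truth.pirnas)

    def test_truth_merges_all_generators(self):
        sim = simulate_cohort(seed=13, n_target_pirnas=2)
        assert {"is_de", "true_lfc", "klass", "is_biomarker"} <= set(sim.truth.pirnas.columns)
        assert sim.truth.transcripts is not None
        assert sim.truth.covariates is not None
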