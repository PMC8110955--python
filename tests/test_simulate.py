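"""Synthetic genomes, count tables, SAM read sets and motif collections."""

import numpy as np
import pysam
import pytest

from ppredit import (
    SyntheticTruth,
    add_editing_site,
    build_consensus,
    count_bases,
    scan_sequence,
    simulate_counts,
    simulate_genome,
    simulate_motif_collection,
    simulate_sam,
)


class TestSimulateGenome:
    def test_length_and_empty_truth(self):
        truth = simulate_genome(1000, seed=1)
        [seq] = truth.sequences.values()
        assert len(seq) == 1000
        assert truth.planted_binding_sites == []
        assert truth.planted_editing_sites == []

    def test_same_seed_identical(self):
        assert simulate_genome(500, seed=3).sequences == simulate_genome(500, seed=3).sequences

    def test_different_seed_differs(self):
        assert simulate_genome(500, seed=3).sequences != simulate_genome(500, seed=4).sequences

    def test_gc_fraction_respected(self):
        truth = simulate_genome(20000, gc_fraction=0.3, seed=5)
        [seq] = truth.sequences.values()
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.3, abs=0.02)

    def test_planted_target_recovered_by_scan(self, designed_factor, code_table, match_table):
        truth = simulate_genome(
            2000, seed=6, plant_factor=designed_factor, code=code_table,
            scoring_table=match_table,
        )
        [binding] = truth.planted_binding_sites
        [editing] = truth.planted_editing_sites
        top = scan_sequence(designed_factor, truth.sequences, match_table)[0]
        assert top.window_start == binding.window_start
        assert top.edit_position == editing.position
        # the planted coordinate carries a reference-sense C
        assert truth.sequences[editing.sequence_name][editing.position] == "C"

    def test_plant_collision_with_end_errors(self, designed_factor, code_table, match_table):
        with pytest.raises(ValueError, match="collides"):
            simulate_genome(
                100, seed=7, plant_factor=designed_factor, code=code_table,
                scoring_table=match_table, plant_position=95,
            )

    def test_add_editing_site_requires_transcript_sense_c(self):
        truth = simulate_genome(100, seed=8)
        name = next(iter(truth.sequences))
        pos_a = truth.sequences[name].index("A")
        with pytest.raises(ValueError, match="not a transcript-sense C"):
            add_editing_site(truth, name, pos_a, "+", 0.4)


class TestSimulateCounts:
    def test_no_editing_no_error_means_no_t_at_c(self):
        truth = simulate_genome(300, seed=10, mean_depth=50, error_rate=0.0)
        table = simulate_counts(truth, "treatment")
        name = next(iter(truth.sequences))
        seq = truth.sequences[name]
        c_pos = [i for i, b in enumerate(seq) if b == "C"]
        assert table.counts[name]["+"][c_pos, 3].sum() == 0  # no T at any C

    def test_full_efficiency_converts_all_coverage(self):
        truth = simulate_genome(300, seed=11, mean_depth=80, error_rate=0.0)
        name = next(iter(truth.sequences))
        pos = truth.sequences[name].index("C", 50)
        add_editing_site(truth, name, pos, "+", efficiency_treat=1.0)
        table = simulate_counts(truth, "treatment")
        counts = table.counts[name]["+"][pos]
        assert counts[3] == counts.sum()  # everything is T

    def test_control_uses_control_efficiency(self):
        truth = simulate_genome(300, seed=12, mean_depth=100, error_rate=0.0)
        name = next(iter(truth.sequences))
        pos = truth.sequences[name].index("C", 50)
        add_editing_site(truth, name, pos, "+", efficiency_treat=0.5, efficiency_ctrl=0.0)
        ctrl = simulate_counts(truth, "control")
        assert ctrl.counts[name]["+"][pos, 3] == 0

    def test_editing_fraction_unbiased(self):
        """Mean edited fraction over 50 seeded replicates within 3 SE of 0.4."""
        fractions = []
        for seed in range(50):
            truth = simulate_genome(60, seed=seed, mean_depth=500, error_rate=0.0)
            name = next(iter(truth.sequences))
            try:
                pos = truth.sequences[name].index("C")
            except ValueError:
                continue
            add_editing_site(truth, name, pos, "+", efficiency_treat=0.4)
            counts = simulate_counts(truth, "treatment").counts[name]["+"][pos]
            fractions.append(counts[3] / (counts[1] + counts[3]))
        se = np.sqrt(0.4 * 0.6 / (500 * len(fractions)))
        assert np.mean(fractions) == pytest.approx(0.4, abs=3 * se)

    def test_minus_one_purine_penalty_scales_efficiency(self):
        # build a genome, find a C whose -1 base is a purine, halve efficiency
        truth = simulate_genome(500, seed=13, mean_depth=2000, error_rate=0.0,
                                minus_one_purine_penalty=0.5)
        name = next(iter(truth.sequences))
        seq = truth.sequences[name]
        pos = next(i for i in range(1, len(seq)) if seq[i] == "C" and seq[i - 1] in "AG")
        add_editing_site(truth, name, pos, "+", efficiency_treat=0.8)
        counts = simulate_counts(truth, "treatment").counts[name]["+"][pos]
        frac = counts[3] / (counts[1] + counts[3])
        assert frac == pytest.approx(0.4, abs=0.05)

    def test_deterministic_given_truth(self):
        truth = simulate_genome(200, seed=14, mean_depth=100)
        a = simulate_counts(truth, "treatment")
        b = simulate_counts(truth, "treatment")
        name = next(iter(truth.sequences))
        for strand in "+-":
            np.testing.assert_array_equal(a.counts[name][strand], b.counts[name][strand])

    def test_invalid_role(self):
        truth = simulate_genome(50, seed=15)
        with pytest.raises(ValueError, match="sample_role"):
            simulate_counts(truth, "case")


class TestSimulateSam:
    def test_zero_reads_valid_empty_sam(self, tmp_path):
        truth = simulate_genome(200, seed=16)
        path = tmp_path / "empty.sam"
        simulate_sam(truth, path, n_reads=0, read_length=50)
        with pysam.AlignmentFile(str(path)) as handle:
            assert list(handle) == []
            assert handle.references == tuple(truth.sequences)

    def test_fixed_seed_byte_identical(self, tmp_path):
        truth = simulate_genome(300, seed=17)
        a, b = tmp_path / "a.sam", tmp_path / "b.sam"
        simulate_sam(truth, a, n_reads=100, read_length=60)
        simulate_sam(truth, b, n_reads=100, read_length=60)
        assert a.read_bytes() == b.read_bytes()

    def test_counts_roundtrip_matches_truth_fractions(self, tmp_path):
        truth = simulate_genome(400, seed=18, error_rate=0.0)
        name = next(iter(truth.sequences))
        pos = truth.sequences[name].index("C", 150)
        add_editing_site(truth, name, pos, "+", efficiency_treat=0.5)
        path = tmp_path / "reads.sam"
        simulate_sam(truth, path, n_reads=6000, read_length=80)
        table = count_bases(path)
        counts = table.counts[name]["+"][pos]
        frac = counts[3] / (counts[1] + counts[3])
        n = counts[1] + counts[3]
        assert n > 200
        assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))

    def test_read_length_longer_than_reference_errors(self, tmp_path):
        truth = simulate_genome(50, seed=19)
        with pytest.raises(ValueError, match="read_length"):
            simulate_sam(truth, tmp_path / "x.sam", n_reads=1, read_length=100)


class TestSimulateMotifCollection:
    def test_zero_divergence_identity(self):
        seqs = simulate_motif_collection(10, "VVTYNTLIDGL", divergence=0.0, seed=20)
        assert set(seqs) == {"VVTYNTLIDGL"}

    def test_consensus_recovery_at_20_percent(self):
        consensus = "VVTYNTLIDGLCKAGKVDEALELFEEMKEKGIKPD"
        seqs = simulate_motif_collection(200, consensus, divergence=0.2, seed=21)
        assert build_consensus(seqs) == consensus

    def test_same_seed_identical(self):
        a = simulate_motif_collection(20, "ACDEF", divergence=0.3, seed=22)
        b = simulate_motif_collection(20, "ACDEF", divergence=0.3, seed=22)
        assert a == b

    def test_fasta_output_parses_as_collection(self, tmp_path):
        from ppredit import read_motif_collection
        from ppredit.motifs import MotifType

        path = tmp_path / "motifs.fasta"
        simulate_motif_collection(5, "ACDEF", divergence=0.1, seed=23,
                                  motif_type="L1", triplet_index=2, path=path)
        groups = read_motif_collection(path)
        assert list(groups) == [(MotifType.L1, 2)]
        assert len(groups[(MotifType.L1, 2)]) == 5

    def test_divergence_range_checked(self):
        with pytest.raises(ValueError, match="divergence"):
            simulate_motif_collection(5, "ACD", divergence=0.6, seed=24)


class TestTruthSerialisation:
    def test_json_roundtrip_and_regeneration(self, tmp_path):
        truth = simulate_genome(200, seed=25, mean_depth=60)
        name = next(iter(truth.sequences))
        pos = truth.sequences[name].index("C")
        add_editing_site(truth, name, pos, "+", 0.3)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back == truth
        a = simulate_counts(truth, "treatment")
        b = simulate_counts(back, "treatment")
        for strand in "+-":
            np.testing.assert_array_equal(a.counts[name][strand], b.counts[name][strand])
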