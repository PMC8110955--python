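"""Alignment scoring, genome scanning and site scoring."""

import numpy as np
import pytest

from ppredit import (
    MotifType,
    ScoringTable,
    parse_factor,
    scan_sequence,
    score_alignment,
    score_site_table,
)
from ppredit.scoring import edit_offset_in_window, reverse_complement, window_span

from conftest import PAIR_FOR_BASE, TARGET


@pytest.fixture(scope="module")
def one_p1():
    return parse_factor("P1 T D")


def random_genome(rng, length, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


class TestScoreAlignment:
    def test_constant_table_gives_default_everywhere(self, designed_factor):
        table = ScoringTable({}, default_score=-0.25)
        aln = score_alignment(designed_factor, TARGET, table)
        assert aln.per_motif_scores == (-0.25,) * 12
        assert aln.total_score == 12 * -0.25

    def test_single_motif_lookup(self, one_p1):
        table = ScoringTable({("T", "D", "G"): 1.0})
        assert score_alignment(one_p1, "G", table).total_score == 1.0
        assert score_alignment(one_p1, "A", table).total_score == 0.0

    def test_total_matches_bruteforce_lookup(self, designed_factor):
        rng = np.random.default_rng(3)
        pairs = {m for m in zip(
            [m.fifth for m in designed_factor.contacting_motifs],
            [m.last for m in designed_factor.contacting_motifs],
        )}
        entries = {
            (f, l, b): float(rng.normal()) for f, l in pairs for b in "ACGU"
        }
        table = ScoringTable(entries)
        window = "".join(rng.choice(list("ACGU"), size=12))
        aln = score_alignment(designed_factor, window, table)
        expected = [
            entries[(m.fifth, m.last, b)]
            for m, b in zip(designed_factor.contacting_motifs, window)
        ]
        assert list(aln.per_motif_scores) == expected
        assert aln.total_score == sum(expected)  # exact sum, no re-rounding

    def test_window_length_mismatch(self, designed_factor, match_table):
        with pytest.raises(ValueError, match="window length"):
            score_alignment(designed_factor, "GAU", match_table)

    def test_invalid_base(self, one_p1, match_table):
        with pytest.raises(ValueError, match="invalid base"):
            score_alignment(one_p1, "X", match_table)

    def test_t_accepted_as_u(self, one_p1):
        table = ScoringTable({("T", "D", "U"): 2.0})
        assert score_alignment(one_p1, "T", table).total_score == 2.0

    def test_edit_position_is_s2_plus_4(self, designed_factor, one_p1):
        # S2 is the 12th contacting motif (index 11) of the canonical factor
        assert edit_offset_in_window(designed_factor) == 11 + 4
        # factors without S2 fall back to the last contacting motif
        assert edit_offset_in_window(one_p1) == 0 + 4


class TestScanSequence:
    def test_planted_target_is_rank_one(self, designed_factor, match_table):
        rng = np.random.default_rng(5)
        genome = list(random_genome(rng, 1000))
        insert = (TARGET.replace("U", "T") + "TTTC")
        genome[200 : 200 + len(insert)] = insert
        hits = scan_sequence(
            designed_factor, {"chr": "".join(genome)}, match_table, anchor="edited_C_only"
        )
        assert hits[0].window_start == 200
        assert hits[0].strand == "+"
        assert hits[0].edit_position == 200 + 15
        assert hits[0].total_score == 12.0

    def test_record_count_all_positions(self, designed_factor, match_table):
        rng = np.random.default_rng(6)
        L = 1000
        genome = {"chr": random_genome(rng, L)}
        hits = scan_sequence(
            designed_factor, genome, match_table, anchor="all_positions"
        )
        span = window_span(designed_factor)
        assert len(hits) == 2 * (L - span + 1)

    def test_strand_symmetry(self, designed_factor, match_table):
        rng = np.random.default_rng(8)
        seq = random_genome(rng, 60)
        fwd = scan_sequence(
            designed_factor, {"s": seq}, match_table, strands="forward",
            anchor="all_positions",
        )
        rev = scan_sequence(
            designed_factor, {"s": reverse_complement(seq).replace("U", "T")},
            match_table, strands="reverse", anchor="all_positions",
        )
        assert sorted(h.total_score for h in fwd) == sorted(h.total_score for h in rev)

    def test_deterministic_and_sorted(self, designed_factor, match_table):
        rng = np.random.default_rng(9)
        genome = {"chr": random_genome(rng, 500)}
        first = scan_sequence(designed_factor, genome, match_table, anchor="all_positions")
        second = scan_sequence(designed_factor, genome, match_table, anchor="all_positions")
        assert first == second
        scores = [h.total_score for h in first]
        assert scores == sorted(scores, reverse=True)

    def test_empty_genome_gives_empty_list(self, designed_factor, match_table):
        assert scan_sequence(designed_factor, {}, match_table) == []
        assert scan_sequence(designed_factor, {"short": "ACGT"}, match_table) == []

    def test_unknown_strand_selector(self, designed_factor, match_table):
        with pytest.raises(ValueError, match="strand selector"):
            scan_sequence(designed_factor, {"s": "ACGT" * 20}, match_table, strands="up")

    def test_minus_strand_edited_c_is_forward_g(self, designed_factor, match_table):
        """A plus-strand G can be a minus-strand edited C."""
        rng = np.random.default_rng(10)
        window = TARGET.replace("U", "T") + "TTTC"
        seq = random_genome(rng, 300)
        planted = seq[:100] + reverse_complement(window).replace("U", "T") + seq[100:]
        hits = scan_sequence(
            designed_factor, {"chr": planted}, match_table, anchor="edited_C_only"
        )
        top = hits[0]
        assert top.strand == "-"
        assert top.total_score == 12.0
        assert planted[top.edit_position] == "G"  # reference sense

    def test_circular_wraps_origin(self, designed_factor, match_table):
        rng = np.random.default_rng(12)
        window = TARGET.replace("U", "T") + "TTTC"
        seq = random_genome(rng, 200)
        # place the window across the linear end: last 6 bases + first 10
        seq = window[6:] + seq[len(window) - 6 : 200 - 6] + window[:6]
        linear = scan_sequence(
            designed_factor, {"c": seq}, match_table, anchor="edited_C_only"
        )
        circular = scan_sequence(
            designed_factor, {"c": seq}, match_table, anchor="edited_C_only",
            circular=True,
        )
        assert all(h.total_score < 12.0 for h in linear)
        top = circular[0]
        assert top.total_score == 12.0
        assert top.window_start == 194
        assert top.edit_position == (194 + 15) % 200


class TestScoreSiteTable:
    def test_design_target_scores_matched_entries(self, designed_factor, match_table):
        window = TARGET.replace("U", "T") + "TTTC"
        genome = {"g": "AAAA" + window + "AAAA"}
        edit_pos = 4 + 15
        [aln] = score_site_table(designed_factor, [("g", edit_pos, "+")], genome, match_table)
        assert aln.per_motif_scores == (1.0,) * 12
        assert aln.edit_position == edit_pos

    def test_empty_site_list(self, designed_factor, match_table):
        assert score_site_table(designed_factor, [], {}, match_table) == []

    def test_overrun_flagged_not_scored(self, designed_factor, match_table):
        genome = {"g": "C" * 50}
        [res] = score_site_table(designed_factor, [("g", 3, "+")], genome, match_table)
        assert res is None

    def test_consistent_with_scan(self, designed_factor, match_table):
        rng = np.random.default_rng(13)
        genome = {"g": random_genome(rng, 400)}
        hits = scan_sequence(
            designed_factor, genome, match_table, anchor="all_positions"
        )
        sample = [hits[0], hits[len(hits) // 2], hits[-1]]
        sites = [(h.sequence_name, h.edit_position, h.strand) for h in sample]
        rescored = score_site_table(designed_factor, sites, genome, match_table)
        for h, r in zip(sample, rescored):
            assert r is not None and r.total_score == h.total_score


class TestScoringTableIO:
    def test_file_roundtrip_lossless(self, tmp_path):
        rng = np.random.default_rng(14)
        entries = {
            (f, l, b): float(rng.normal())
            for f, l in [("T", "D"), ("N", "S"), ("S", "N")]
            for b in "ACGU"
        }
        table = ScoringTable(entries, default_score=0.0)
        path = tmp_path / "table.tsv"
        table.write(path)
        back = ScoringTable.read(path)
        assert back.entries == table.entries

    def test_unseen_pair_scores_default(self):
        table = ScoringTable({("T", "D", "G"): 1.0}, default_score=0.125)
        assert table.score("Q", "Q", "A") == 0.125

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            ScoringTable({("T", "D", "G"): float("nan")})
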