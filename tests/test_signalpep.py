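"""Vote combination, n/h/c parsing, segmental alignments, surrogate scanners."""

import numpy as np
import pandas as pd
import pytest

from orgproteome.signalpep import (
    ANCHORS,
    NoHRegionError,
    SignalPeptideAnnotation,
    consensus_cleavage,
    h_region_phe_count,
    join_alignments,
    majority_vote,
    parse_regions,
    position_frequency_matrix,
    segmental_align,
    tat_scan,
    tmh_scan,
)
from orgproteome.simulate import GeneratorConfig, generate_training_sets


def vote_frame(rows):
    return pd.DataFrame(rows, columns=["protein_id", "predictor", "call", "cleavage_pos"])


def n_of_m_votes(pid, n_pos, m, pos=20):
    return [
        (pid, f"pred{i}", 1 if i < n_pos else 0, pos if i < n_pos else "")
        for i in range(m)
    ]


class TestMajorityVote:
    @pytest.mark.parametrize("n_pos,m,expected", [
        (8, 15, True),   # strict majority of 15
        (7, 15, False),  # just below
        (2, 4, False),   # even count, tie -> negative
        (3, 4, True),
        (0, 15, False),
    ])
    def test_threshold(self, n_pos, m, expected):
        table = vote_frame(n_of_m_votes("p1", n_pos, m))
        assert majority_vote(table, m)["p1"] is expected

    def test_missing_rows_count_negative(self):
        table = vote_frame(n_of_m_votes("p1", 7, 7))  # 7 of 15 reported, all positive
        assert majority_vote(table, 15)["p1"] is False

    def test_monotone_in_positive_votes(self):
        for m in (4, 15):
            decisions = [
                majority_vote(vote_frame(n_of_m_votes("p", k, m)), m)["p"]
                for k in range(m + 1)
            ]
            # once positive, adding positive votes never flips the call back
            assert decisions == sorted(decisions)

    def test_duplicate_predictor_rejected(self):
        table = vote_frame([("p", "x", 1, 20), ("p", "x", 1, 21)])
        with pytest.raises(ValueError, match="duplicate"):
            majority_vote(table, 15)

    def test_consensus_cleavage_is_floored_median(self):
        table = vote_frame([("p", "a", 1, 20), ("p", "b", 1, 23), ("p", "c", 1, 27),
                            ("p", "d", 0, ""), ("p", "e", 1, 24)])
        # positives report 20, 23, 27, 24 -> median 23.5 -> floor 23
        assert consensus_cleavage(table)["p"] == 23


class TestParseRegions:
    def test_worked_example(self):
        seq = "M" + "KK" + "L" * 10 + "SVAQA" + "G" * 20
        ann = parse_regions(seq, 18)
        assert (ann.n, ann.h, ann.c) == ((1, 4), (4, 14), (14, 19))
        assert ann.n_region == "MKK"
        assert ann.h_region == "L" * 10
        assert ann.c_region == "SVAQA"

    def test_hydrophilic_peptide_has_no_h_region(self):
        with pytest.raises(NoHRegionError):
            parse_regions("D" * 40, 15)

    def test_idempotent_and_partitioning(self):
        A, P = generate_training_sets(GeneratorConfig(seed=4, n_A=10, n_P=10))
        for rec in A + P:
            ann = parse_regions(rec.sequence, rec.sp_truth)
            ann2 = parse_regions(rec.sequence, rec.sp_truth)
            assert (ann.n, ann.h, ann.c) == (ann2.n, ann2.h, ann2.c)
            # contiguous partition of 1..k
            assert ann.n[0] == 1 and ann.n[1] == ann.h[0]
            assert ann.h[1] == ann.c[0] and ann.c[1] == rec.sp_truth + 1
            assert ann.h[1] > ann.h[0]  # h nonempty

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            parse_regions("MKKLLLLLLA", 3)
        with pytest.raises(ValueError):
            parse_regions("A" * 120, 60)


@pytest.fixture(scope="module")
def annotations():
    A, P = generate_training_sets(GeneratorConfig(seed=6, n_A=8, n_P=8))
    return [parse_regions(r.sequence, r.sp_truth) for r in A + P]


class TestSegmentalAlignment:
    def test_cleavage_anchor_has_axa_columns(self, annotations):
        aln = segmental_align(annotations[:3], "cleavage_site")
        i1 = aln.col_coords.index(-1)
        i3 = aln.col_coords.index(-3)
        for row in aln.rows:
            assert row[i1] == "A" and row[i3] == "A"

    def test_single_sequence_alignment_is_the_segment(self, annotations):
        ann = annotations[0]
        aln = segmental_align([ann], "h_start")
        assert len(aln.rows) == 1
        assert aln.rows[0].strip("-") in ann.h_region

    def test_roundtrip_reconstructs_signal_peptides(self, annotations):
        alns = [segmental_align(annotations, a) for a in ANCHORS]
        assert join_alignments(alns) == [a.signal_peptide for a in annotations]

    def test_unknown_anchor(self, annotations):
        with pytest.raises(ValueError):
            segmental_align(annotations, "middle")


class TestPFM:
    def test_hand_counts(self):
        aln = segmental_align(
            [
                SignalPeptideAnnotation("MKALLLLLLAGA", 12, (1, 2), (2, 9), (9, 13)),
            ],
            "n_terminus",
        )
        pfm = position_frequency_matrix(aln)
        assert pfm.loc["M", 0] == 1.0

    def test_gap_excluded_column(self):
        from orgproteome.signalpep import SegmentalAlignment

        aln = SegmentalAlignment("n_terminus", ["A", "A", "G", "-"], [0])
        pfm = position_frequency_matrix(aln)
        assert pfm.loc["A", 0] == pytest.approx(2 / 3)
        assert pfm.loc["G", 0] == pytest.approx(1 / 3)

    def test_columns_are_probability_vectors(self, annotations):
        for anchor in ANCHORS:
            pfm = position_frequency_matrix(segmental_align(annotations, anchor))
            sums = pfm.sum(axis=0).to_numpy()
            assert np.all((np.isclose(sums, 1.0)) | (sums == 0.0))

    def test_canonical_set_cleavage_consensus(self, annotations):
        pfm = position_frequency_matrix(segmental_align(annotations, "cleavage_site"))
        assert pfm[-1].idxmax() == "A" and pfm[-3].idxmax() == "A"


def test_h_region_phe_mean():
    mk = lambda h: SignalPeptideAnnotation("MK" + h + "SAA", 5 + len(h),
                                           (1, 3), (3, 3 + len(h)), (3 + len(h), 6 + len(h)))
    assert h_region_phe_count([mk("FFFLLL")]) == 3.0
    assert h_region_phe_count([mk("LLLLLL")]) == 0.0
    assert h_region_phe_count([mk("FLLLLL"), mk("FFFLLL")]) == 2.0


class TestSurrogateScanners:
    def test_tat_positive_example(self):
        assert tat_scan("MSRRQFLKGLLLLLLLLLAGDDDDDDDD") is True

    def test_tat_negative_without_rr(self):
        assert tat_scan("MAKLLLLLLLLLLLLDDDD") is False

    def test_tat_rr_outside_window(self):
        seq = "M" + "G" * 58 + "SRRQ" + "L" * 15
        assert tat_scan(seq) is False

    def test_tmh_homopolymer(self):
        assert tmh_scan("L" * 20) == [(1, 20)]

    def test_tmh_hydrophilic_empty(self):
        assert tmh_scan("K" * 40) == []

    def test_tmh_two_helices(self):
        seq = "KKKK" + "I" * 19 + "DDDD" + "I" * 19 + "KKKK"
        assert len(tmh_scan(seq)) == 2

    def test_tmh_short_sequence(self):
        assert tmh_scan("LLLL") == []
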