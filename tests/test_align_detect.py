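"""Built-in aligner and fusion-candidate detection rules."""
import io
import random

import numpy as np
import pytest

from fusionevo.align import (ProteinAlignment, align_proteomes, evalue,
                             local_align, read_tabular_alignments,
                             write_tabular_alignments)
from fusionevo.detect import (CandidateStatus, DetectionThresholds,
                              detect_fusion_candidates, filter_alignments,
                              merge_regions)

SPECIES = "TestSpecies"
TH = DetectionThresholds(min_identity_by_species={SPECIES: 50.0})


def mk_alignment(query_gene, subject, s_start, s_end, *, query_protein=None,
                 align_len=None, pct=90.0, ev=1e-6):
    return ProteinAlignment(
        query_protein or f"{query_gene}.1", query_gene, subject, SPECIES,
        1, s_end - s_start + 1, s_start, s_end,
        align_len or (s_end - s_start + 1), pct, ev, 100.0)


# ---------------------------------------------------------------------
# Smith-Waterman reference oracle (plain quadratic DP, affine gaps)
# ---------------------------------------------------------------------

def sw_reference_score(q, s, mat, gap_open=11, gap_extend=1):
    """Gotoh local-alignment best score; independent of the library path."""
    n, m = len(q), len(s)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            sub = H[i - 1][j - 1] + mat[q[i - 1], s[j - 1]]
            H[i][j] = max(0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlign:
    def test_self_alignment(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQA"[:30]
        a = local_align(seq, seq)
        assert a.align_len == 30
        assert a.pct_identity == 100.0
        assert a.q_start == a.s_start == 1
        assert a.q_end == a.s_end == 30

    def test_embedded_match_coordinates(self):
        a = local_align("ACDEFGHIKL", "WWACDEFGHIKLWW")
        assert (a.s_start, a.s_end) == (3, 12)
        assert (a.q_start, a.q_end) == (1, 10)
        assert a.pct_identity == 100.0

    def test_score_matches_reference_dp(self):
        from fusionevo.align import _blosum62_x0
        mat = _blosum62_x0()
        rng = random.Random(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(15):
            q = "".join(rng.choices(aas, k=rng.randint(10, 40)))
            s = "".join(rng.choices(aas, k=rng.randint(10, 40)))
            a = local_align(q, s)
            expected = sw_reference_score(q, s, mat)
            got = a.score if a is not None else 0
            assert got == pytest.approx(expected)

    def test_unrelated_sequences_insignificant(self):
        rng = random.Random(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        q = "".join(rng.choices(aas, k=50))
        s = "".join(rng.choices(aas, k=50))
        a = local_align(q, s)
        assert a is None or a.e_value > 0.1

    def test_x_scores_zero(self):
        # an X-only sequence can never produce a positive local score
        assert local_align("XXXXXXXXXX", "ACDEFGHIKL") is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACDEFG")

    def test_evalue_decreases_with_score(self):
        assert evalue(100, 200, 300) < evalue(50, 200, 300)


def test_prefiltered_batch_matches_direct_alignment():
    rng = random.Random(9)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    core = "".join(rng.choices(aas, k=60))
    queries = {"q1.1": core, "q2.1": "".join(rng.choices(aas, k=60))}
    subjects = {"s1": "AAA" + core + "WWW",
                "s2": "".join(rng.choices(aas, k=80))}
    hits = align_proteomes(queries, subjects, {"q1.1": "q1", "q2.1": "q2"},
                           SPECIES, max_evalue=0.1)
    keys = {(h.query_protein, h.subject_protein) for h in hits}
    assert ("q1.1", "s1") in keys
    hit = next(h for h in hits if (h.query_protein, h.subject_protein)
               == ("q1.1", "s1"))
    assert hit.e_value <= 0.1
    direct = local_align(core, subjects["s1"])
    assert hit.score == direct.score


# ---------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------

class TestFilterAlignments:
    def test_length_threshold_inclusive_at_20(self):
        short = mk_alignment("g1", "s", 1, 19)
        exact = mk_alignment("g1", "s", 1, 20)
        assert filter_alignments([short], TH) == []
        assert filter_alignments([exact], TH) == [exact]

    def test_evalue_threshold_inclusive(self):
        at = mk_alignment("g1", "s", 1, 30, ev=0.1)
        above = mk_alignment("g1", "s", 1, 30, ev=0.10001)
        assert filter_alignments([at], TH) == [at]
        assert filter_alignments([above], TH) == []

    def test_identity_threshold_strict(self):
        at = mk_alignment("g1", "s", 1, 30, pct=50.0)
        above = mk_alignment("g1", "s", 1, 30, pct=50.01)
        assert filter_alignments([at], TH) == []
        assert filter_alignments([above], TH) == [above]

    def test_missing_species_threshold_is_an_error(self):
        a = mk_alignment("g1", "s", 1, 30)
        with pytest.raises(KeyError, match="TestSpecies"):
            filter_alignments([a], DetectionThresholds())

    def test_drop_counts_per_criterion(self):
        from collections import Counter
        als = [mk_alignment("g1", "s", 1, 10),
               mk_alignment("g1", "s", 1, 30, ev=5.0),
               mk_alignment("g1", "s", 1, 30, pct=10.0),
               mk_alignment("g1", "s", 1, 30)]
        drops = Counter()
        kept = filter_alignments(als, TH, drops)
        assert len(kept) == 1
        assert drops == Counter(align_len=1, evalue=1, identity=1)


# ---------------------------------------------------------------------
# region merging
# ---------------------------------------------------------------------

class TestMergeRegions:
    def test_overlapping_intervals_union(self):
        r = merge_regions([mk_alignment("g", "s", 10, 60),
                           mk_alignment("g", "s", 50, 120)])
        assert r.intervals == ((10, 120),)
        assert r.covered_aa == 111

    def test_disjoint_intervals_kept_separate(self):
        r = merge_regions([mk_alignment("g", "s", 10, 30),
                           mk_alignment("g", "s", 50, 60)])
        assert r.intervals == ((10, 30), (50, 60))
        assert r.covered_aa == 32

    def test_abutting_intervals_merge(self):
        r = merge_regions([mk_alignment("g", "s", 10, 20),
                           mk_alignment("g", "s", 21, 30)])
        assert r.intervals == ((10, 30),)

    def test_single_alignment_identity(self):
        r = merge_regions([mk_alignment("g", "s", 5, 40)])
        assert r.intervals == ((5, 40),)
        assert r.covered_aa == 36

    def test_order_invariant_and_idempotent(self):
        als = [mk_alignment("g", "s", 50, 120), mk_alignment("g", "s", 10, 60),
               mk_alignment("g", "s", 200, 230)]
        r1 = merge_regions(als)
        r2 = merge_regions(list(reversed(als)))
        assert r1 == r2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_regions([])


# ---------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------

class TestDetectCandidates:
    def test_overlap_boundary_five_accepted(self):
        als = [mk_alignment("A", "s", 1, 100), mk_alignment("B", "s", 96, 200)]
        cands = detect_fusion_candidates(als, TH)
        assert len(cands) == 1
        assert cands[0].overlap_aa == 5
        assert cands[0].status is CandidateStatus.ACCEPTED

    def test_overlap_six_not_a_candidate(self):
        als = [mk_alignment("A", "s", 1, 100), mk_alignment("B", "s", 95, 200)]
        assert detect_fusion_candidates(als, TH) == []

    def test_containment_discards(self):
        als = [mk_alignment("A", "s", 1, 100), mk_alignment("B", "s", 110, 200),
               mk_alignment("C", "s", 1, 200)]
        cands = detect_fusion_candidates(als, TH)
        ab = next(c for c in cands if c.gene_pair.key == ("A", "B"))
        assert ab.status is CandidateStatus.DISCARDED_CONTAINMENT

    def test_three_genes_without_containment_flagged(self):
        als = [mk_alignment("A", "s", 1, 90), mk_alignment("B", "s", 100, 190),
               mk_alignment("C", "s", 200, 290)]
        cands = detect_fusion_candidates(als, TH)
        assert len(cands) == 3
        assert all(c.status is CandidateStatus.FLAG_MANUAL for c in cands)

    def test_symmetric_in_gene_order_and_isoform_order(self):
        als = [mk_alignment("B", "s", 96, 200, query_protein="B.2"),
               mk_alignment("A", "s", 1, 100, query_protein="A.1"),
               mk_alignment("A", "s", 20, 80, query_protein="A.2")]
        c1 = detect_fusion_candidates(als, TH)
        c2 = detect_fusion_candidates(list(reversed(als)), TH)
        assert [c.gene_pair.key for c in c1] == [c.gene_pair.key for c in c2]
        assert c1[0].gene_pair.key == ("A", "B")

    def test_raising_min_len_never_adds_candidates(self):
        rng = np.random.default_rng(0)
        als = []
        for i in range(30):
            g = f"g{int(rng.integers(6))}"
            s = f"s{int(rng.integers(3))}"
            start = int(rng.integers(1, 150))
            length = int(rng.integers(15, 80))
            als.append(mk_alignment(g, s, start, start + length))
        loose = {c.gene_pair.key for c in detect_fusion_candidates(
            filter_alignments(als, TH), TH)
            if c.status is CandidateStatus.ACCEPTED}
        strict_th = DetectionThresholds(
            min_align_len=40, min_identity_by_species={SPECIES: 50.0})
        strict = {c.gene_pair.key for c in detect_fusion_candidates(
            filter_alignments(als, strict_th), strict_th)
            if c.status is CandidateStatus.ACCEPTED}
        assert strict <= loose


def test_tabular_roundtrip(tmp_path):
    als = [mk_alignment("g1", "s1", 10, 60), mk_alignment("g2", "s1", 70, 120)]
    path = tmp_path / "hits.tsv"
    write_tabular_alignments(als, path)
    back = read_tabular_alignments(path, {"g1.1": "g1", "g2.1": "g2"}, SPECIES)
    assert [(a.query_gene, a.s_start, a.s_end) for a in back] \
        == [("g1", 10, 60), ("g2", 70, 120)]
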