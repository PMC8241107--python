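import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_local_score
from mimicscan.alignment import (LocalAlignment, ScoringScheme,
                                 best_protein_per_organism, compute_evalue,
                                 encode, passes_mimicry_filter, scan_epitopes,
                                 smith_waterman)
from mimicscan.io_formats import (EpitopeRecord, OrganismAnnotation,
                                  PipelineConfig, ProteinRecord)

seqs3 = st.text(alphabet="ARN", min_size=1, max_size=6)


def _aln(identity=100.0, cover=100.0, gaps=0, evalue=0.5, score=50):
    return LocalAlignment("q", "s", score, evalue, 1, 15, 1, 15,
                          "A" * 15, "A" * 15, identity, cover, gaps)


class TestSmithWaterman:
    def test_exact_match_scores_blosum_diagonal(self, scheme):
        aln = smith_waterman("KDEL", "KDEL", scheme)[0]
        assert aln.score == 20  # 5 + 6 + 5 + 4 on the BLOSUM62 diagonal
        assert aln.identity_pct == 100.0
        assert aln.query_cover_pct == 100.0
        assert aln.gap_count == 0

    @given(q=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_self_alignment_is_full_identity(self, q):
        aln = smith_waterman(q, q)[0]
        assert aln.identity_pct == 100.0
        assert aln.query_cover_pct == 100.0
        assert aln.gap_count == 0

    def test_empty_sequence_rejected(self, scheme):
        with pytest.raises(ValueError):
            smith_waterman("", "ACD", scheme)

    def test_embedded_query_found_at_coordinates(self, scheme):
        aln = smith_waterman("ACDEFGHIK", "MMMACDEFGHIKMMM", scheme)[0]
        assert (aln.subject_start, aln.subject_end) == (4, 12)
        assert (aln.query_start, aln.query_end) == (1, 9)

    def test_gapped_alignment_counts_gap_columns(self, scheme):
        # a single insertion in non-repetitive sequence: bridging the gap
        # (cost 12) beats any ungapped placement
        q = "ACDEFGHIKLMNPQRSTVWY"
        s = "ACDEFGHIKL" + "W" + "MNPQRSTVWY"
        aln = smith_waterman(q, s, scheme)[0]
        assert aln.gap_count == 1
        assert "-" in aln.aligned_query
        assert len(aln.aligned_query) == len(aln.aligned_subject)

    @given(a=seqs3, b=seqs3)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_score_symmetry(self, a, b, scheme):
        sa = smith_waterman(a, b, scheme)
        sb = smith_waterman(b, a, scheme)
        assert bool(sa) == bool(sb)
        if sa:
            assert sa[0].score == sb[0].score

    @given(a=seqs3, b=seqs3)
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_oracle_equivalence_property(self, a, b, scheme):
        expected = brute_force_local_score(encode(a), encode(b),
                                           scheme.substitution_matrix)
        alns = smith_waterman(a, b, scheme)
        got = alns[0].score if alns else 0
        assert got == expected

    def test_oracle_equivalence_exhaustive_small(self, scheme):
        # every pair with both lengths <= 2 over a 3-letter alphabet
        seqs = [''.join(p) for n in (1, 2)
                for p in itertools.product("ARN", repeat=n)]
        for a in seqs:
            for b in seqs:
                expected = brute_force_local_score(encode(a), encode(b),
                                                   scheme.substitution_matrix)
                alns = smith_waterman(a, b, scheme)
                got = alns[0].score if alns else 0
                assert got == expected, (a, b)

    def test_agrees_with_biopython_on_random_pairs(self, scheme):
        # independent cross-check against a separately developed aligner
        from Bio import Align
        aligner = Align.PairwiseAligner(mode="local",
                                        substitution_matrix=None)
        from Bio.Align import substitution_matrices
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(42)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(60):
            a = "".join(rng.choice(aas, size=rng.integers(5, 25)))
            b = "".join(rng.choice(aas, size=rng.integers(5, 60)))
            ours = smith_waterman(a, b, scheme)
            theirs = aligner.score(a, b)
            assert (ours[0].score if ours else 0) == max(0, theirs)

    def test_suboptimal_alignments_nonoverlapping_and_ordered(self, scheme):
        subject = "MMMM" + "ACDEFGHIKW" + "PPPP" + "ACDEFGHIKW" + "MMMM"
        alns = smith_waterman("ACDEFGHIKW", subject, scheme, suboptimal_count=2)
        assert len(alns) >= 2
        assert alns[0].score >= alns[1].score
        s0 = set(range(alns[0].subject_start, alns[0].subject_end + 1))
        s1 = set(range(alns[1].subject_start, alns[1].subject_end + 1))
        assert not s0 & s1

    def test_deterministic_tie_break_prefers_first_subject_occurrence(self, scheme):
        alns = smith_waterman("KDEL", "AAKDELAAKDELAA", scheme)
        assert alns[0].subject_start == 3


class TestEvalue:
    def test_closed_form(self):
        scheme = ScoringScheme()
        expected = 0.041 * 15 * 10000 * math.exp(-0.267 * 40)
        assert compute_evalue(40, 15, 10000, scheme) == pytest.approx(expected)

    def test_strictly_decreasing_in_score(self):
        evs = [compute_evalue(s, 15, 10**6) for s in range(0, 200, 5)]
        assert all(a > b for a, b in zip(evs, evs[1:]))
        assert evs[-1] < 1e-12  # -> 0 as score grows

    def test_linear_in_database_size(self):
        assert compute_evalue(40, 15, 20000) == pytest.approx(
            2 * compute_evalue(40, 15, 10000))

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            compute_evalue(40, 0, 100)


class TestMimicryFilter:
    def test_boundary_values_inclusive_for_identity_and_cover(self, cfg):
        assert passes_mimicry_filter(_aln(identity=80.0, cover=80.0), cfg)

    def test_evalue_boundary_strict(self, cfg):
        assert not passes_mimicry_filter(_aln(evalue=1.0), cfg)

    def test_any_gap_fails(self, cfg):
        assert not passes_mimicry_filter(_aln(gaps=1), cfg)

    @pytest.mark.parametrize("mismatches,expected", [(0, True), (3, True), (4, False)])
    def test_15mer_mismatch_budget(self, mismatches, expected, cfg):
        identity = 100.0 * (15 - mismatches) / 15
        assert passes_mimicry_filter(_aln(identity=identity), cfg) is expected

    @pytest.mark.parametrize("L", [9, 12, 15, 20])
    def test_mismatch_bound_is_floor_of_length_times_tolerance(self, L, cfg):
        bound = math.floor(L * (100 - cfg.identity_min_pct) / 100 + 1e-9)
        for d in range(L + 1):
            identity = 100.0 * (L - d) / L
            assert passes_mimicry_filter(_aln(identity=identity), cfg) \
                == (d <= bound)


class TestScan:
    def test_empty_epitope_list_gives_no_hits(self, cfg, scheme):
        prots = [ProteinRecord("P1", sequence="ACDEFGHIKLMNPQRSTVWY")]
        assert scan_epitopes([], prots, cfg, scheme) == []

    def test_empty_proteome_is_an_error(self, cfg, scheme):
        with pytest.raises(ValueError):
            scan_epitopes([EpitopeRecord("E1", "ACDEFGHIKLMNPQR")], [], cfg, scheme)

    def test_exact_plant_found_at_planted_coordinates(self, cfg, scheme):
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        epi = EpitopeRecord("E1", "WWKDELACDEFGHIK", antigen_id="Antigen_1")
        prots = []
        for k in range(3):
            seq = list(rng.choice(aas, size=300))
            if k == 1:
                seq[100:115] = list(epi.sequence)
            prots.append(ProteinRecord(f"P{k}", sequence="".join(seq)))
        hits = scan_epitopes([epi], prots, cfg, scheme)
        assert len(hits) == 1
        h = hits[0]
        assert h.subject_accession == "P1"
        assert (h.alignment.subject_start, h.alignment.subject_end) == (101, 115)
        assert h.alignment.identity_pct == 100.0

    def test_epitope_planted_twice_yields_two_hits(self, cfg, scheme):
        rng = np.random.default_rng(4)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        epi = EpitopeRecord("E1", "WWKDELACDEFGHIK", antigen_id="Antigen_1")
        prots = []
        for k in range(2):
            seq = list(rng.choice(aas, size=300))
            seq[50:65] = list(epi.sequence)
            prots.append(ProteinRecord(f"P{k}", sequence="".join(seq)))
        hits = scan_epitopes([epi], prots, cfg, scheme)
        assert len(hits) == 2
        assert {h.subject_accession for h in hits} == {"P0", "P1"}


class TestBestProteinPerOrganism:
    def _hit(self, org, acc, evalue):
        ann = OrganismAnnotation(org, "Bacteria")
        aln = _aln(evalue=evalue)
        from mimicscan.alignment import MimicryHit
        return MimicryHit(alignment=aln, epitope_id="E1", antigen_id="A1",
                          subject_accession=acc, organism=ann)

    def test_single_protein(self):
        assert best_protein_per_organism([self._hit("O1", "P1", 1e-4)]) == {"O1": "P1"}

    def test_lowest_evalue_wins(self):
        hits = [self._hit("O1", "P_worse", 1e-3), self._hit("O1", "P_best", 1e-5)]
        assert best_protein_per_organism(hits)["O1"] == "P_best"

    def test_tie_broken_lexicographically(self, caplog):
        hits = [self._hit("O1", "P_b", 1e-5), self._hit("O1", "P_a", 1e-5)]
        with caplog.at_level("WARNING"):
            assert best_protein_per_organism(hits)["O1"] == "P_a"
        assert any("tie" in r.message for r in caplog.records)
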