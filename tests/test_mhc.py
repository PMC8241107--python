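import numpy as np
import pytest

from mimicscan.io_formats import (CLASS1_PANEL_27, CLASS2_PANEL_26,
                                  EXCLUDED_ALLELES_RA, EpitopeRecord,
                                  ProteinRecord)
from mimicscan.mhc import (PSSMScorer, apply_allele_exclusions,
                           exclude_homologous_to_experimental,
                           generate_peptides, load_pssm, percentile_ranks,
                           save_pssm, score_panel, select_tier)


@pytest.fixture(scope="module")
def protein():
    rng = np.random.default_rng(11)
    return ProteinRecord("P1", sequence="".join(
        rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200)))


@pytest.fixture(scope="module")
def scorer():
    return PSSMScorer.random(["AL1", "AL2", "AL3"], seed=5)


class TestGeneratePeptides:
    def test_class2_starts_are_arithmetic_with_step_five(self):
        prot = ProteinRecord("P", sequence="A" * 14 + "CDEFGHIKLMNPQRSTVWY" * 2)
        peps = generate_peptides(prot, length=15, overlap=10)
        starts = [s for s, _ in peps]
        assert all(b - a == 5 for a, b in zip(starts, starts[1:]))

    def test_window_arithmetic_for_30mer(self):
        prot = ProteinRecord("P", sequence="ACDEFGHIKLMNPQRSTVWY" + "WYVTSRQPNM")
        peps = generate_peptides(prot, length=15, overlap=10)
        assert [s for s, _ in peps] == [1, 6, 11, 16]

    def test_class1_sliding_window_count(self):
        prot = ProteinRecord("P", sequence="ACDEFGHIKL")
        assert len(generate_peptides(prot, length=9, overlap=8)) == 2

    def test_short_protein_gives_empty_list(self):
        prot = ProteinRecord("P", sequence="ACDEF")
        assert generate_peptides(prot, length=15, overlap=10) == []

    def test_duplicates_removed_first_kept(self):
        prot = ProteinRecord("P", sequence="ACDEF" * 8)
        peps = generate_peptides(prot, length=15, overlap=10)
        assert len(peps) == 1  # step 5 on a period-5 sequence repeats one window

    def test_overlap_must_be_less_than_length(self, protein):
        with pytest.raises(ValueError):
            generate_peptides(protein, length=15, overlap=15)

    def test_every_peptide_is_exact_substring(self, protein):
        for start, pep in generate_peptides(protein, 15, 10):
            assert protein.sequence[start - 1:start + 14] == pep


class TestScoring:
    def test_cardinality_and_determinism(self, protein, scorer):
        peps = generate_peptides(protein, 15, 10)
        scored = score_panel(peps, ["AL1", "AL2", "AL3"], scorer, "P1", "II")
        assert len(scored) == len(peps) * 3
        again = score_panel(peps, ["AL1", "AL2", "AL3"], scorer, "P1", "II")
        assert [p.raw_score for p in scored] == [p.raw_score for p in again]

    def test_unsupported_allele_named_in_error(self, protein, scorer):
        peps = generate_peptides(protein, 15, 10)
        with pytest.raises(KeyError, match="AL9"):
            score_panel(peps, ["AL1", "AL9"], scorer, "P1", "II")

    def test_pssm_score_is_max_over_core_offsets(self, scorer):
        pep = "ACDEFGHIKLMNPQR"
        m = scorer.matrices["AL1"]
        from mimicscan.alignment import encode
        idx = encode(pep)
        expected = max(m[np.arange(9), idx[o:o + 9]].sum() for o in range(7))
        assert scorer.score(pep, "AL1") == pytest.approx(expected)

    def test_planted_motif_peptide_ranks_first(self, protein):
        motif = "WWWHHHKKK"
        seq = protein.sequence[:80] + motif + protein.sequence[80:]
        prot = ProteinRecord("P2", sequence=seq)
        scorer = PSSMScorer.random(["AL1"], seed=5, motifs={"AL1": motif})
        peps = generate_peptides(prot, 15, 10)
        ranked = percentile_ranks(score_panel(peps, ["AL1"], scorer, "P2", "II"))
        best = min(ranked, key=lambda p: p.percentile_rank)
        assert motif in best.peptide
        assert best.percentile_rank == pytest.approx(100.0 / len(peps))

    def test_pssm_text_round_trip(self, scorer, tmp_path):
        path = tmp_path / "pssm.txt"
        save_pssm(scorer.matrices["AL1"], path)
        back = load_pssm(path)
        np.testing.assert_allclose(back, scorer.matrices["AL1"], atol=1e-6)


class TestPercentileRanks:
    def _ranked(self, scores, protein="P", allele="A"):
        from mimicscan.mhc import PredictedPeptide
        preds = [PredictedPeptide(protein, i + 1, f"PEP{i}", allele, s, "II")
                 for i, s in enumerate(scores)]
        return percentile_ranks(preds)

    def test_top_of_200_is_half_percent(self):
        ranked = self._ranked(list(range(200)))
        top = max(ranked, key=lambda p: p.raw_score)
        assert top.percentile_rank == pytest.approx(0.5)

    def test_ties_share_smaller_rank(self):
        ranked = self._ranked([9.0, 9.0, 1.0, 0.5])
        tied = [p for p in ranked if p.raw_score == 9.0]
        assert all(p.percentile_rank == pytest.approx(25.0) for p in tied)

    def test_rank_multiset_is_exact_for_distinct_scores(self):
        rng = np.random.default_rng(0)
        n = 37
        ranked = self._ranked(list(rng.permutation(n).astype(float)))
        got = sorted(p.percentile_rank for p in ranked)
        expected = [100.0 * r / n for r in range(1, n + 1)]
        assert got == pytest.approx(expected)


class TestExclusionsAndTiers:
    def _panel_preds(self, n_peptides=40, alleles=("A1", "A2", "A3"), seed=0):
        rng = np.random.default_rng(seed)
        prot = ProteinRecord("P", sequence="".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_peptides + 14)))
        peps = generate_peptides(prot, 15, 14)
        scorer = PSSMScorer.random(list(alleles), seed=seed)
        return percentile_ranks(score_panel(peps, list(alleles), scorer, "P", "II"))

    def test_no_exclusions_is_identity(self):
        preds = self._panel_preds()
        assert apply_allele_exclusions(preds, []) == preds

    def test_best_rank_worsens_when_best_allele_excluded(self):
        preds = self._panel_preds()
        target = min(preds, key=lambda p: p.percentile_rank)
        kept = apply_allele_exclusions(preds, [target.allele])
        same = [p for p in kept if p.start == target.start]
        assert all(p.best_rank >= target.best_rank for p in same)
        assert all(p.allele != target.allele for p in kept)

    def test_paper_panel_exclusion_leaves_23_alleles(self):
        excluded = set(EXCLUDED_ALLELES_RA)
        assert excluded <= set(CLASS2_PANEL_26)
        assert len(CLASS2_PANEL_26) == 26
        assert len(CLASS1_PANEL_27) == 27
        assert len(set(CLASS2_PANEL_26) - excluded) == 23

    def test_missing_excluded_allele_warns_not_errors(self, caplog):
        preds = self._panel_preds()
        with caplog.at_level("WARNING"):
            apply_allele_exclusions(preds, ["NOT_IN_PANEL"])
        assert any("NOT_IN_PANEL" in r.message for r in caplog.records)

    def test_tier_100_selects_every_peptide(self):
        preds = self._panel_preds()
        n_peptides = len({(p.start, p.peptide) for p in preds})
        assert len(select_tier(preds, 100.0)) == n_peptides

    def test_tier_10_of_200_distinct_scores_is_20(self):
        # 200 peptides with strictly distinct scores: r <= 20 iff rank
        # percentile 100r/200 <= 10
        from mimicscan.mhc import PredictedPeptide
        preds = percentile_ranks([
            PredictedPeptide("P", i + 1, f"PEP{i}", "A1", float(i), "II")
            for i in range(200)])
        assert len(select_tier(preds, 10.0)) == 20

    def test_tier_nesting_monotone(self):
        preds = self._panel_preds()
        keys = lambda sel: {(p.start, p.peptide) for p in sel}
        for a, b in [(0.5, 1.0), (1.0, 2.0), (2.0, 10.0), (10.0, 100.0)]:
            assert keys(select_tier(preds, a)) <= keys(select_tier(preds, b))


class TestHomologyExclusion:
    def test_identical_prediction_removed(self):
        from mimicscan.mhc import PredictedPeptide
        epi = EpitopeRecord("E1", "WKDELACDEFGHIKW", antigen_id="A1")
        pred = PredictedPeptide("P", 1, "WKDELACDEFGHIKW", "A", 0.0, "II")
        assert exclude_homologous_to_experimental([pred], [epi]) == []

    def test_dissimilar_prediction_retained(self):
        from mimicscan.mhc import PredictedPeptide
        epi = EpitopeRecord("E1", "WWWWWWWWWWWWWWW", antigen_id="A1")
        pred = PredictedPeptide("P", 1, "ACDEFGHIKLMNPQR", "A", 0.0, "II")
        assert exclude_homologous_to_experimental([pred], [epi]) == [pred]

    def test_planted_copies_removed_others_survive(self):
        from mimicscan.mhc import PredictedPeptide
        rng = np.random.default_rng(9)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        experimental = [EpitopeRecord(f"E{i}", "".join(rng.choice(aas, size=15)),
                                      antigen_id="A1") for i in range(3)]
        preds = [PredictedPeptide("P", i + 1, "".join(rng.choice(aas, size=15)),
                                  "A", 0.0, "II") for i in range(8)]
        copies = [PredictedPeptide("P", 100 + i, experimental[i].sequence,
                                   "A", 0.0, "II") for i in range(2)]
        kept = exclude_homologous_to_experimental(preds + copies, experimental)
        assert len(kept) == 8
        assert all(p.start <= 8 for p in kept)
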