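"""PSSM construction, window scoring, empirical E-values and iteration."""

import math

import numpy as np
import pytest

from orbimine.iterative import (
    NullProteomeModel,
    RepeatAlignment,
    SearchInputError,
    build_pssm,
    empirical_evalue,
    iterate_search,
    sample_null_scores,
    score_windows,
)
from orbimine.mining import ProteinRecord
from orbimine.profiles import CANONICAL_RESIDUES

AA = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}


def mutate(rng, s, k):
    s = list(s)
    for i in rng.choice(len(s), size=k, replace=False):
        s[i] = CANONICAL_RESIDUES[int(rng.integers(20))]
    return "".join(s)


def random_seq(rng, n):
    return "".join(rng.choice(list(CANONICAL_RESIDUES), size=n))


class TestBuildPssm:
    def test_conserved_column_score_hand_arithmetic(self):
        # 12 identical D rows, alpha=1, uniform background:
        # p(D) = 12.05/13, score = ln(p/0.05) ~ 2.9198
        aln = RepeatAlignment([f"r{i}" for i in range(12)], ["D"] * 12)
        pssm = build_pssm(aln, alpha=1.0)
        assert pssm.scores[0, AA["D"]] == pytest.approx(
            math.log((12.05 / 13) / 0.05), abs=1e-12)
        assert pssm.scores[0, AA["D"]] == pytest.approx(2.91985, abs=1e-5)

    def test_background_like_column_scores_near_zero(self):
        rows = [aa for aa in CANONICAL_RESIDUES] * 50  # exact background
        aln = RepeatAlignment([f"r{i}" for i in range(len(rows))], rows)
        pssm = build_pssm(aln, alpha=1.0)
        assert np.abs(pssm.scores).max() < 1e-9

    def test_absent_residue_gets_finite_negative_score(self):
        aln = RepeatAlignment(["a", "b"], ["D", "D"])
        pssm = build_pssm(aln, alpha=1.0)
        assert np.isfinite(pssm.scores).all()
        assert pssm.scores[0, AA["W"]] < 0

    def test_gap_only_columns_dropped(self):
        aln = RepeatAlignment(["a", "b"], ["D-K", "D-M"])
        pssm = build_pssm(aln)
        assert pssm.width == 2
        assert pssm.columns == [0, 2]

    def test_input_validation(self):
        with pytest.raises(SearchInputError):
            RepeatAlignment(["a"], ["DK"])
        with pytest.raises(SearchInputError):
            RepeatAlignment(["a", "b"], ["DK", "DKM"])
        aln = RepeatAlignment(["a", "b"], ["DK", "DM"])
        with pytest.raises(SearchInputError):
            build_pssm(aln, alpha=0.0)


class TestScoreWindows:
    def test_score_additivity_against_per_residue_oracle(self, rng):
        rows = [random_seq(rng, 10) for _ in range(6)]
        pssm = build_pssm(RepeatAlignment([f"r{i}" for i in range(6)], rows))
        protein = ProteinRecord("p", "", random_seq(rng, 40))
        scores, _ = score_windows(pssm, protein)
        for start in range(len(scores)):
            expected = sum(
                pssm.scores[c, AA[protein.sequence[start + c]]]
                for c in range(pssm.width))
            assert scores[start] == pytest.approx(expected)

    def test_consensus_scores_maximum(self, rng):
        rows = [random_seq(rng, 12)] * 5
        pssm = build_pssm(RepeatAlignment([f"r{i}" for i in range(5)], rows))
        protein = ProteinRecord("p", "", rows[0])
        scores, best = score_windows(pssm, protein)
        assert len(scores) == 1  # L == w
        assert best.score == pytest.approx(pssm.max_score())

    def test_tie_broken_to_smallest_start(self, rng):
        rows = [random_seq(rng, 8)] * 4
        pssm = build_pssm(RepeatAlignment(list("abcd"), rows))
        protein = ProteinRecord("p", "", rows[0] + "W" + rows[0])
        _, best = score_windows(pssm, protein)
        assert best.start == 0

    def test_planted_two_substitution_repeat_found_at_offset(self, rng):
        cons = random_seq(rng, 20)
        rows = [mutate(rng, cons, 2) for _ in range(10)]
        pssm = build_pssm(RepeatAlignment([f"r{i}" for i in range(10)], rows))
        offset = 33
        seq = random_seq(rng, offset) + mutate(rng, cons, 2) + random_seq(rng, 30)
        _, best = score_windows(pssm, ProteinRecord("p", "", seq))
        assert best.start == offset

    def test_short_protein_rejected(self, rng):
        pssm = build_pssm(RepeatAlignment(["a", "b"],
                                          [random_seq(rng, 10)] * 2))
        with pytest.raises(SearchInputError):
            score_windows(pssm, ProteinRecord("p", "", "MK"))


class TestEmpiricalEvalue:
    @pytest.fixture
    def setup(self, rng):
        rows = [mutate(rng, random_seq(rng, 15), 1) for _ in range(6)]
        pssm = build_pssm(RepeatAlignment([f"r{i}" for i in range(6)], rows))
        proteome = [ProteinRecord(f"b{i}", "", random_seq(rng, 120))
                    for i in range(25)]
        return pssm, NullProteomeModel.from_proteome(proteome)

    def test_low_score_gives_maximal_evalue(self, setup):
        pssm, null_model = setup
        e = empirical_evalue(-1e6, pssm, null_model, n_shuffles=200, seed=1)
        assert e == null_model.database_size

    def test_high_score_gives_zero_evalue(self, setup):
        pssm, null_model = setup
        e = empirical_evalue(1e6, pssm, null_model, n_shuffles=200, seed=1)
        assert e < null_model.database_size / 200
        assert e == 0.0

    def test_seeded_determinism(self, setup):
        pssm, null_model = setup
        args = (10.0, pssm, null_model)
        assert (empirical_evalue(*args, n_shuffles=200, seed=42)
                == empirical_evalue(*args, n_shuffles=200, seed=42))

    def test_too_few_shuffles_rejected(self, setup):
        pssm, null_model = setup
        with pytest.raises(SearchInputError):
            empirical_evalue(1.0, pssm, null_model, n_shuffles=50)


class TestIterateSearch:
    def test_no_hits_converges_after_one_round(self, rng):
        rows = [random_seq(rng, 18)] * 4
        aln = RepeatAlignment(list("abcd"), rows)
        proteome = [ProteinRecord(f"b{i}", "", random_seq(rng, 100))
                    for i in range(20)]
        result = iterate_search(aln, proteome, n_shuffles=200, seed=2)
        assert result.hits == {}
        assert len(result.rounds) == 1
        assert result.alignment.rows == rows

    def test_recovers_planted_homologues_and_is_monotone(self, rng):
        cons = random_seq(rng, 22)
        rows = [mutate(rng, cons, 3) for _ in range(10)]
        aln = RepeatAlignment([f"r{i}" for i in range(10)], rows)
        proteome, planted = [], []
        for i in range(8):
            left = random_seq(rng, int(rng.integers(20, 120)))
            right = random_seq(rng, int(rng.integers(20, 120)))
            proteome.append(ProteinRecord(f"hom{i}", "",
                                          left + mutate(rng, cons, 2) + right))
            planted.append(f"hom{i}")
        for i in range(30):
            proteome.append(ProteinRecord(f"bg{i}", "", random_seq(rng, 150)))
        result = iterate_search(aln, proteome, n_shuffles=500, seed=3)
        assert set(result.hits) == set(planted)
        totals = [log.n_accepted_total for log in result.rounds]
        assert totals == sorted(totals)  # accepted set never shrinks
        assert all(h.evalue is not None and h.evalue < 0.01
                   for h in result.hits.values())

    def test_accepted_windows_grow_the_alignment(self, rng):
        cons = random_seq(rng, 20)
        aln = RepeatAlignment(["a", "b"], [cons, mutate(rng, cons, 1)])
        proteome = [ProteinRecord("hit", "",
                                  random_seq(rng, 30) + cons + random_seq(rng, 30))]
        proteome += [ProteinRecord(f"bg{i}", "", random_seq(rng, 80))
                     for i in range(10)]
        result = iterate_search(aln, proteome, n_shuffles=200, seed=4)
        assert "hit" in result.hits
        assert len(result.alignment.rows) == 3
        assert result.alignment.rows[-1] == cons

    def test_bad_arguments(self, rng):
        aln = RepeatAlignment(["a", "b"], ["DK" * 5] * 2)
        with pytest.raises(SearchInputError):
            iterate_search(aln, [ProteinRecord("p", "", "M" * 30)], max_rounds=0)
        with pytest.raises(SearchInputError):
            iterate_search(aln, [ProteinRecord("p", "", "M" * 30)], n_shuffles=10)
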