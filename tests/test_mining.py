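"""Mining pipeline: primary pool, multi-match filter, repeat confirmation,
calls, Venn categories, leader extraction and hit statistics."""

import numpy as np
import pytest

from orbimine.mining import (
    MiningInputError,
    MiningParams,
    ProteinRecord,
    call_lldr,
    confirm_repeats,
    filter_multi_match,
    hit_statistics,
    leader_region,
    mine_primary_pool,
    venn_categories,
)
from orbimine.profiles import build_canonical_profiles, scan_sequence
from orbimine.synthetic import SyntheticSpec, generate_proteome

REPEAT = "DGAVILVNIFGK"
TWO_REPEAT_PROTEIN = "M" + "S" * 20 + "DGAVILVNIFGK" + "T" * 8 + "DATMWGGVDSFGK"


def tandem_protein(n_units, unit=REPEAT + "NNSS", leader="M" + "L" * 19):
    return ProteinRecord("tandem", "", leader + unit * n_units)


class TestPrimaryPoolAndFilter:
    def test_single_printed_repeat_enters_pool(self, canonical_profiles):
        pool = mine_primary_pool([ProteinRecord("g39692", "", REPEAT)],
                                 canonical_profiles[:1])
        assert set(pool) == {"g39692"}
        assert len(pool["g39692"]["1"]) == 1

    def test_empty_proteome_gives_empty_pool(self, canonical_profiles):
        assert mine_primary_pool([], canonical_profiles) == {}

    def test_duplicate_ids_rejected(self, canonical_profiles):
        records = [ProteinRecord("x", "", REPEAT)] * 2
        with pytest.raises(MiningInputError):
            mine_primary_pool(records, canonical_profiles)

    def test_two_repeat_protein_excluded_at_default_threshold(self,
                                                              canonical_profiles):
        pool = mine_primary_pool([ProteinRecord("g39692", "", TWO_REPEAT_PROTEIN)],
                                 canonical_profiles[:1])
        assert len(pool["g39692"]["1"]) == 2
        assert filter_multi_match(pool) == {}

    def test_exactly_three_matches_is_retained(self, canonical_profiles):
        pool = mine_primary_pool([tandem_protein(3)], canonical_profiles[:1])
        refined = filter_multi_match(pool)
        assert len(refined["tandem"]["1"]) == 3

    def test_min_matches_one_keeps_primary_pool(self, canonical_profiles):
        pool = mine_primary_pool([ProteinRecord("g39692", "", TWO_REPEAT_PROTEIN)],
                                 canonical_profiles)
        assert filter_multi_match(pool, MiningParams(min_matches=1)) == pool

    def test_filter_monotone_in_min_matches(self, canonical_profiles):
        spec = SyntheticSpec(seed=3, n_background=30, n_lldr=4,
                             repeats_per_protein=(3, 6))
        proteins, _ = generate_proteome(spec)
        pool = mine_primary_pool(proteins, canonical_profiles)
        previous = None
        for k in range(1, 6):
            refined = filter_multi_match(pool, MiningParams(min_matches=k))
            if previous is not None:
                assert set(refined) <= set(previous)
                for pid in refined:
                    assert set(refined[pid]) <= set(previous[pid])
            previous = refined


class TestConfirmRepeats:
    def test_verbatim_triplicate_is_confirmed(self, canonical_profiles):
        protein = tandem_protein(3)
        matches = scan_sequence(protein.sequence, canonical_profiles[0])
        confirmed, units = confirm_repeats(protein, matches)
        assert confirmed
        assert units[0] == units[1]

    def test_fewer_than_three_matches_is_an_input_error(self, canonical_profiles):
        protein = ProteinRecord("x", "", TWO_REPEAT_PROTEIN)
        matches = scan_sequence(protein.sequence, canonical_profiles[0])
        assert len(matches) == 2
        with pytest.raises(MiningInputError):
            confirm_repeats(protein, matches)

    def test_long_random_spacers_are_rejected(self, rng, canonical_profiles,
                                              profile1):
        """Matches separated by 100 residues of independent uniform noise do
        not look like a repeat pattern: rejection rate well above 95%."""
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        rejected = 0
        n_reps = 400
        for _ in range(n_reps):
            parts = []
            for _ in range(3):
                core = "".join(rng.choice(letters, size=8))
                parts.append("DG" + core + "FGK")
                parts.append("".join(rng.choice(letters, size=100)))
            protein = ProteinRecord("x", "", "".join(parts))
            matches = scan_sequence(protein.sequence, profile1)
            if len(matches) != 3:  # chance extra match; skip ambiguous draw
                continue
            confirmed, _ = confirm_repeats(protein, matches)
            rejected += not confirmed
        assert rejected / n_reps > 0.95


class TestCalls:
    def test_round_trip_on_clean_synthetic_proteome(self, canonical_profiles):
        spec = SyntheticSpec(seed=5, n_background=60, n_lldr=5,
                             repeats_per_protein=(3, 3), corruption_rate=0.0)
        proteins, truth = generate_proteome(spec)
        pool = mine_primary_pool(proteins, canonical_profiles)
        calls = call_lldr(filter_multi_match(pool), proteins)
        called = {c.protein_id for c in calls}
        planted = {t.protein_id for t in truth if t.is_lldr}
        assert called == planted  # precision = recall = 1

    def test_background_only_proteome_yields_no_calls(self, canonical_profiles):
        spec = SyntheticSpec(seed=17, n_background=100, n_lldr=0,
                             bg_length_range=(300, 300))
        proteins, _ = generate_proteome(spec)
        pool = mine_primary_pool(proteins, canonical_profiles)
        assert call_lldr(filter_multi_match(pool), proteins) == []

    def test_profile1_pass_implies_all_relaxed_profiles_in_all_mode(
            self, canonical_profiles):
        """mode=all: every profile-1 match is a match of each relaxed profile,
        so a >=3-match protein passes the filter for all six."""
        params = MiningParams(mode="all")
        pool = mine_primary_pool([tandem_protein(3)], canonical_profiles, params)
        refined = filter_multi_match(pool, params)
        assert set(refined["tandem"]) == {"1", "2", "3", "4", "5", "6"}

    def test_matched_profiles_on_clean_tandem_protein(self, canonical_profiles):
        pool = mine_primary_pool([tandem_protein(4)], canonical_profiles)
        calls = call_lldr(filter_multi_match(pool), [tandem_protein(4)])
        assert len(calls) == 1
        assert calls[0].matched_profiles >= {"1"}
        assert calls[0].repeat_confirmed


class TestVennAndLeader:
    def test_empty_calls_empty_regions(self):
        table, counts = venn_categories([], ["1", "2"])
        assert table.empty and counts == {}

    def test_all_profiles_single_region(self, canonical_profiles):
        pool = mine_primary_pool([tandem_protein(4)], canonical_profiles)
        calls = call_lldr(filter_multi_match(pool), [tandem_protein(4)])
        table, counts = venn_categories(calls, [p.profile_id
                                                for p in canonical_profiles])
        assert sum(counts.values()) == len(calls)

    def test_planted_mixture_regions_match_truth(self, canonical_profiles):
        """k1 fully conserved proteins and k2 proteins whose +2 site is A
        land in the all-profiles region and the profile-5-only region."""
        k1, k2 = 3, 2
        proteins = []
        for i in range(k1):
            proteins.append(ProteinRecord(f"full{i}", "",
                                          tandem_protein(4).sequence))
        broken_unit = "DGAVILVNIFAK" + "NNSS"  # +2 G -> A
        for i in range(k2):
            proteins.append(ProteinRecord(f"deg{i}", "",
                                          "M" + "L" * 19 + broken_unit * 4))
        pool = mine_primary_pool(proteins, canonical_profiles)
        calls = call_lldr(filter_multi_match(pool), proteins)
        _, counts = venn_categories(calls, [p.profile_id
                                            for p in canonical_profiles])
        assert counts[("1", "2", "3", "4", "5", "6")] == k1
        assert counts[("5",)] == k2  # only the +2-randomized profile matches

    def test_leader_region_prefix(self, profile1):
        protein = tandem_protein(3)
        matches = scan_sequence(protein.sequence, profile1)
        leader = leader_region(protein, matches)
        assert leader == "M" + "L" * 19
        assert protein.sequence.startswith(leader)

    def test_leader_region_boundaries(self, profile1):
        protein = ProteinRecord("x", "", REPEAT)
        matches = scan_sequence(protein.sequence, profile1)
        assert leader_region(protein, matches) == ""
        with pytest.raises(MiningInputError):
            leader_region(protein, [])


class TestHitStatistics:
    def test_ratio_and_proportion(self, canonical_profiles):
        pool = mine_primary_pool([tandem_protein(4)], canonical_profiles[:1])
        refined = filter_multi_match(pool)
        stats = hit_statistics(pool, refined, database_size=10)
        row = stats.loc[stats.profile_id == "1"].iloc[0]
        assert row.n_hit_proteins == 1
        assert row.n_matching_strings == 4
        assert row.ratio == 4.0
        assert row.proportion == 0.1

    def test_zero_hits_reported_missing(self):
        stats = hit_statistics({}, {}, database_size=5, profile_ids=["1"])
        row = stats.iloc[0]
        assert row.proportion == 0.0
        assert np.isnan(row.ratio)

    def test_database_size_zero_rejected(self):
        with pytest.raises(MiningInputError):
            hit_statistics({}, {}, 0)

    def test_count_conservation(self, canonical_profiles):
        spec = SyntheticSpec(seed=9, n_background=40, n_lldr=3)
        proteins, _ = generate_proteome(spec)
        pool = mine_primary_pool(proteins, canonical_profiles)
        stats = hit_statistics(pool, filter_multi_match(pool), len(proteins))
        total_from_pool = sum(len(m) for per in pool.values()
                              for m in per.values())
        assert stats.n_matching_strings.sum() == total_from_pool

    def test_orf_library_ratio_near_one(self, profile1):
        """Single-exon ORFs carrying one planted match each: mean ratio 1."""
        proteins = [ProteinRecord(f"orf{i}", "", "M" + "L" * 10 + REPEAT + "SS")
                    for i in range(20)]
        pool = mine_primary_pool(proteins, [profile1])
        stats = hit_statistics(pool, {}, len(proteins))
        assert stats.loc[stats.profile_id == "1", "ratio"].iloc[0] == 1.0
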