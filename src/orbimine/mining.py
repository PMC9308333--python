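"""The profile-matching mining pipeline.

Stages: scan a protein database with a profile set into a primary candidate
pool (any protein with at least one match), keep (protein, profile) entries
with multiple (>= 3 by default) matches, confirm that the matching strings
actually sit in a repeat pattern (median pairwise unit identity), and emit
repeat-protein calls annotated with the full set of profiles each protein
independently passes.  The per-profile protein sets feed the Venn
categorization; per-profile hit statistics feed the trend analysis.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import pandas as pd

from .align import AlignmentParams, DEFAULT_PARAMS, pairwise_global_align
from .profiles import FlankingProfile, ProfileMatch, scan_sequence


class MiningInputError(ValueError):
    pass


@dataclass
class ProteinRecord:
    protein_id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise MiningInputError(f"empty sequence for {self.protein_id!r}")


@dataclass
class MiningParams:
    min_matches: int = 3
    mode: str = "canonical"
    theta: float = 0.3
    align_params: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        if self.min_matches < 1:
            raise MiningInputError("min_matches must be >= 1")
        if not 0.0 <= self.theta <= 1.0:
            raise MiningInputError("theta must be in [0, 1]")


@dataclass
class LLDRCall:
    protein_id: str
    matches: list[ProfileMatch]
    repeat_confirmed: bool
    matched_profiles: set[str]


#: pool structure: protein_id -> profile_id -> canonical matches
Pool = dict[str, dict[str, list[ProfileMatch]]]


def mine_primary_pool(proteome: list[ProteinRecord],
                      profiles: list[FlankingProfile],
                      params: MiningParams | None = None) -> Pool:
    """Scan every protein with every profile; keep proteins with >= 1 match."""
    params = params or MiningParams()
    if not proteome or not profiles:
        return {}
    ids = [p.protein_id for p in proteome]
    if len(set(ids)) != len(ids):
        raise MiningInputError("duplicate protein ids in database")
    pool: Pool = {}
    for protein in proteome:
        per_profile: dict[str, list[ProfileMatch]] = {}
        for profile in profiles:
            matches = scan_sequence(protein.sequence, profile, mode=params.mode,
                                    protein_id=protein.protein_id)
            if matches:
                per_profile[profile.profile_id] = matches
        if per_profile:
            pool[protein.protein_id] = per_profile
    return pool


def filter_multi_match(pool: Pool, params: MiningParams | None = None) -> Pool:
    """Keep (protein, profile) entries with at least ``min_matches`` matches."""
    params = params or MiningParams()
    refined: Pool = {}
    for protein_id, per_profile in pool.items():
        kept = {pid: m for pid, m in per_profile.items()
                if len(m) >= params.min_matches}
        if kept:
            refined[protein_id] = kept
    return refined


def repeat_units(protein: ProteinRecord,
                 matches: list[ProfileMatch]) -> list[str]:
    """Inter-start repeat units: match start to next match start; last = its span."""
    if len(matches) < 2:
        raise MiningInputError("repeat units require >= 2 matches")
    # keep the longest match per start so mode=all inputs yield no empty units
    by_start: dict[int, ProfileMatch] = {}
    for m in sorted(matches, key=lambda m: (m.start, m.end)):
        by_start[m.start] = m
    ordered = sorted(by_start.values(), key=lambda m: m.start)
    units = [protein.sequence[a.start:b.start]
             for a, b in zip(ordered, ordered[1:])]
    units.append(protein.sequence[ordered[-1].start:ordered[-1].end])
    return units


def confirm_repeats(protein: ProteinRecord, matches: list[ProfileMatch],
                    theta: float = 0.3,
                    align_params: AlignmentParams = DEFAULT_PARAMS
                    ) -> tuple[bool, list[str]]:
    """Surrogate repeat-pattern confirmation.

    Units run from each match start to the next match start (the last unit is
    the last match span).  The protein is confirmed iff the median of all
    pairwise unit identities (global alignment, identical columns / aligned
    columns) is >= ``theta``.  Fewer than 3 matches cannot form a repeat
    pattern under the multi-match rule and are rejected as input.
    """
    if len(matches) < 3:
        raise MiningInputError("repeat confirmation requires >= 3 matches")
    units = repeat_units(protein, matches)
    identities = [
        pairwise_global_align(units[i], units[j], align_params).identity
        for i in range(len(units))
        for j in range(i + 1, len(units))
    ]
    confirmed = len(matches) >= 3 and statistics.median(identities) >= theta
    return confirmed, units


def call_lldr(refined: Pool, proteome: list[ProteinRecord],
              params: MiningParams | None = None) -> list[LLDRCall]:
    """Emit one call per protein passing the multi-match filter and repeat
    confirmation for at least one profile.

    ``matched_profiles`` lists every profile the protein independently passes;
    ``matches`` holds the canonical matches of the lowest-numbered matched
    profile (the most constrained one scanned).
    """
    params = params or MiningParams()
    by_id = {p.protein_id: p for p in proteome}
    calls: list[LLDRCall] = []
    for protein_id in sorted(refined):
        protein = by_id[protein_id]
        matched: dict[str, list[ProfileMatch]] = {}
        for profile_id, matches in refined[protein_id].items():
            if len(matches) < 3:
                continue
            confirmed, _ = confirm_repeats(protein, matches, params.theta,
                                           params.align_params)
            if confirmed:
                matched[profile_id] = matches
        if matched:
            first = sorted(matched, key=_profile_sort_key)[0]
            calls.append(LLDRCall(protein_id, matched[first], True, set(matched)))
    return calls


def _profile_sort_key(profile_id: str):
    return (0, int(profile_id)) if profile_id.isdigit() else (1, profile_id)


def venn_categories(calls: list[LLDRCall],
                    profile_ids: list[str]) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Assign each call to exactly one Venn region (its matched-profile set).

    Returns a per-protein membership table and per-region counts; region
    counts sum to the number of calls.
    """
    rows = []
    counts: dict[tuple[str, ...], int] = {}
    for call in calls:
        member = {pid: (pid in call.matched_profiles) for pid in profile_ids}
        region = tuple(sorted((call.matched_profiles & set(profile_ids)),
                              key=_profile_sort_key))
        counts[region] = counts.get(region, 0) + 1
        rows.append({"protein_id": call.protein_id, **member,
                     "region": "&".join(region) if region else "(none)"})
    table = pd.DataFrame(rows, columns=["protein_id", *profile_ids, "region"])
    return table, counts


def leader_region(protein: ProteinRecord, matches: list[ProfileMatch]) -> str:
    """The N-terminal segment preceding the first match (the putative leader)."""
    if not matches:
        raise MiningInputError("leader_region requires at least one match")
    first = min(m.start for m in matches)
    return protein.sequence[:first]


def hit_statistics(pool: Pool, refined: Pool, database_size: int,
                   profile_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-profile summary: hit proteins, matching strings, proportion, ratio.

    ``proportion`` is hit proteins / database size; ``ratio`` is matching
    strings per hit protein (NaN when a profile has no hits).  ``n_refined``
    counts proteins surviving the multi-match filter.
    """
    if database_size <= 0:
        raise MiningInputError("database size must be positive")
    if profile_ids is None:
        profile_ids = sorted({pid for per in pool.values() for pid in per},
                             key=_profile_sort_key)
    rows = []
    for pid in profile_ids:
        n_hits = sum(1 for per in pool.values() if pid in per)
        n_strings = sum(len(per[pid]) for per in pool.values() if pid in per)
        n_refined = sum(1 for per in refined.values() if pid in per)
        rows.append({
            "profile_id": pid,
            "n_hit_proteins": n_hits,
            "n_matching_strings": n_strings,
            "n_refined": n_refined,
            "proportion": n_hits / database_size,
            "ratio": (n_strings / n_hits) if n_hits else float("nan"),
        })
    return pd.DataFrame(rows)
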