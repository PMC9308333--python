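"""Flanking-site sequence profiles and profile scanning.

An orbitide-like repeat unit is a hypervariable 4-13 residue core flanked by
five signature positions: -2 and -1 on the N-terminal side of the core, and
+1, +2, +3 on the C-terminal side.  In the known flax (linusorb) precursor
repeats the sites are dominated by D (-2), [DAG] (-1), [FVI] (+1), G (+2) and
K (+3).  A :class:`FlankingProfile` fixes a subset of these sites to their
signature residue sets and leaves the rest (and always the core) unconstrained
("random").  The information content of a profile measures how constraining
its specified sites are, in nats, against a uniform 20-residue background.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

#: Flank positions, N- to C-terminal, relative to the core.
SITE_ORDER: tuple[str, ...] = ("-2", "-1", "+1", "+2", "+3")

#: Signature residue sets of the five flanking positions.
CANONICAL_SITE_SETS: dict[str, frozenset[str]] = {
    "-2": frozenset("D"),
    "-1": frozenset("DAG"),
    "+1": frozenset("FVI"),
    "+2": frozenset("G"),
    "+3": frozenset("K"),
}

CORE_MIN_DEFAULT = 4
CORE_MAX_DEFAULT = 13


class ProfileError(ValueError):
    """Invalid profile or scan input."""


@dataclass(frozen=True)
class SiteConstraint:
    """Constraint at one flanking position.

    ``allowed`` is a set of canonical residues, or ``None`` for a random
    (unconstrained) site.  A random site still has to hold *some* canonical
    residue; non-canonical characters never match.
    """

    position: str
    allowed: frozenset[str] | None

    def __post_init__(self) -> None:
        if self.position not in SITE_ORDER:
            raise ProfileError(f"unknown flank position {self.position!r}")
        if self.allowed is not None:
            allowed = frozenset(self.allowed)
            if not allowed or not allowed <= _CANONICAL_SET:
                raise ProfileError(
                    f"allowed set at {self.position} must be a nonempty subset "
                    f"of the 20 canonical residues, got {sorted(self.allowed)}"
                )
            object.__setattr__(self, "allowed", allowed)

    @property
    def is_random(self) -> bool:
        return self.allowed is None

    def admits(self, residue: str) -> bool:
        if residue not in _CANONICAL_SET:
            return False
        return self.allowed is None or residue in self.allowed


@dataclass(frozen=True)
class FlankingProfile:
    """One profile: a constraint per flanking site plus core length bounds."""

    profile_id: str
    constraints: tuple[SiteConstraint, ...]
    core_min: int = CORE_MIN_DEFAULT
    core_max: int = CORE_MAX_DEFAULT

    def __post_init__(self) -> None:
        if tuple(c.position for c in self.constraints) != SITE_ORDER:
            raise ProfileError(
                "profile must carry exactly one constraint per position "
                f"{SITE_ORDER}, in order"
            )
        if not (4 <= self.core_min <= self.core_max <= 13):
            raise ProfileError(
                f"core length bounds must satisfy 4 <= min <= max <= 13, "
                f"got [{self.core_min}, {self.core_max}]"
            )

    def constraint(self, position: str) -> SiteConstraint:
        return self.constraints[SITE_ORDER.index(position)]

    @property
    def n_specified(self) -> int:
        return sum(not c.is_random for c in self.constraints)

    @property
    def ic(self) -> float:
        """Information content in nats; see :func:`information_content`."""
        return information_content(self)

    def matches_string(self, s: str) -> bool:
        """True iff the *whole* string is one repeat unit under this profile."""
        return any(m.start == 0 and m.end == len(s)
                   for m in scan_sequence(s, self, mode="all"))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "profile_id": self.profile_id,
            "sites": {
                c.position: (sorted(c.allowed) if c.allowed is not None else "RANDOM")
                for c in self.constraints
            },
            "core_min": self.core_min,
            "core_max": self.core_max,
            "ic": self.ic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlankingProfile":
        constraints = tuple(
            SiteConstraint(
                pos,
                None if d["sites"][pos] == "RANDOM" else frozenset(d["sites"][pos]),
            )
            for pos in SITE_ORDER
        )
        return cls(str(d["profile_id"]), constraints,
                   d.get("core_min", CORE_MIN_DEFAULT),
                   d.get("core_max", CORE_MAX_DEFAULT))


def profiles_to_json(profiles: list[FlankingProfile]) -> str:
    return json.dumps([p.to_dict() for p in profiles], indent=1)


def profiles_from_json(text: str) -> list[FlankingProfile]:
    return [FlankingProfile.from_dict(d) for d in json.loads(text)]


@dataclass
class ProfileMatch:
    """A located repeat unit: five flanks plus the core, half-open coords."""

    protein_id: str
    start: int
    end: int
    core_start: int
    core_end: int
    core: str
    flank_residues: dict[str, str]
    profile_id: str

    @property
    def core_length(self) -> int:
        return self.core_end - self.core_start

    def validate(self, profile: FlankingProfile) -> None:
        """Self-check: the match must satisfy the profile it claims."""
        if self.end - self.start != 5 + self.core_length:
            raise ProfileError("match span must equal 5 flanks + core")
        if not profile.core_min <= self.core_length <= profile.core_max:
            raise ProfileError("core length outside profile bounds")
        for pos in SITE_ORDER:
            if not profile.constraint(pos).admits(self.flank_residues[pos]):
                raise ProfileError(f"flank residue at {pos} violates profile")


# ---------------------------------------------------------------------------
# Profile families


def information_content(profile: FlankingProfile) -> float:
    """Sum over specified sites of ln(20/|allowed|), in nats.

    Random sites and core positions contribute nothing: they impose no
    constraint relative to the uniform 20-residue background.
    """
    total = 0.0
    for c in profile.constraints:
        if c.allowed is not None:
            total += math.log(20.0 / len(c.allowed))
    return total


def _profile_from_random_sites(profile_id: str,
                               random_sites: frozenset[str]) -> FlankingProfile:
    constraints = tuple(
        SiteConstraint(pos, None if pos in random_sites else CANONICAL_SITE_SETS[pos])
        for pos in SITE_ORDER
    )
    return FlankingProfile(profile_id, constraints)


def build_canonical_profiles() -> list[FlankingProfile]:
    """The six profiles used for the Venn categorization.

    Profile 1 has all five sites specified; profiles 2-6 each relax exactly
    one site to random, in position order -2, -1, +1, +2, +3.
    """
    profiles = [_profile_from_random_sites("1", frozenset())]
    for i, pos in enumerate(SITE_ORDER, start=2):
        profiles.append(_profile_from_random_sites(str(i), frozenset({pos})))
    return profiles


def build_extended_profiles(min_specified: int = 2) -> list[FlankingProfile]:
    """Every specified/random assignment with >= ``min_specified`` specified sites.

    The default of 2 yields 2^5 - C(5,0) - C(5,1) = 26 profiles; the six
    canonical profiles come first and keep their ids.
    """
    if not 0 <= min_specified <= 5:
        raise ProfileError("min_specified must be between 0 and 5")
    assignments: list[frozenset[str]] = []
    for n_random in range(0, 5 - min_specified + 1):
        for combo in itertools.combinations(SITE_ORDER, n_random):
            assignments.append(frozenset(combo))
    return [
        _profile_from_random_sites(str(i), random_sites)
        for i, random_sites in enumerate(assignments, start=1)
    ]


# ---------------------------------------------------------------------------
# Scanning

_TABLE_CACHE: dict[frozenset[str] | None, np.ndarray] = {}


def _membership_table(allowed: frozenset[str] | None) -> np.ndarray:
    key = allowed
    table = _TABLE_CACHE.get(key)
    if table is None:
        table = np.zeros(256, dtype=bool)
        residues = CANONICAL_RESIDUES if allowed is None else "".join(allowed)
        for ch in residues:
            table[ord(ch)] = True
        _TABLE_CACHE[key] = table
    return table


def _all_hits(seq: str, profile: FlankingProfile) -> list[tuple[int, int]]:
    """All (start, core_length) pairs satisfying the profile (vectorized)."""
    n = len(seq)
    if n < profile.core_min + 5:
        return []
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    site_ok = {c.position: _membership_table(c.allowed)[arr]
               for c in profile.constraints}
    core_ok = _membership_table(None)[arr]
    ccum = np.concatenate(([0], np.cumsum(core_ok)))
    hits: list[tuple[int, int]] = []
    for core_len in range(profile.core_min, profile.core_max + 1):
        width = core_len + 5
        if n < width:
            break
        k = n - width + 1
        m = (
            site_ok["-2"][0:k]
            & site_ok["-1"][1:1 + k]
            & site_ok["+1"][2 + core_len:2 + core_len + k]
            & site_ok["+2"][3 + core_len:3 + core_len + k]
            & site_ok["+3"][4 + core_len:4 + core_len + k]
            & ((ccum[2 + core_len:2 + core_len + k] - ccum[2:2 + k]) == core_len)
        )
        hits.extend((int(s), core_len) for s in np.nonzero(m)[0])
    hits.sort()
    return hits


def _to_match(seq: str, start: int, core_len: int,
              profile: FlankingProfile, protein_id: str) -> ProfileMatch:
    core_start = start + 2
    core_end = core_start + core_len
    return ProfileMatch(
        protein_id=protein_id,
        start=start,
        end=core_end + 3,
        core_start=core_start,
        core_end=core_end,
        core=seq[core_start:core_end],
        flank_residues={
            "-2": seq[start],
            "-1": seq[start + 1],
            "+1": seq[core_end],
            "+2": seq[core_end + 1],
            "+3": seq[core_end + 2],
        },
        profile_id=profile.profile_id,
    )


def scan_sequence(seq: str, profile: FlankingProfile, mode: str = "canonical",
                  protein_id: str = "") -> list[ProfileMatch]:
    """Scan a protein sequence for repeat units matching a profile.

    mode="all" returns every (start, core length) combination that satisfies
    all site constraints.  mode="canonical" returns leftmost, longest-core,
    non-overlapping matches: at each leftmost feasible start the longest core
    is taken and scanning resumes after the match end.  Non-canonical residues
    never match anywhere (flanks or core).
    """
    if mode not in ("all", "canonical"):
        raise ProfileError(f"unknown scan mode {mode!r}")
    hits = _all_hits(seq, profile)
    if mode == "all":
        return [_to_match(seq, s, L, profile, protein_id) for s, L in hits]
    chosen: list[tuple[int, int]] = []
    cursor = 0
    best: tuple[int, int] | None = None
    for s, core_len in hits:
        if s < cursor:
            continue
        if best is None or s == best[0]:
            # hits are sorted by (start, core_len): keep the longest at this start
            best = (s, core_len)
            continue
        chosen.append(best)
        cursor = best[0] + best[1] + 5
        best = (s, core_len) if s >= cursor else None
    if best is not None:
        chosen.append(best)
    return [_to_match(seq, s, L, profile, protein_id) for s, L in chosen]
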