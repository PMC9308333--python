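"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized/library code paths:
the scanner oracle is a triple loop over (start, core length), the ORF
oracle tests every position as a start codon, the alignment oracle is a
memoized three-state affine DP, and the additive-matrix oracle generates
distances directly from a random tree structure.
"""

from __future__ import annotations

import functools

import numpy as np

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"


# --- profile scanning -------------------------------------------------------

def brute_force_hits(seq: str, sites: dict[str, frozenset | None],
                     core_min: int = 4, core_max: int = 13):
    """All (start, core_len) satisfying the five flank sets + canonical core."""
    def ok(ch, allowed):
        if ch not in CANONICAL:
            return False
        return allowed is None or ch in allowed

    hits = []
    n = len(seq)
    for start in range(n):
        for core_len in range(core_min, core_max + 1):
            end = start + core_len + 5
            if end > n:
                break
            if not ok(seq[start], sites["-2"]):
                continue
            if not ok(seq[start + 1], sites["-1"]):
                continue
            core = seq[start + 2:start + 2 + core_len]
            if any(c not in CANONICAL for c in core):
                continue
            if not ok(seq[start + 2 + core_len], sites["+1"]):
                continue
            if not ok(seq[start + 3 + core_len], sites["+2"]):
                continue
            if not ok(seq[start + 4 + core_len], sites["+3"]):
                continue
            hits.append((start, core_len))
    return sorted(hits)


def brute_force_canonical(seq, sites, core_min=4, core_max=13):
    """Leftmost, longest-core, non-overlapping selection from all hits."""
    hits = brute_force_hits(seq, sites, core_min, core_max)
    chosen = []
    cursor = 0
    while True:
        candidates = [h for h in hits if h[0] >= cursor]
        if not candidates:
            return chosen
        first = min(s for s, _ in candidates)
        best = max(l for s, l in candidates if s == first)
        chosen.append((first, best))
        cursor = first + best + 5


# --- ORFs --------------------------------------------------------------------

_CODONS = {}


def _codon_table():
    if not _CODONS:
        from Bio.Data import CodonTable

        _CODONS.update(CodonTable.unambiguous_dna_by_id[1].forward_table)
    return _CODONS


STOPS = {"TAA", "TAG", "TGA"}


def _revcomp(dna: str) -> str:
    return dna.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_force_orfs(dna: str, min_len: int = 1):
    """Every ATG on both strands, scanned forward codon by codon.

    Returns a set of (strand, nt_start, nt_end, peptide, partial) with
    forward-strand half-open coordinates.
    """
    table = _codon_table()
    out = set()
    n = len(dna)
    for strand in "+-":
        s = dna if strand == "+" else _revcomp(dna)
        for i in range(n - 2):
            if s[i:i + 3] != "ATG":
                continue
            pep = []
            j = i
            partial = True
            while j + 3 <= n:
                codon = s[j:j + 3]
                if codon in STOPS:
                    partial = False
                    break
                pep.append(table.get(codon, "X"))
                j += 3
            if partial:
                s_start, s_end = i, j
            else:
                s_start, s_end = i, j + 3
            peptide = "".join(pep)
            if len(peptide) < min_len:
                continue
            if strand == "+":
                coords = (s_start, s_end)
            else:
                coords = (n - s_end, n - s_start)
            out.add((strand, coords[0], coords[1], peptide, partial))
    return out


# --- alignment ---------------------------------------------------------------

def dp_global_score(a: str, b: str, matrix, gap_open: float,
                    gap_extend: float) -> float:
    """Affine-gap global alignment score by memoized three-state recursion.

    Gap of length k costs gap_open + (k-1)*gap_extend; terminal gaps count.
    States: 0 = match/mismatch, 1 = gap in a (consume b), 2 = gap in b.
    """
    neg = float("-inf")

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == 0 else neg
        best = neg
        if state == 0:
            if i > 0 and j > 0:
                sub = matrix[a[i - 1], b[j - 1]]
                best = max(rec(i - 1, j - 1, s) for s in (0, 1, 2)) + sub
        elif state == 1:  # gap in a: b[j-1] aligned to '-'
            if j > 0:
                best = max(
                    rec(i, j - 1, 1) - gap_extend,
                    max(rec(i, j - 1, 0), rec(i, j - 1, 2)) - gap_open,
                )
        else:  # gap in b
            if i > 0:
                best = max(
                    rec(i - 1, j, 2) - gap_extend,
                    max(rec(i - 1, j, 0), rec(i - 1, j, 1)) - gap_open,
                )
        return best

    result = max(rec(len(a), len(b), s) for s in (0, 1, 2))
    rec.cache_clear()
    return result


# --- random additive trees ---------------------------------------------------

def random_additive_matrix(n_leaves: int, rng: np.random.Generator):
    """Random binary tree -> exact leaf-to-leaf path-length matrix.

    The tree is built by repeatedly joining two random clusters with random
    positive branch lengths; distances are accumulated directly, never via
    the package's tree code.
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    # each cluster: dict leaf -> distance to cluster root
    clusters = [{lab: 0.0} for lab in labels]
    dist: dict[tuple[str, str], float] = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        li, lj = rng.uniform(0.05, 1.0, size=2)
        a, b = clusters[i], clusters[j]
        for la, da in a.items():
            for lb, db in b.items():
                key = tuple(sorted((la, lb)))
                dist[key] = da + li + db + lj
        merged = {k: v + li for k, v in a.items()}
        merged.update({k: v + lj for k, v in b.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    m = np.zeros((n_leaves, n_leaves))
    for x in range(n_leaves):
        for y in range(x + 1, n_leaves):
            m[x, y] = m[y, x] = dist[tuple(sorted((labels[x], labels[y])))]
    return labels, m
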