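"""Repeat-unit analysis: anchored alignment, logo matrices, category
comparison, and mature-peptide (orbitide) prediction.

Repeat units are aligned at their flanking anchor columns (-2, -1 | core |
+1, +2, +3) with variable-length cores left-justified and right-padded with
gaps.  Logo matrices hold per-column residue frequencies over non-gap
residues and the per-column information content in bits, IC = log2(20) - H.

Orbitide prediction maps a matched repeat to its candidate mature cycle: the
core itself, plus a glycine-appended variant when the -1 residue is G (the
alternative cleavage between the -2 aspartate and the -1 glycine observed for
the G-appended linusorb analogues).  The head-to-tail cyclic monoisotopic
mass is the sum of residue masses with no terminal water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pyteomics import mass as _pmass

from .profiles import CANONICAL_RESIDUES, ProfileMatch, SITE_ORDER

GAP = "-"
LOG2_20 = math.log2(20)

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}


class RepeatAnalysisError(ValueError):
    pass


@dataclass
class AnchoredAlignment:
    """Rows of equal length with the anchor map of flank/core columns.

    ``anchor_map`` maps "-2", "-1", "+1", "+2", "+3" to column indices and
    "core" to the half-open column span of the core block.
    """

    ids: list[str]
    rows: list[str]
    anchor_map: dict[str, object]

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def core_span(self) -> tuple[int, int]:
        return self.anchor_map["core"]


def anchor_align(matches: list[ProfileMatch]) -> AnchoredAlignment:
    """Align repeat units on their flank anchors.

    Cores are left-justified in the core block and right-padded with gaps to
    the longest core; flank columns are gap-free by construction.
    """
    if not matches:
        raise RepeatAnalysisError("anchor_align requires at least one match")
    core_width = max(m.core_length for m in matches)
    rows, ids = [], []
    for i, m in enumerate(matches):
        row = (m.flank_residues["-2"] + m.flank_residues["-1"]
               + m.core + GAP * (core_width - m.core_length)
               + m.flank_residues["+1"] + m.flank_residues["+2"]
               + m.flank_residues["+3"])
        rows.append(row)
        ids.append(m.protein_id or f"match{i + 1}")
    anchor_map = {
        "-2": 0,
        "-1": 1,
        "core": (2, 2 + core_width),
        "+1": 2 + core_width,
        "+2": 3 + core_width,
        "+3": 4 + core_width,
    }
    return AnchoredAlignment(ids, rows, anchor_map)


@dataclass
class LogoMatrix:
    """Per-column residue frequencies (gaps excluded) and IC in bits."""

    freqs: np.ndarray  # (width, 20); rows of empty columns are all-zero
    ic: np.ndarray  # (width,); NaN where the column is all-gap
    empty: np.ndarray  # (width,) bool
    anchor_map: dict[str, object]

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def core_span(self) -> tuple[int, int]:
        return self.anchor_map["core"]

    def column_frequencies(self, col: int) -> dict[str, float]:
        return {aa: float(self.freqs[col, i])
                for aa, i in _AA_INDEX.items() if self.freqs[col, i] > 0}


def logo_matrix(alignment: AnchoredAlignment,
                small_sample_correction: bool = False) -> LogoMatrix:
    """Column frequencies and information content of an anchored alignment.

    IC = log2(20) - H in bits, computed over non-gap residues.  The optional
    small-sample correction subtracts the WebLogo-style bias term
    (20 - 1) / (2 * ln 2 * n) per column.
    """
    width = alignment.width
    freqs = np.zeros((width, 20))
    ic = np.full(width, np.nan)
    empty = np.zeros(width, dtype=bool)
    for j in range(width):
        column = [r[j] for r in alignment.rows if r[j] != GAP]
        if not column:
            empty[j] = True
            continue
        for ch in column:
            freqs[j, _AA_INDEX[ch]] += 1
        freqs[j] /= len(column)
        p = freqs[j][freqs[j] > 0]
        entropy = float(-(p * np.log2(p)).sum())
        value = LOG2_20 - entropy
        if small_sample_correction:
            value -= (20 - 1) / (2 * math.log(2) * len(column))
        ic[j] = max(value, 0.0)
    return LogoMatrix(freqs, ic, empty, dict(alignment.anchor_map))


@dataclass
class AnchorComparison:
    position: str
    dominant_a: str
    freq_a: float
    dominant_b: str
    freq_b: float
    difference: float  # max over residues of |freq_a - freq_b|


def compare_categories(logo_a: LogoMatrix, logo_b: LogoMatrix
                       ) -> tuple[list[AnchorComparison], dict[str, float]]:
    """Per-anchor-column comparison of two repeat categories.

    For each flank column: the dominant residue and its frequency on each
    side (ties broken alphabetically) and the largest absolute per-residue
    frequency difference.  The core block is summarized separately by its
    mean per-column largest difference (over columns defined in both logos).
    """
    if logo_a.anchor_map != logo_b.anchor_map:
        raise RepeatAnalysisError("logos have mismatched anchor structure")
    report = []
    for pos in SITE_ORDER:
        col = logo_a.anchor_map[pos]
        fa, fb = logo_a.freqs[col], logo_b.freqs[col]
        report.append(AnchorComparison(
            position=pos,
            dominant_a=CANONICAL_RESIDUES[int(np.argmax(fa))],
            freq_a=float(fa.max()),
            dominant_b=CANONICAL_RESIDUES[int(np.argmax(fb))],
            freq_b=float(fb.max()),
            difference=float(np.abs(fa - fb).max()),
        ))
    lo, hi = logo_a.core_span
    diffs = [float(np.abs(logo_a.freqs[j] - logo_b.freqs[j]).max())
             for j in range(lo, hi)
             if not (logo_a.empty[j] or logo_b.empty[j])]
    core_summary = {
        "n_columns": float(hi - lo),
        "mean_difference": float(np.mean(diffs)) if diffs else float("nan"),
    }
    return report, core_summary


def _monoisotopic_residue_mass(aa: str) -> float:
    return _pmass.std_aa_mass[aa]


def canonical_rotation(core: str) -> str:
    """Lexicographically smallest rotation (head-to-tail cycles are rotationally
    equivalent, so this gives a unique representative)."""
    if not core:
        raise RepeatAnalysisError("empty core")
    return min(core[i:] + core[:i] for i in range(len(core)))


def cyclic_monoisotopic_mass(core: str) -> float:
    """Monoisotopic mass of the head-to-tail cycle: sum of residue masses,
    no terminal water (the cyclizing amide bond consumes it)."""
    return sum(_monoisotopic_residue_mass(aa) for aa in core)


@dataclass
class OrbitideCandidate:
    core: str
    variants: set[str]
    canonical_rotation: str
    monoisotopic_mass: float


def predict_orbitide(match: ProfileMatch) -> OrbitideCandidate:
    """Candidate mature peptide(s) for one matched repeat.

    Variants are the core itself plus the glycine-appended form iff the -1
    residue is G; the canonical rotation and the cyclic mass are computed on
    the primary core.
    """
    variants = {match.core}
    if match.flank_residues["-1"] == "G":
        variants.add("G" + match.core)
    return OrbitideCandidate(
        core=match.core,
        variants=variants,
        canonical_rotation=canonical_rotation(match.core),
        monoisotopic_mass=cyclic_monoisotopic_mass(match.core),
    )
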