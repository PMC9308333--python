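"""Iterative profile search with a PSSM and empirical E-values.

A position-specific scoring matrix is built from an alignment of repeat units
(log-odds with pseudocounts against a background distribution) and slid over
each protein as a fixed-width ungapped window; the best window per protein is
the hit.  Significance is judged against an empirical null: each of
``n_shuffles`` replicates draws a full surrogate database (one i.i.d. sequence
per database entry, residues from the database composition, lengths equal to
the database lengths) and records the database-wide best window score, so

    E(s) = #{null replicates with best >= s} / n_shuffles * database_size

estimates how many database-best scores as good as ``s`` arise by chance.
Hits below the E-value threshold are appended to the alignment at their best
window (ungapped) and the search iterates until no new proteins are accepted,
mirroring PSI-BLAST/HMMER iteration logic without their internal statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mining import ProteinRecord
from .profiles import CANONICAL_RESIDUES

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}
GAP = "-"


class SearchInputError(ValueError):
    pass


@dataclass
class RepeatAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise SearchInputError("alignment needs >= 2 rows")
        if len(self.ids) != len(self.rows):
            raise SearchInputError("one id per row required")
        if len({len(r) for r in self.rows}) != 1:
            raise SearchInputError("alignment rows must have equal length")
        bad = set("".join(self.rows)) - set(CANONICAL_RESIDUES) - {GAP}
        if bad:
            raise SearchInputError(f"non-canonical characters in alignment: {sorted(bad)}")


@dataclass
class PSSM:
    """Per-column log-odds scores over the 20 canonical residues (nats)."""

    scores: np.ndarray  # (width, 20)
    background: np.ndarray  # (20,)
    alpha: float
    columns: list[int] = field(default_factory=list)  # source alignment columns

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())


@dataclass
class SearchHit:
    protein_id: str
    start: int
    end: int
    score: float
    evalue: float | None = None
    round: int | None = None


def build_pssm(alignment: RepeatAlignment, alpha: float = 1.0,
               background: np.ndarray | None = None) -> PSSM:
    """Log-odds PSSM with pseudocounts.

    Column probabilities are p(a) = (count(a) + alpha*b(a)) / (n_ungapped +
    alpha) and scores ln(p(a)/b(a)); columns containing only gaps are dropped.
    """
    if alpha <= 0:
        raise SearchInputError("alpha must be > 0")
    if background is None:
        background = np.full(20, 0.05)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or abs(background.sum() - 1.0) > 1e-9:
        raise SearchInputError("background must be 20 probabilities summing to 1")
    rows = alignment.rows
    width = len(rows[0])
    counts = np.zeros((width, 20))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                counts[j, _AA_INDEX[ch]] += 1
    n_ungapped = counts.sum(axis=1)
    keep = n_ungapped > 0
    counts, n_ungapped = counts[keep], n_ungapped[keep]
    p = (counts + alpha * background) / (n_ungapped + alpha)[:, None]
    scores = np.log(p / background)
    return PSSM(scores, background, alpha, columns=list(np.nonzero(keep)[0]))


_LOW = -1e18  # sentinel score for padding / non-canonical residues


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    lut = np.full(256, 20, dtype=np.int64)
    for aa, i in _AA_INDEX.items():
        lut[ord(aa)] = i
    return lut[arr]


def _extended_scores(pssm: PSSM) -> np.ndarray:
    """Scores with a 21st column of a large negative sentinel."""
    return np.hstack([pssm.scores, np.full((pssm.width, 1), _LOW)])


def _window_scores_matrix(sx: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Window scores for encoded sequences stacked as rows (padded with 20)."""
    w = sx.shape[0]
    n_windows = x.shape[1] - w + 1
    acc = np.zeros((x.shape[0], n_windows))
    for c in range(w):
        acc += sx[c][x[:, c:c + n_windows]]
    return acc


def score_windows(pssm: PSSM, protein: ProteinRecord
                  ) -> tuple[np.ndarray, SearchHit]:
    """All L - w + 1 window scores plus the best hit (ties -> smallest start)."""
    if len(protein.sequence) < pssm.width:
        raise SearchInputError(
            f"protein {protein.protein_id!r} shorter than PSSM width")
    x = _encode(protein.sequence)[None, :]
    scores = _window_scores_matrix(_extended_scores(pssm), x)[0]
    best = int(np.argmax(scores))
    hit = SearchHit(protein.protein_id, best, best + pssm.width,
                    float(scores[best]))
    return scores, hit


@dataclass
class NullProteomeModel:
    """Composition + length model of a database, for the shuffle null."""

    freqs: np.ndarray  # (20,)
    lengths: np.ndarray  # database sequence lengths
    database_size: int

    @classmethod
    def from_proteome(cls, proteome: list[ProteinRecord]) -> "NullProteomeModel":
        counts = np.zeros(20)
        lengths = []
        for p in proteome:
            x = _encode(p.sequence)
            counts += np.bincount(x[x < 20], minlength=20)
            lengths.append(len(p.sequence))
        if counts.sum() == 0:
            raise SearchInputError("empty proteome")
        return cls(counts / counts.sum(), np.array(lengths), len(proteome))


def sample_null_scores(pssm: PSSM, null_model: NullProteomeModel,
                       n_shuffles: int, rng: np.random.Generator) -> np.ndarray:
    """Database-wide best window score for each of ``n_shuffles`` null databases."""
    w = pssm.width
    lengths = null_model.lengths[null_model.lengths >= w]
    if lengths.size == 0:
        raise SearchInputError("no database sequence reaches the PSSM width")
    m = lengths.size
    lmax = int(lengths.max())
    sx = _extended_scores(pssm)
    null = np.empty(n_shuffles)
    # replicate in blocks to bound memory
    block = max(1, int(2_000_000 // max(1, m * lmax)))
    done = 0
    while done < n_shuffles:
        b = min(block, n_shuffles - done)
        x = rng.choice(20, size=(b * m, lmax), p=null_model.freqs)
        pad = np.arange(lmax)[None, :] >= np.tile(lengths, b)[:, None]
        x[pad] = 20
        best = _window_scores_matrix(sx, x).max(axis=1)
        null[done:done + b] = best.reshape(b, m).max(axis=1)
        done += b
    return null


def empirical_evalue(score: float, pssm: PSSM,
                     null_model: NullProteomeModel,
                     n_shuffles: int = 1000, seed: int = 0,
                     null_scores: np.ndarray | None = None) -> float:
    """Empirical E-value of a window score against the shuffle null.

    Deterministic for a fixed seed.  ``null_scores`` may be supplied to reuse
    a precomputed null distribution (as the iterative search does per round).
    """
    if null_scores is None:
        if n_shuffles < 100:
            raise SearchInputError("n_shuffles must be >= 100")
        rng = np.random.default_rng(seed)
        null_scores = sample_null_scores(pssm, null_model, n_shuffles, rng)
    n = len(null_scores)
    return float((null_scores >= score).sum()) / n * null_model.database_size


@dataclass
class RoundLog:
    round: int
    n_new: int
    n_accepted_total: int
    pssm_width: int


@dataclass
class IterativeSearchResult:
    hits: dict[str, SearchHit]
    rounds: list[RoundLog]
    alignment: RepeatAlignment


def _degap_all_gap_columns(rows: list[str]) -> list[str]:
    width = len(rows[0])
    keep = [j for j in range(width) if any(r[j] != GAP for r in rows)]
    return ["".join(r[j] for j in keep) for r in rows]


def iterate_search(seed_alignment: RepeatAlignment,
                   proteome: list[ProteinRecord],
                   e_threshold: float = 0.01,
                   max_rounds: int = 10,
                   alpha: float = 1.0,
                   n_shuffles: int = 1000,
                   seed: int = 0,
                   background: np.ndarray | None = None
                   ) -> IterativeSearchResult:
    """Iterate PSSM search to convergence.

    Each round rebuilds the PSSM from the current alignment, scores the
    proteome, accepts new proteins with E < ``e_threshold``, and appends their
    best windows (ungapped, at the PSSM coordinates) to the alignment.  Stops
    when a round adds nothing or ``max_rounds`` is reached; the accepted set
    is monotonically non-decreasing across rounds.
    """
    if max_rounds < 1:
        raise SearchInputError("max_rounds must be >= 1")
    if n_shuffles < 100:
        raise SearchInputError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    null_model = NullProteomeModel.from_proteome(proteome)
    rows = _degap_all_gap_columns(list(seed_alignment.rows))
    ids = list(seed_alignment.ids)
    accepted: dict[str, SearchHit] = {}
    rounds: list[RoundLog] = []
    for rnd in range(1, max_rounds + 1):
        aln = RepeatAlignment(ids, rows)
        pssm = build_pssm(aln, alpha=alpha, background=background)
        null = sample_null_scores(pssm, null_model, n_shuffles, rng)
        new_hits: list[SearchHit] = []
        for protein in proteome:
            if protein.protein_id in accepted:
                continue
            if len(protein.sequence) < pssm.width:
                continue
            _, best = score_windows(pssm, protein)
            best.evalue = empirical_evalue(best.score, pssm, null_model,
                                           null_scores=null)
            if best.evalue < e_threshold:
                best.round = rnd
                new_hits.append(best)
        for hit in new_hits:
            accepted[hit.protein_id] = hit
        rounds.append(RoundLog(rnd, len(new_hits), len(accepted), pssm.width))
        if not new_hits:
            break
        by_id = {p.protein_id: p for p in proteome}
        for hit in new_hits:
            window = by_id[hit.protein_id].sequence[hit.start:hit.end]
            rows.append(window)
            ids.append(hit.protein_id)
    return IterativeSearchResult(accepted, rounds,
                                 RepeatAlignment(ids, rows))
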