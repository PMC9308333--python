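"""Synthetic proteome/genome generator with planted repeat proteins.

The generator emulates the study system: a proteome of background proteins
plus a handful of precursor-like proteins carrying tandem repeats, each repeat
a hypervariable 4-13 residue core flanked by the five conserved signature
sites.  Optionally the proteins are encoded as single-exon genes (ATG .. stop)
embedded in random intergenic DNA, so the six-frame ORF extractor can be
exercised end to end.  A machine-readable truth table records every planted
repeat, which makes recall/precision of the mining pipeline measurable.

Planted proteins are rejection-sampled (seeded, bounded retries) so that a
canonical scan with the planting profile yields exactly the uncorrupted
planted matches; spacers and cores therefore never blur the truth coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mining import ProteinRecord
from .profiles import (
    CANONICAL_RESIDUES,
    FlankingProfile,
    SITE_ORDER,
    build_extended_profiles,
    scan_sequence,
)

_RESIDUES = np.frombuffer(CANONICAL_RESIDUES.encode(), dtype=np.uint8)

_SYNONYMS: dict[str, list[str]] = {}


def _codon_synonyms() -> dict[str, list[str]]:
    if not _SYNONYMS:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        for codon, aa in sorted(table.forward_table.items()):
            _SYNONYMS.setdefault(aa, []).append(codon)
    return _SYNONYMS


class SyntheticSpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic proteome/genome.

    Defaults describe a desk-scale stand-in for the study conditions: a few
    hundred background proteins, a handful of planted repeat proteins with
    3-8 repeats each (the real repeat proteins carry 3 to ~26), cores uniform
    over the full 4-13 length window the profiles allow, and short spacers so
    the repeats are tandem.
    """

    seed: int = 0
    n_background: int = 200
    bg_length_range: tuple[int, int] = (100, 400)
    bg_freqs: dict[str, float] | None = None  # None -> uniform over 20 residues
    n_lldr: int = 5
    repeats_per_protein: tuple[int, int] = (3, 8)
    core_length_dist: dict[int, float] | None = None  # None -> uniform on 4..13
    profile_id: str = "1"
    spacer_length_range: tuple[int, int] = (3, 15)
    repeat_divergence: float = 0.15
    corruption_rate: float = 0.0
    genome_mode: bool = False
    intergenic_length_range: tuple[int, int] = (50, 300)
    leader_length_range: tuple[int, int] = (20, 60)

    def validate(self) -> None:
        for name in ("n_background", "n_lldr"):
            if getattr(self, name) < 0:
                raise SyntheticSpecError(f"{name} must be >= 0")
        for name in ("bg_length_range", "repeats_per_protein",
                     "spacer_length_range", "intergenic_length_range",
                     "leader_length_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise SyntheticSpecError(f"{name} must satisfy 0 < min <= max")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise SyntheticSpecError("corruption_rate must be in [0, 1]")
        if not 0.0 <= self.repeat_divergence <= 1.0:
            raise SyntheticSpecError("repeat_divergence must be in [0, 1]")
        if self.bg_freqs is not None:
            vals = np.array([self.bg_freqs.get(a, 0.0) for a in CANONICAL_RESIDUES])
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise SyntheticSpecError(
                    "bg_freqs must be nonnegative and sum to 1 over the 20 residues")
        if self.core_length_dist is not None:
            if any(not 4 <= k <= 13 for k in self.core_length_dist):
                raise SyntheticSpecError("core_length_dist supported on [4, 13] only")
            vals = np.array(list(self.core_length_dist.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise SyntheticSpecError("core_length_dist must sum to 1")
        if self.profile_id not in {p.profile_id for p in build_extended_profiles(0)}:
            raise SyntheticSpecError(f"unknown profile_id {self.profile_id!r}")

    def _bg_probs(self) -> np.ndarray:
        if self.bg_freqs is None:
            return np.full(20, 0.05)
        return np.array([self.bg_freqs.get(a, 0.0) for a in CANONICAL_RESIDUES])

    def _core_lengths(self) -> tuple[np.ndarray, np.ndarray]:
        if self.core_length_dist is None:
            lengths = np.arange(4, 14)
            return lengths, np.full(10, 0.1)
        items = sorted(self.core_length_dist.items())
        return (np.array([k for k, _ in items]),
                np.array([v for _, v in items], dtype=float))

    def target_profile(self) -> FlankingProfile:
        for p in build_extended_profiles(0):
            if p.profile_id == self.profile_id:
                return p
        raise SyntheticSpecError(f"unknown profile_id {self.profile_id!r}")


@dataclass
class TruthRecord:
    protein_id: str
    is_lldr: bool
    planted_matches: list[tuple[int, int, str]] = field(default_factory=list)
    corrupted_sites: list[tuple[int, str]] = field(default_factory=list)

    def uncorrupted_matches(self) -> list[tuple[int, int, str]]:
        bad = {i for i, _ in self.corrupted_sites}
        return [m for i, m in enumerate(self.planted_matches) if i not in bad]


@dataclass
class GeneRecord:
    protein_id: str
    contig_id: str
    strand: str
    nt_start: int
    nt_end: int  # half-open, includes stop codon


def _random_residues(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    if n <= 0:
        return ""
    return bytes(rng.choice(_RESIDUES, size=n, p=probs)).decode()


def _mutate(rng: np.random.Generator, template: str, rate: float,
            probs: np.ndarray) -> str:
    """Substitute each residue with probability ``rate`` (draw from background)."""
    if rate <= 0 or not template:
        return template
    chars = list(template)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = _random_residues(rng, 1, probs)
    return "".join(chars)


def _build_repeat(rng: np.random.Generator, profile: FlankingProfile,
                  spec: SyntheticSpec, template_core: str,
                  template_flanks: dict[str, str],
                  ) -> tuple[str, str, list[str]]:
    """One repeat unit derived from the protein's template.

    Tandem repeats within one precursor arise from duplication, so copies
    share a per-protein template core/flanks and diverge at
    ``spec.repeat_divergence`` per residue; cores stay hypervariable across
    proteins.  Returns (unit, core, corrupted site labels).
    """
    lengths, probs = spec._core_lengths()
    core_len = int(rng.choice(lengths, p=probs))
    bg = spec._bg_probs()
    core = _mutate(rng, template_core[:core_len], spec.repeat_divergence, bg)
    flanks: dict[str, str] = {}
    corrupted: list[str] = []
    for pos in SITE_ORDER:
        constraint = profile.constraint(pos)
        if constraint.is_random:
            flanks[pos] = _mutate(rng, template_flanks[pos],
                                  spec.repeat_divergence, bg)
        else:
            flanks[pos] = template_flanks[pos]
            if spec.corruption_rate > 0 and rng.random() < spec.corruption_rate:
                disallowed = sorted(set(CANONICAL_RESIDUES) - constraint.allowed)
                flanks[pos] = disallowed[int(rng.integers(len(disallowed)))]
                corrupted.append(pos)
    unit = flanks["-2"] + flanks["-1"] + core + flanks["+1"] + flanks["+2"] + flanks["+3"]
    return unit, core, corrupted


def _build_planted_protein(rng: np.random.Generator, spec: SyntheticSpec,
                           protein_id: str,
                           max_retries: int = 200) -> tuple[ProteinRecord, TruthRecord]:
    profile = spec.target_profile()
    bg = spec._bg_probs()
    lo, hi = spec.repeats_per_protein
    n_repeats = int(rng.integers(lo, hi + 1))
    for _ in range(max_retries):
        # per-protein templates: repeats are diverged copies of one unit
        template_core = _random_residues(rng, profile.core_max, bg)
        template_flanks: dict[str, str] = {}
        for pos in SITE_ORDER:
            constraint = profile.constraint(pos)
            if constraint.is_random:
                template_flanks[pos] = _random_residues(rng, 1, bg)
            else:
                allowed = sorted(constraint.allowed)
                template_flanks[pos] = allowed[int(rng.integers(len(allowed)))]
        spacer_len = int(rng.integers(*spec.spacer_length_range, endpoint=True))
        template_spacer = _random_residues(rng, spacer_len, bg)

        leader_len = int(rng.integers(*spec.leader_length_range, endpoint=True))
        parts = ["M" + _random_residues(rng, leader_len - 1, bg)]
        planted: list[tuple[int, int, str]] = []
        corrupted_sites: list[tuple[int, str]] = []
        pos = leader_len
        for i in range(n_repeats):
            unit, core, corrupted = _build_repeat(rng, profile, spec,
                                                  template_core, template_flanks)
            parts.append(unit)
            planted.append((pos, pos + len(unit), core))
            corrupted_sites.extend((i, label) for label in corrupted)
            pos += len(unit)
            spacer = _mutate(rng, template_spacer, spec.repeat_divergence, bg)
            parts.append(spacer)
            pos += len(spacer)
        seq = "".join(parts)
        truth = TruthRecord(protein_id, True, planted, corrupted_sites)
        expected = {(s, e) for s, e, _ in truth.uncorrupted_matches()}
        observed = {(m.start, m.end)
                    for m in scan_sequence(seq, profile, mode="canonical")}
        if observed == expected:
            return ProteinRecord(protein_id, "planted repeat protein", seq), truth
    raise RuntimeError(
        f"could not assemble a clean planted protein after {max_retries} retries")


def generate_proteome(spec: SyntheticSpec
                      ) -> tuple[list[ProteinRecord], list[TruthRecord]]:
    """Generate the synthetic proteome and its truth table.

    Deterministic for a fixed ``spec.seed``.  Every planted, uncorrupted
    repeat satisfies the target profile at exactly the truth coordinates
    under the canonical scan.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg = spec._bg_probs()
    proteins: list[ProteinRecord] = []
    truth: list[TruthRecord] = []
    for i in range(spec.n_lldr):
        pid = f"LLDR{i + 1:03d}"
        record, t = _build_planted_protein(rng, spec, pid)
        proteins.append(record)
        truth.append(t)
    for i in range(spec.n_background):
        pid = f"BG{i + 1:04d}"
        length = int(rng.integers(*spec.bg_length_range, endpoint=True))
        seq = "M" + _random_residues(rng, length - 1, bg)
        proteins.append(ProteinRecord(pid, "background protein", seq))
        truth.append(TruthRecord(pid, False))
    return proteins, truth


_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(rng.choice(_NT, size=n)).decode()


def _encode_protein(rng: np.random.Generator, seq: str) -> str:
    synonyms = _codon_synonyms()
    codons = [synonyms[aa][int(rng.integers(len(synonyms[aa])))] for aa in seq]
    stops = ["TAA", "TAG", "TGA"]
    codons.append(stops[int(rng.integers(3))])
    return "".join(codons)


def _intergenic_is_clean(dna: str, repeat_strings: list[str]) -> bool:
    """No in-frame planted repeat strings in any translation of the segment."""
    from .orfs import translate_codon
    from Bio.Seq import reverse_complement

    if not repeat_strings:
        return True
    for strand_seq in (dna, reverse_complement(dna)):
        for offset in range(3):
            pep = "".join(
                translate_codon(strand_seq[i:i + 3])
                for i in range(offset, len(strand_seq) - 2, 3)
            )
            if any(r in pep for r in repeat_strings):
                return False
    return True


@dataclass
class SyntheticGenome:
    contigs: list[tuple[str, str]]
    genes: list[GeneRecord]
    proteins: list[ProteinRecord]
    truth: list[TruthRecord]


def generate_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Encode the synthetic proteome as single-exon genes in intergenic DNA.

    Each protein becomes ATG .. stop in one reading frame (codons drawn
    uniformly over synonyms), reverse-complemented with probability 0.5, on a
    single contig.  Intergenic segments are verified by construction check to
    contain no in-frame planted repeat strings.
    """
    spec.validate()
    if not spec.genome_mode:
        raise SyntheticSpecError("genome_mode must be set for generate_genome")
    proteins, truth = generate_proteome(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    repeat_strings = [
        prot.sequence[s:e]
        for prot, t_rec in zip(proteins, truth) if t_rec.is_lldr
        for s, e, _ in t_rec.planted_matches
    ]
    contig_id = "synth_contig_1"
    parts: list[str] = []
    genes: list[GeneRecord] = []
    pos = 0

    def intergenic() -> str:
        n = int(rng.integers(*spec.intergenic_length_range, endpoint=True))
        for _ in range(50):
            seg = _random_dna(rng, n)
            if _intergenic_is_clean(seg, repeat_strings):
                return seg
        raise RuntimeError("could not draw clean intergenic DNA")

    for prot in proteins:
        seg = intergenic()
        parts.append(seg)
        pos += len(seg)
        gene = _encode_protein(rng, prot.sequence)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            from Bio.Seq import reverse_complement

            gene = reverse_complement(gene)
        genes.append(GeneRecord(prot.protein_id, contig_id, strand,
                                pos, pos + len(gene)))
        parts.append(gene)
        pos += len(gene)
    parts.append(intergenic())
    return SyntheticGenome([(contig_id, "".join(parts))], genes, proteins, truth)
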