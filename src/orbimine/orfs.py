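"""Virtual ORF library construction by six-frame translation.

A virtual ORF is a fragment that starts at a start codon (ATG) and runs to
the first in-frame stop codon, with no gene model: every ATG on both strands
yields one ORF, so nested starts produce nested ORFs.  This mirrors how short
or unusually structured precursor genes (e.g. single-exon cyclic-peptide
precursors) can be recovered even when gene-calling pipelines miss them.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard code; plant nuclear genome
STOP_CODONS = frozenset(_TABLE.stop_codons)
START_CODON = "ATG"
_FORWARD = dict(_TABLE.forward_table)

VALID_NUCLEOTIDES = frozenset("ACGTN")


class ORFInputError(ValueError):
    pass


def translate_codon(codon: str) -> str:
    """Translate one codon; codons containing N translate to 'X'."""
    return _FORWARD.get(codon, "X")


@dataclass
class ORFRecord:
    """One virtual ORF.

    Coordinates are 0-based half-open on the *forward* strand regardless of
    ORF strand; for non-partial ORFs the span includes the stop codon.
    ``frame`` is 1..3 on the ORF's own strand.
    """

    contig_id: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    peptide: str
    partial: bool

    @property
    def header(self) -> str:
        return (f"{self.contig_id}|{self.strand}|{self.frame}"
                f"|{self.nt_start}-{self.nt_end}|"
                f"{'partial' if self.partial else 'complete'}")


def six_frame_orfs(dna: str, min_len: int = 10,
                   contig_id: str = "contig") -> list[ORFRecord]:
    """Extract every ORF from all six frames of ``dna``.

    Every ATG in every frame on both strands yields one record whose ORF runs
    to the first in-frame stop codon, or to the sequence end with
    ``partial=True`` when no stop is reached.  The stop codon is excluded from
    the peptide.  Records with peptide length < ``min_len`` are dropped.
    Codons containing N translate to 'X' and never act as start or stop.
    """
    if min_len < 1:
        raise ORFInputError("min_len must be >= 1")
    dna = dna.upper()
    bad = set(dna) - VALID_NUCLEOTIDES
    if bad:
        raise ORFInputError(f"invalid nucleotide characters: {sorted(bad)}")
    n = len(dna)
    records: list[ORFRecord] = []
    for strand in "+-":
        seq = dna if strand == "+" else reverse_complement(dna)
        for offset in range(3):
            ncod = (n - offset) // 3
            if ncod <= 0:
                continue
            codons = [seq[offset + 3 * i: offset + 3 * i + 3] for i in range(ncod)]
            stop_idx = [i for i, c in enumerate(codons) if c in STOP_CODONS]
            for j, codon in enumerate(codons):
                if codon != START_CODON:
                    continue
                stop = next((k for k in stop_idx if k >= j), None)
                if stop is None:
                    pep_codons = codons[j:]
                    partial = True
                    s_start, s_end = offset + 3 * j, offset + 3 * ncod
                else:
                    pep_codons = codons[j:stop]
                    partial = False
                    s_start, s_end = offset + 3 * j, offset + 3 * (stop + 1)
                peptide = "".join(translate_codon(c) for c in pep_codons)
                if len(peptide) < min_len:
                    continue
                if strand == "+":
                    nt_start, nt_end = s_start, s_end
                else:
                    nt_start, nt_end = n - s_end, n - s_start
                records.append(ORFRecord(contig_id, strand, offset + 1,
                                         nt_start, nt_end, peptide, partial))
    records.sort(key=lambda r: (r.strand, r.frame, r.nt_start, r.nt_end))
    return records


def six_frame_orfs_fasta(records: list[tuple[str, str]],
                         min_len: int = 10) -> list[ORFRecord]:
    """Run :func:`six_frame_orfs` over (contig_id, dna) records."""
    out: list[ORFRecord] = []
    for contig_id, dna in records:
        out.extend(six_frame_orfs(dna, min_len=min_len, contig_id=contig_id))
    return out
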