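"""FASTA and tabular input/output helpers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mining import LLDRCall, Pool, ProteinRecord
from .orfs import ORFRecord
from .synthetic import GeneRecord, TruthRecord


def read_protein_fasta(path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, rec.description, str(rec.seq)))
    return records


def read_dna_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: list[tuple[str, str]],
                descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    seq_records = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_protein_fasta(path, proteins: list[ProteinRecord]) -> None:
    write_fasta(path, [(p.protein_id, p.sequence) for p in proteins],
                {p.protein_id: p.description for p in proteins})


def write_truth_table(path, truth: list[TruthRecord],
                      profile_id: str = "") -> None:
    rows = []
    for t in truth:
        if t.planted_matches:
            corrupted = {i for i, _ in t.corrupted_sites}
            for i, (start, end, core) in enumerate(t.planted_matches):
                rows.append({
                    "protein_id": t.protein_id,
                    "is_lldr": int(t.is_lldr),
                    "start": start,
                    "end": end,
                    "core": core,
                    "profile_id": profile_id,
                    "corrupted": int(i in corrupted),
                })
        else:
            rows.append({"protein_id": t.protein_id, "is_lldr": int(t.is_lldr),
                         "start": "", "end": "", "core": "",
                         "profile_id": "", "corrupted": ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_orf_records(fasta_path, tsv_path, records: list[ORFRecord]) -> None:
    write_fasta(fasta_path, [(r.header, r.peptide) for r in records])
    pd.DataFrame([{
        "contig_id": r.contig_id, "strand": r.strand, "frame": r.frame,
        "nt_start": r.nt_start, "nt_end": r.nt_end,
        "length_aa": len(r.peptide), "partial": int(r.partial),
    } for r in records]).to_csv(tsv_path, sep="\t", index=False)


def write_gene_table(path, genes: list[GeneRecord]) -> None:
    pd.DataFrame([{
        "protein_id": g.protein_id, "contig_id": g.contig_id,
        "strand": g.strand, "nt_start": g.nt_start, "nt_end": g.nt_end,
    } for g in genes]).to_csv(path, sep="\t", index=False)


def matches_table(pool: Pool) -> pd.DataFrame:
    rows = []
    for protein_id in sorted(pool):
        for profile_id, matches in sorted(pool[protein_id].items()):
            for m in matches:
                rows.append({
                    "protein_id": protein_id, "profile_id": profile_id,
                    "start": m.start, "end": m.end, "core": m.core,
                    "flank_-2": m.flank_residues["-2"],
                    "flank_-1": m.flank_residues["-1"],
                    "flank_+1": m.flank_residues["+1"],
                    "flank_+2": m.flank_residues["+2"],
                    "flank_+3": m.flank_residues["+3"],
                })
    return pd.DataFrame(rows)


def calls_table(calls: list[LLDRCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "protein_id": c.protein_id,
        "n_matches": len(c.matches),
        "repeat_confirmed": int(c.repeat_confirmed),
        "matched_profiles": ",".join(sorted(c.matched_profiles, key=_pkey)),
    } for c in calls])


def _pkey(pid: str):
    return (0, int(pid)) if pid.isdigit() else (1, pid)


def ensure_parent(path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
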