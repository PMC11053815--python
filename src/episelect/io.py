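"""Readers for the pipeline's plain-text inputs."""

from __future__ import annotations

from Bio import SeqIO

from .core import MissenseMutation, ProteinRecord, parse_mutation


def read_protein_fasta(path) -> ProteinRecord:
    """First and only record of a FASTA file as a :class:`ProteinRecord`.

    Multi-record files are rejected: the pipeline analyses one canonical
    protein per run and silently picking a record would hide isoform
    mix-ups.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(
            f"{path} contains {len(records)} records; supply exactly one "
            "canonical protein sequence"
        )
    rec = records[0]
    return ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())


def read_mutation_list(path) -> list[MissenseMutation]:
    """One ``L858R``-style token per line; ``#`` comments and blanks ignored."""
    mutations = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                mutations.append(parse_mutation(token))
    return mutations
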