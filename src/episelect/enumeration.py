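"""Enumeration of mutant epitope windows and their HLA cross-products.

Every peptide window of a requested length that lies fully inside the
protein and contains the mutated residue is a candidate epitope.  Default
window lengths are 9 and 10 for MHC class I and 15 for class II; both are
configurable.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .core import (
    MHC_I,
    EhlaPair,
    EpitopeCandidate,
    HlaAllele,
    MissenseMutation,
    ProteinRecord,
    apply_mutation,
)

#: Default class-I window lengths (9- and 10-mers).
DEFAULT_CLASS_I_LENGTHS = (9, 10)
#: Default class-II window length (15-mer, field convention).
DEFAULT_CLASS_II_LENGTHS = (15,)


def window_starts(position: int, length: int, protein_length: int) -> range:
    """1-based start positions of windows of ``length`` containing ``position``."""
    lo = max(1, position - length + 1)
    hi = min(position, protein_length - length + 1)
    return range(lo, hi + 1)


def enumerate_epitopes(
    protein: ProteinRecord,
    mutation: MissenseMutation,
    lengths: Iterable[int],
    mhc_class: str = MHC_I,
) -> list[EpitopeCandidate]:
    """All mutant windows of the requested lengths containing the mutation.

    Each candidate carries its matched wild-type window.  Ordering is by
    (length ascending, start ascending).  A mutation with no valid window
    (length longer than the protein) yields an empty list.
    """
    lengths = sorted(set(int(x) for x in lengths))
    if any(l < 1 for l in lengths):
        raise ValueError("window lengths must be >= 1")
    mutant_protein = apply_mutation(protein, mutation)  # validates wt residue
    out: list[EpitopeCandidate] = []
    for length in lengths:
        if length > len(protein):
            continue
        for start in window_starts(mutation.position, length, len(protein)):
            i = start - 1
            out.append(
                EpitopeCandidate(
                    mutant_sequence=mutant_protein[i : i + length],
                    wildtype_sequence=protein.sequence[i : i + length],
                    start=start,
                    mutation_offset=mutation.position - start + 1,
                    mhc_class=mhc_class,
                    source_mutation=mutation.token,
                )
            )
    return out


def enumerate_all(
    protein: ProteinRecord,
    mutations: Sequence[MissenseMutation],
    lengths: Iterable[int],
    mhc_class: str = MHC_I,
) -> list[EpitopeCandidate]:
    """Concatenated candidates over a mutation list (duplicates retained).

    Duplicate peptide sequences arising from different mutations are kept:
    each mutation is an independent vaccine target.
    """
    out: list[EpitopeCandidate] = []
    for m in mutations:
        out.extend(enumerate_epitopes(protein, m, lengths, mhc_class))
    return out


def make_ehla_pairs(
    candidates: Sequence[EpitopeCandidate],
    panel: Sequence[HlaAllele],
) -> list[EhlaPair]:
    """Full cross-product of candidates with an allele panel, no dedup."""
    classes = {c.mhc_class for c in candidates} | {a.mhc_class for a in panel}
    if len(classes) > 1:
        raise ValueError(
            f"candidates and panel must share one MHC class, got {sorted(classes)}"
        )
    return [EhlaPair(epitope=c, allele=a) for c in candidates for a in panel]
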