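"""Core domain objects for the epitope-selection pipeline.

The unit of analysis is the EHLA pair: one candidate epitope (a mutant
peptide window together with its matched wild-type window) crossed with one
HLA allele.  Everything downstream — feature collection, classification,
exclusion filtering, population coverage — operates on lists of these pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

#: The 20 canonical amino acids, one-letter codes.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

MHC_I = "I"
MHC_II = "II"

#: Class-I loci are HLA-A and HLA-B; class-II loci pool the DR beta genes
#: into one DR locus and treat paired alpha/beta DP and DQ names as single
#: units at one locus each.
CLASS_I_LOCI = ("A", "B")
CLASS_II_LOCI = ("DRB1", "DRB3", "DRB4", "DRB5", "DP", "DQ")


class EpiselectError(Exception):
    """Base class for all package errors."""


class MutationError(EpiselectError):
    """A mutation token is malformed or inconsistent with the protein."""


class ConfigurationError(EpiselectError):
    """A run configuration is incomplete or self-contradictory."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue coordinates."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("protein sequence must be non-empty")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains non-canonical residues: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.sequence[position - 1]


_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class MissenseMutation:
    """A single amino-acid substitution, e.g. L858R (1-based position)."""

    wt_residue: str
    position: int
    mut_residue: str
    token: str

    def __str__(self) -> str:
        return self.token


def parse_mutation(token: str) -> MissenseMutation:
    """Parse a ``L858R``-style token into a :class:`MissenseMutation`.

    Raises :class:`MutationError` for malformed tokens, non-canonical
    residue letters (including X and U), and identical wt/mut residues.
    """
    stripped = token.strip()
    m = _MUTATION_RE.match(stripped)
    if m is None:
        raise MutationError(f"malformed mutation token: {token!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if wt not in CANONICAL_AA:
        raise MutationError(f"{token!r}: non-canonical wild-type residue {wt!r}")
    if mut not in CANONICAL_AA:
        raise MutationError(f"{token!r}: non-canonical mutant residue {mut!r}")
    if pos < 1:
        raise MutationError(f"{token!r}: position must be >= 1")
    if wt == mut:
        raise MutationError(f"{token!r}: wild-type and mutant residues are equal")
    return MissenseMutation(wt_residue=wt, position=pos, mut_residue=mut,
                            token=stripped.upper())


def apply_mutation(protein: ProteinRecord, mutation: MissenseMutation) -> str:
    """Return the protein sequence with the substitution applied.

    Raises :class:`MutationError` when the protein's residue at the
    mutation position does not match the token's wild-type residue — the
    usual symptom of a wrong isoform or an off-by-one coordinate.
    """
    pos = mutation.position
    if pos > len(protein):
        raise MutationError(
            f"{mutation.token}: position {pos} beyond protein length "
            f"{len(protein)}"
        )
    actual = protein.residue(pos)
    if actual != mutation.wt_residue:
        raise MutationError(
            f"{mutation.token}: protein {protein.id!r} has {actual} at "
            f"position {pos}, expected {mutation.wt_residue}"
        )
    seq = protein.sequence
    return seq[: pos - 1] + mutation.mut_residue + seq[pos:]


@dataclass(frozen=True)
class EpitopeCandidate:
    """A mutant peptide window plus its matched wild-type window.

    ``start`` is the 1-based position of the window's first residue in the
    source protein; ``mutation_offset`` is the 1-based position of the
    mutated residue within the window.
    """

    mutant_sequence: str
    wildtype_sequence: str
    start: int
    mutation_offset: int
    mhc_class: str
    source_mutation: Optional[str] = None

    def __post_init__(self) -> None:
        n = len(self.mutant_sequence)
        if len(self.wildtype_sequence) != n:
            raise ValueError("mutant and wild-type windows differ in length")
        if not 1 <= self.mutation_offset <= n:
            raise ValueError("mutation_offset outside the window")
        diffs = [i for i in range(n)
                 if self.mutant_sequence[i] != self.wildtype_sequence[i]]
        if diffs != [self.mutation_offset - 1]:
            raise ValueError(
                "windows must differ exactly at mutation_offset and nowhere else"
            )
        if self.mhc_class not in (MHC_I, MHC_II):
            raise ValueError(f"unknown MHC class {self.mhc_class!r}")

    @property
    def length(self) -> int:
        return len(self.mutant_sequence)


@dataclass(frozen=True)
class HlaAllele:
    """An HLA allele in IEDB star-colon notation, e.g. HLA-A*02:01."""

    name: str
    locus: str
    mhc_class: str

    def __post_init__(self) -> None:
        if self.mhc_class == MHC_I:
            if self.locus not in CLASS_I_LOCI:
                raise ValueError(
                    f"class-I allele {self.name} must be at locus A or B, "
                    f"got {self.locus}"
                )
        elif self.mhc_class == MHC_II:
            if self.locus not in CLASS_II_LOCI:
                raise ValueError(
                    f"class-II allele {self.name} has non-class-II locus "
                    f"{self.locus}"
                )
        else:
            raise ValueError(f"unknown MHC class {self.mhc_class!r}")


def allele_from_name(name: str) -> HlaAllele:
    """Build an :class:`HlaAllele`, inferring locus and class from the name.

    DRB1/3/4/5 names map to their own loci; paired alpha/beta DP and DQ
    names (``HLA-DPA1*01:03/DPB1*02:01``) are treated as single units at
    the DP or DQ locus.
    """
    body = name[4:] if name.startswith("HLA-") else name
    gene = body.split("*", 1)[0]
    if gene in ("A", "B"):
        return HlaAllele(name=name, locus=gene, mhc_class=MHC_I)
    if gene in ("DRB1", "DRB3", "DRB4", "DRB5"):
        return HlaAllele(name=name, locus=gene, mhc_class=MHC_II)
    if gene.startswith("DPA") or gene.startswith("DPB"):
        return HlaAllele(name=name, locus="DP", mhc_class=MHC_II)
    if gene.startswith("DQA") or gene.startswith("DQB"):
        return HlaAllele(name=name, locus="DQ", mhc_class=MHC_II)
    raise ValueError(f"cannot infer locus for allele name {name!r}")


@dataclass
class EhlaPair:
    """One epitope crossed with one HLA allele — the pipeline's atom.

    ``features`` is populated by the predictor registry; ``id_label``
    (0/1, or None until classified) by the classifier; ``score`` by the
    regression ranker.
    """

    epitope: EpitopeCandidate
    allele: HlaAllele
    features: dict = field(default_factory=dict)
    id_label: Optional[int] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.epitope.mhc_class != self.allele.mhc_class:
            raise ValueError(
                f"epitope class {self.epitope.mhc_class} does not match "
                f"allele class {self.allele.mhc_class}"
            )

    def with_features(self, **extra) -> "EhlaPair":
        merged = dict(self.features)
        merged.update(extra)
        return replace(self, features=merged)

    @property
    def key(self) -> tuple:
        return (self.epitope.mutant_sequence, self.allele.name)
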