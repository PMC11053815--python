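"""Locally computable peptide descriptors.

The hydropathicity score used for epitope assessment is a *positional*
Kyte–Doolittle sum over residues 4 through n−1 of the epitope (1-based,
inclusive), which deliberately ignores the termini most constrained by MHC
anchor positions.  The remaining descriptors are the standard ProtParam
set: GRAVY (mean KD over all residues), the Guruprasad instability index,
Ikai's aliphatic index, the Bjellqvist isoelectric point, and the N-end
rule half-life (mammalian reticulocytes, in hours).

KD and DIWV constants come from Biopython's ProtParam data; the N-end
half-life table ships with the package as CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .core import CANONICAL_AA

__all__ = [
    "KYTE_DOOLITTLE",
    "NEND_HALFLIFE_HOURS",
    "PhyschemProfile",
    "hydropathicity",
    "gravy",
    "instability_index",
    "aliphatic_index",
    "isoelectric_point",
    "half_life_nend",
    "physchem_profile",
]


def _load_nend_table() -> dict[str, float]:
    text = resources.files("episelect.data").joinpath("nend_halflife.csv").read_text()
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    table = {}
    for rec in csv.DictReader(rows):
        table[rec["residue"]] = float(rec["half_life_hours"])
    return table


#: N-end rule half-lives (hours), mammalian reticulocytes in vitro.
NEND_HALFLIFE_HOURS: dict[str, float] = _load_nend_table()


def _check_peptide(seq: str, minimum: int = 1) -> str:
    if len(seq) < minimum:
        raise ValueError(f"peptide must have >= {minimum} residues, got {len(seq)}")
    bad = set(seq) - CANONICAL_AA
    if bad:
        raise ValueError(f"non-canonical residues in peptide: {sorted(bad)}")
    return seq


def hydropathicity(seq: str) -> float:
    """Positional KD sum over residues 4 … n−1 (1-based, inclusive).

    Requires at least 5 residues so the range is non-empty; epitopes in
    this pipeline are 9-mers or longer.
    """
    _check_peptide(seq, minimum=5)
    return float(sum(KYTE_DOOLITTLE[aa] for aa in seq[3 : len(seq) - 1]))


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean KD over all residues."""
    _check_peptide(seq, minimum=1)
    return float(sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq))


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) × Σ DIWV over adjacent pairs.

    Values above 40 conventionally denote an unstable peptide.
    """
    _check_peptide(seq, minimum=2)
    return float(ProteinAnalysis(seq).instability_index())


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index: 100·X_Ala + 2.9·100·X_Val + 3.9·100·(X_Ile + X_Leu)."""
    _check_peptide(seq, minimum=1)
    n = len(seq)
    x_ala = seq.count("A") / n
    x_val = seq.count("V") / n
    x_il = (seq.count("I") + seq.count("L")) / n
    return 100.0 * (x_ala + 2.9 * x_val + 3.9 * x_il)


def isoelectric_point(seq: str) -> float:
    """pH at which the net peptide charge crosses zero (Bjellqvist pKa set).

    Solved by bisection; the Henderson–Hasselbalch charge model includes
    both termini and all ionizable side chains.
    """
    _check_peptide(seq, minimum=1)
    # full-range bracket: strongly acidic/basic peptides fall outside the
    # solver's default [4.05, 12] window
    return float(IsoelectricPoint(seq).pi(pH=7.0, min_=0.0, max_=14.0))


def net_charge_at_pH(seq: str, pH: float) -> float:
    """Net charge of the peptide at a given pH (same model as the pI solver)."""
    _check_peptide(seq, minimum=1)
    return float(IsoelectricPoint(seq).charge_at_pH(pH))


def half_life_nend(seq: str) -> float:
    """N-end rule half-life in hours, determined by the N-terminal residue."""
    _check_peptide(seq, minimum=1)
    return NEND_HALFLIFE_HOURS[seq[0]]


@dataclass(frozen=True)
class PhyschemProfile:
    """The locally computed descriptor set for one epitope."""

    hydropathicity: float
    gravy: float
    half_life_hours: float
    isoelectric_point: float
    instability_index: float
    aliphatic_index: float

    def as_dict(self) -> dict[str, float]:
        return {
            "hydropathicity": self.hydropathicity,
            "gravy": self.gravy,
            "half_life_hours": self.half_life_hours,
            "isoelectric_point": self.isoelectric_point,
            "instability_index": self.instability_index,
            "aliphatic_index": self.aliphatic_index,
        }


def physchem_profile(seq: str) -> PhyschemProfile:
    """Compute all descriptors for one peptide."""
    return PhyschemProfile(
        hydropathicity=hydropathicity(seq),
        gravy=gravy(seq),
        half_life_hours=half_life_nend(seq),
        isoelectric_point=isoelectric_point(seq),
        instability_index=instability_index(seq),
        aliphatic_index=aliphatic_index(seq),
    )
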