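"""Seeded synthetic inputs for every stage of the pipeline.

The training-table generator emulates the regime of the experimental
class-I training data the models are meant for: 109 positive pairs
(epitopes shown to induce tumour-infiltrating lymphocytes) against 654
sampled negatives — roughly 1:6 imbalance — where positives carry low
percentile binding ranks, long predicted binding half-lives, mildly
elevated wild-type:mutant rank ratios and antigenicity, while negatives
are diffuse (ranks near-uniform on (0, 100]).  Effect sizes are chosen so
a cross-validated classifier lands in the high-0.9 accuracy range without
being trivially perfect; a small label-noise rate keeps the problem from
becoming separable.  None of this claims to match the real data-generating
process — see the methods note for what that implies.

Protein/mutation and allele-frequency generators exist so the end-to-end
pipeline and the coverage stack run with no external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import MissenseMutation, ProteinRecord
from .coverage import AlleleFrequencyTable
from .ml import TrainingDataset

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for every generator; defaults are the study conditions."""

    seed: int = 0
    n_positive: int = 109
    n_negative: int = 654
    label_noise: float = 0.01
    # positive-class location parameters (negatives drawn diffuse)
    pos_rank_log_mean: float = 0.0       # lognormal -> ranks centred ~1st pct
    pos_rank_log_sd: float = 0.9
    pos_stability_mean: float = 6.0      # hours
    pos_ratio_log_mean: float = 0.7      # ratios centred ~2 (mutation helps)
    pos_antigenicity_mean: float = 0.9
    neg_antigenicity_mean: float = 0.3
    antigenicity_sd: float = 0.35
    pos_immunogenicity_mean: float = 62.0
    neg_immunogenicity_mean: float = 42.0
    immunogenicity_sd: float = 14.0
    # protein / mutation generation
    protein_length: int = 1210
    n_mutations: int = 96
    # allele-frequency generation
    alleles_per_locus: int = 6
    concentration: float = 1.0
    n_regions: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("class counts must be >= 0")


def _clip_rank(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 1e-3, 100.0)


def generate_training_dataset(cfg: SyntheticConfig = SyntheticConfig()
                              ) -> TrainingDataset:
    """Labelled feature table in the 109/654 positive:negative regime."""
    rng = np.random.default_rng(cfg.seed)
    n_pos, n_neg = cfg.n_positive, cfg.n_negative

    def positives(n):
        return pd.DataFrame({
            "mhcflurry_rank": _clip_rank(
                rng.lognormal(cfg.pos_rank_log_mean, cfg.pos_rank_log_sd, n)),
            "netmhcpan_rank": _clip_rank(
                rng.lognormal(cfg.pos_rank_log_mean + 0.2,
                              cfg.pos_rank_log_sd, n)),
            "stability_halflife": rng.gamma(3.0, cfg.pos_stability_mean / 3.0, n),
            "wt_mut_rank_ratio": rng.lognormal(cfg.pos_ratio_log_mean, 0.8, n),
            "immunogenicity": rng.normal(cfg.pos_immunogenicity_mean,
                                         cfg.immunogenicity_sd, n),
            "antigenicity": rng.normal(cfg.pos_antigenicity_mean,
                                       cfg.antigenicity_sd, n),
            "hydropathicity": rng.normal(-4.0, 4.0, n),
        })

    def negatives(n):
        return pd.DataFrame({
            "mhcflurry_rank": rng.uniform(1e-3, 100.0, n),
            "netmhcpan_rank": rng.uniform(1e-3, 100.0, n),
            "stability_halflife": rng.gamma(1.2, 1.2, n),
            "wt_mut_rank_ratio": rng.lognormal(0.0, 0.8, n),
            "immunogenicity": rng.normal(cfg.neg_immunogenicity_mean,
                                         cfg.immunogenicity_sd, n),
            "antigenicity": rng.normal(cfg.neg_antigenicity_mean,
                                       cfg.antigenicity_sd, n),
            "hydropathicity": rng.normal(-2.0, 5.0, n),
        })

    features = pd.concat([positives(n_pos), negatives(n_neg)],
                         ignore_index=True)
    labels = np.concatenate([np.ones(n_pos, dtype=int),
                             np.zeros(n_neg, dtype=int)])
    flip = rng.random(len(labels)) < cfg.label_noise
    labels = np.where(flip, 1 - labels, labels)
    return TrainingDataset(features, labels,
                           provenance=f"synthetic(seed={cfg.seed})")


def null_training_dataset(cfg: SyntheticConfig = SyntheticConfig()
                          ) -> TrainingDataset:
    """Same marginals for both classes: no feature carries label signal."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_positive + cfg.n_negative
    features = pd.DataFrame({
        "mhcflurry_rank": rng.uniform(1e-3, 100.0, n),
        "netmhcpan_rank": rng.uniform(1e-3, 100.0, n),
        "stability_halflife": rng.gamma(1.5, 2.0, n),
        "wt_mut_rank_ratio": rng.lognormal(0.0, 0.8, n),
        "immunogenicity": rng.normal(50.0, 15.0, n),
        "antigenicity": rng.normal(0.5, 0.4, n),
        "hydropathicity": rng.normal(-3.0, 5.0, n),
    })
    labels = np.zeros(n, dtype=int)
    labels[: cfg.n_positive] = 1
    rng.shuffle(labels)
    return TrainingDataset(features, labels,
                           provenance=f"synthetic-null(seed={cfg.seed})")


def generate_protein_and_mutations(
    cfg: SyntheticConfig = SyntheticConfig(),
) -> tuple[ProteinRecord, list[MissenseMutation]]:
    """A random canonical-alphabet protein plus consistent missense tokens.

    Mutation positions are sampled without replacement; the wild-type
    residue is read from the protein and the mutant residue is any other
    canonical residue, so every generated token re-parses and validates.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_mutations > cfg.protein_length:
        raise ValueError("cannot place more mutations than residues")
    seq = "".join(rng.choice(list(_AA), size=cfg.protein_length))
    protein = ProteinRecord(id=f"synthetic-{cfg.seed}", sequence=seq)
    positions = rng.choice(cfg.protein_length, size=cfg.n_mutations,
                           replace=False) + 1
    mutations = []
    for pos in sorted(int(p) for p in positions):
        wt = protein.residue(pos)
        alternatives = [a for a in _AA if a != wt]
        mut = str(rng.choice(alternatives))
        mutations.append(MissenseMutation(
            wt_residue=wt, position=pos, mut_residue=mut,
            token=f"{wt}{pos}{mut}"))
    return protein, mutations


def generate_allele_frequencies(
    cfg: SyntheticConfig,
    panel,
    regions: Optional[Sequence[str]] = None,
) -> AlleleFrequencyTable:
    """Dirichlet-drawn per-locus frequencies scaled to sum below 1.

    Each region and locus gets an independent Dirichlet(concentration)
    draw over the panel's alleles at that locus, scaled by a coverage mass
    drawn in (0.6, 0.95) — the shortfall models unlisted alleles.  Always
    includes a "World" entry.
    """
    rng = np.random.default_rng(cfg.seed)
    if regions is None:
        regions = ["World"] + [f"Region{i + 1}" for i in range(cfg.n_regions)]
    elif "World" not in regions:
        regions = ["World"] + list(regions)
    by_locus: dict[str, list[str]] = {}
    for allele in panel:
        by_locus.setdefault(allele.locus, []).append(allele.name)
    rows = []
    for region in regions:
        for locus, names in sorted(by_locus.items()):
            k = min(cfg.alleles_per_locus, len(names))
            chosen = sorted(rng.choice(names, size=k, replace=False))
            weights = rng.dirichlet(np.full(k, cfg.concentration))
            mass = rng.uniform(0.6, 0.95)
            for name, w in zip(chosen, weights):
                rows.append({"region": region, "locus": locus,
                             "allele": name, "frequency": mass * w})
    return AlleleFrequencyTable(pd.DataFrame(rows))
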