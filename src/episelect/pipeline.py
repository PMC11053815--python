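"""End-to-end orchestration: mutations + protein in, epitope lists out.

One run analyses one protein and one mutation list for one cancer, and
writes a folder named after the cancer containing:

* ``CD8 Epitopes.csv``       — every class-I pair, features, ID, score
  (sorted by ID desc, score desc);
* ``CD8 Filtered Epitopes.csv`` — the class-I survivors of the exclusion
  criteria;
* ``CD4 Epitopes.csv``       — every class-II pair and features;
* ``CD4 Filtered Epitopes.csv`` — the class-II survivors;
* ``Sequence.txt``           — the deduplicated mutant epitope sequences,
  one per line (sorted);
* ``manifest.yaml``          — config, seed, package and library versions.

File names keep their historical spaces by default; ``safe_names=True``
swaps them for underscores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .core import EhlaPair, MHC_I, MHC_II
from .enumeration import (
    DEFAULT_CLASS_I_LENGTHS,
    DEFAULT_CLASS_II_LENGTHS,
    enumerate_all,
    make_ehla_pairs,
)
from .filters import filter_ehla_i, filter_ehla_ii
from .io import read_mutation_list, read_protein_fasta
from .ml import FittedModels, TrainingDataset, classify_and_rank, train_final_models
from .panels import class_i_panel, class_ii_panel
from .predictors import collect_features, mock_registry, registry_from_csv
from .synthetic import SyntheticConfig, generate_training_dataset

log = logging.getLogger("episelect.pipeline")

#: Features recorded for class-I pairs (classifier/ranker inputs, filter
#: inputs, and the remaining recorded descriptors).
CLASS_I_FEATURES = (
    "mhcflurry_rank", "netmhcpan_rank", "binding_affinity_nM",
    "stability_halflife", "wt_mut_rank_ratio", "immunogenicity",
    "antigenicity", "hydropathicity", "toxicity_label", "half_life_hours",
    "instability_index", "allergenicity_label", "gravy",
    "isoelectric_point", "aliphatic_index",
)

CLASS_II_FEATURES = (
    "netmhcii_rank", "netmhcii_affinity", "immunogenicity", "antigenicity",
    "ifng_label", "toxicity_label", "half_life_hours", "instability_index",
    "allergenicity_label", "hydropathicity", "gravy", "isoelectric_point",
    "aliphatic_index",
)

_FILES = {
    "cd8": "CD8 Epitopes.csv",
    "cd8_filtered": "CD8 Filtered Epitopes.csv",
    "cd4": "CD4 Epitopes.csv",
    "cd4_filtered": "CD4 Filtered Epitopes.csv",
    "sequence": "Sequence.txt",
    "manifest": "manifest.yaml",
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    cancer_name: str
    protein_path: str
    mutations_path: str
    output_dir: str = "."
    class_i_lengths: tuple = DEFAULT_CLASS_I_LENGTHS
    class_ii_lengths: tuple = DEFAULT_CLASS_II_LENGTHS
    class_i_panel: Optional[Sequence] = None
    class_ii_panel: Optional[Sequence] = None
    feature_csv: Optional[str] = None      # bring-your-own-scores table
    training_csv: Optional[str] = None     # labelled class-I training table
    seed: int = 0
    safe_names: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _file_name(key: str, safe: bool) -> str:
    name = _FILES[key]
    return name.replace(" ", "_") if safe else name


def pairs_to_frame(pairs: Sequence[EhlaPair], feature_order: Sequence[str],
                   with_models: bool) -> pd.DataFrame:
    rows = []
    for p in pairs:
        row = {
            "mutation": p.epitope.source_mutation,
            "epitope": p.epitope.mutant_sequence,
            "wildtype_epitope": p.epitope.wildtype_sequence,
            "start": p.epitope.start,
            "length": p.epitope.length,
            "allele": p.allele.name,
        }
        for f in feature_order:
            row[f] = p.features.get(f)
        if with_models:
            row["id"] = p.id_label
            row["score"] = p.score
        rows.append(row)
    columns = (["mutation", "epitope", "wildtype_epitope", "start", "length",
                "allele"] + list(feature_order)
               + (["id", "score"] if with_models else []))
    return pd.DataFrame(rows, columns=columns)


def _resolve_models(cfg: RunConfig) -> FittedModels:
    if cfg.training_csv is not None:
        data = TrainingDataset.from_csv(cfg.training_csv)
    else:
        data = generate_training_dataset(SyntheticConfig(seed=cfg.seed))
    return train_final_models(data, seed=cfg.seed)


def run_pipeline(cfg: RunConfig, models: Optional[FittedModels] = None) -> dict:
    """Execute a full run; returns the mapping of output names to paths."""
    protein = read_protein_fasta(cfg.protein_path)
    mutations = read_mutation_list(cfg.mutations_path)
    log.info("protein %s (%d aa), %d mutations", protein.id, len(protein),
             len(mutations))

    panel_i = list(cfg.class_i_panel or class_i_panel())
    panel_ii = list(cfg.class_ii_panel or class_ii_panel())
    if cfg.feature_csv is not None:
        registry = registry_from_csv(cfg.feature_csv)
    else:
        registry = mock_registry(cfg.seed)

    candidates_i = enumerate_all(protein, mutations, cfg.class_i_lengths, MHC_I)
    candidates_ii = enumerate_all(protein, mutations, cfg.class_ii_lengths, MHC_II)
    pairs_i = make_ehla_pairs(candidates_i, panel_i)
    pairs_ii = make_ehla_pairs(candidates_ii, panel_ii)
    log.info("enumerated %d class-I and %d class-II pairs",
             len(pairs_i), len(pairs_ii))

    pairs_i = collect_features(pairs_i, registry, CLASS_I_FEATURES)
    pairs_ii = collect_features(pairs_ii, registry, CLASS_II_FEATURES)

    if models is None:
        models = _resolve_models(cfg)
    pairs_i = classify_and_rank(pairs_i, models)
    kept_i, audit_i = filter_ehla_i(pairs_i)
    kept_ii, audit_ii = filter_ehla_ii(pairs_ii)
    log.info("filtering kept %d/%d class-I and %d/%d class-II pairs",
             len(kept_i), len(pairs_i), len(kept_ii), len(pairs_ii))

    out_dir = Path(cfg.output_dir) / cfg.cancer_name
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / _file_name(k, cfg.safe_names) for k in _FILES}

    pairs_to_frame(pairs_i, CLASS_I_FEATURES, True).to_csv(
        paths["cd8"], index=False)
    pairs_to_frame(kept_i, CLASS_I_FEATURES, True).to_csv(
        paths["cd8_filtered"], index=False)
    pairs_to_frame(pairs_ii, CLASS_II_FEATURES, False).to_csv(
        paths["cd4"], index=False)
    pairs_to_frame(kept_ii, CLASS_II_FEATURES, False).to_csv(
        paths["cd4_filtered"], index=False)

    sequences = sorted(
        {p.epitope.mutant_sequence for p in pairs_i}
        | {p.epitope.mutant_sequence for p in pairs_ii}
    )
    paths["sequence"].write_text("\n".join(sequences) + "\n", encoding="utf-8")

    manifest = {
        "episelect_version": __version__,
        "cancer_name": cfg.cancer_name,
        "protein": {"id": protein.id, "length": len(protein)},
        "n_mutations": len(mutations),
        "class_i_lengths": list(cfg.class_i_lengths),
        "class_ii_lengths": list(cfg.class_ii_lengths),
        "seed": cfg.seed,
        "registry": "csv" if cfg.feature_csv else "mock",
        "training": cfg.training_csv or "synthetic",
        "counts": {
            "ehla_i": len(pairs_i), "ehla_i_filtered": len(kept_i),
            "ehla_ii": len(pairs_ii), "ehla_ii_filtered": len(kept_ii),
        },
        "filter_audit": {
            "ehla_i": audit_i.rejected_by_rule,
            "ehla_ii": audit_ii.rejected_by_rule,
        },
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
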