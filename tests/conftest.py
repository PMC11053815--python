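import numpy as np
import pytest

from episelect.core import EhlaPair, EpitopeCandidate, HlaAllele, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def make_candidate(mut_seq: str, offset: int = 1, mhc_class: str = "I",
                   start: int = 1) -> EpitopeCandidate:
    """A candidate whose wild-type window differs only at `offset` (1-based)."""
    wt = mut_seq[: offset - 1] + ("A" if mut_seq[offset - 1] != "A" else "G") \
        + mut_seq[offset:]
    return EpitopeCandidate(mutant_sequence=mut_seq, wildtype_sequence=wt,
                           start=start, mutation_offset=offset,
                           mhc_class=mhc_class)


def make_pair(mut_seq: str, allele_name: str = "HLA-A*02:01",
              locus: str = "A", mhc_class: str = "I",
              features=None, id_label=None, score=None) -> EhlaPair:
    pair = EhlaPair(
        epitope=make_candidate(mut_seq, mhc_class=mhc_class),
        allele=HlaAllele(name=allele_name, locus=locus, mhc_class=mhc_class),
        features=dict(features or {}),
    )
    pair.id_label = id_label
    pair.score = score
    return pair


@pytest.fixture
def toy_protein() -> ProteinRecord:
    rng = np.random.default_rng(7)
    return ProteinRecord(id="toy", sequence=random_peptide(rng, 60))


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """A small end-to-end pipeline run shared across tests."""
    from episelect.panels import class_i_panel
    from episelect.pipeline import RunConfig, run_pipeline
    from episelect.synthetic import (
        SyntheticConfig,
        generate_allele_frequencies,
        generate_protein_and_mutations,
    )

    root = tmp_path_factory.mktemp("demo")
    cfg = SyntheticConfig(seed=11, n_mutations=5, protein_length=120)
    protein, muts = generate_protein_and_mutations(cfg)
    (root / "protein.fasta").write_text(f">{protein.id}\n{protein.sequence}\n")
    (root / "mutations.txt").write_text(
        "\n".join(m.token for m in muts) + "\n")
    generate_allele_frequencies(cfg, class_i_panel()).to_csv(root / "freq.csv")
    run_cfg = RunConfig(
        cancer_name="DemoCancer",
        protein_path=str(root / "protein.fasta"),
        mutations_path=str(root / "mutations.txt"),
        output_dir=str(root),
        seed=11,
    )
    paths = run_pipeline(run_cfg)
    return {"root": root, "config": run_cfg, "paths": paths,
            "protein": protein, "mutations": muts}
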