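"""Pluggable predictor registry for externally computed epitope features.

The binding, stability, immunogenicity, antigenicity, toxicity,
allergenicity and IFN-γ predictions that drive selection are produced by
specialised external tools; this package does not re-implement them.
Instead every feature has a uniform contract — a pure callable of
``(epitope_sequence, allele_name) -> value`` — with three interchangeable
backends:

* seeded deterministic mocks (hash-based), so the full pipeline runs and
  tests offline;
* a "bring-your-own-scores" CSV adapter for precomputed values;
* any user-supplied callable.

Two descriptors ARE computed locally because they are simple functions of
other values: the wild-type:mutant binding-rank ratio, and an
auto-cross-covariance (ACC) antigenicity featurisation over Hellberg
z-scales with a configurable linear read-out (the read-out weights are a
pluggable asset, not a claim to reproduce any particular web tool).
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import MHC_I, MHC_II, ConfigurationError, EhlaPair
from . import physchem

PredictorFn = Callable[[str, str], object]

TOXIN = "Toxin"
NON_TOXIN = "Non-Toxin"
PROBABLE_ALLERGEN = "Probable Allergen"
PROBABLE_NON_ALLERGEN = "Probable Non-Allergen"
IFNG_POSITIVE = "Positive"
IFNG_NEGATIVE = "Negative"


@dataclass(frozen=True)
class FeatureSpec:
    """Declared name, kind, preferred direction and class scope of a feature."""

    name: str
    value_kind: str                     # "real" | "categorical"
    direction: str                      # "lower" | "higher" | "none"
    mhc_classes: tuple = (MHC_I, MHC_II)
    mock_range: tuple = (0.0, 1.0)      # reals: (lo, hi]; categoricals: (p, pos, neg)


_REGISTRY_SPECS = [
    FeatureSpec("mhcflurry_rank", "real", "lower", (MHC_I,), (0.0, 100.0)),
    FeatureSpec("netmhcpan_rank", "real", "lower", (MHC_I,), (0.0, 100.0)),
    FeatureSpec("binding_affinity_nM", "real", "lower", (MHC_I,), (1.0, 50000.0)),
    FeatureSpec("stability_halflife", "real", "higher", (MHC_I,), (0.0, 12.0)),
    FeatureSpec("immunogenicity", "real", "higher", (MHC_I, MHC_II), (0.0, 100.0)),
    FeatureSpec("antigenicity", "real", "higher", (MHC_I, MHC_II), (-1.0, 1.5)),
    FeatureSpec("toxicity_label", "categorical", "none", (MHC_I, MHC_II),
                (0.1, TOXIN, NON_TOXIN)),
    FeatureSpec("allergenicity_label", "categorical", "none", (MHC_I, MHC_II),
                (0.3, PROBABLE_ALLERGEN, PROBABLE_NON_ALLERGEN)),
    FeatureSpec("ifng_label", "categorical", "none", (MHC_II,),
                (0.5, IFNG_POSITIVE, IFNG_NEGATIVE)),
    FeatureSpec("netmhcii_rank", "real", "lower", (MHC_II,), (0.0, 100.0)),
    FeatureSpec("netmhcii_affinity", "real", "lower", (MHC_II,), (1.0, 50000.0)),
]

#: Features served by predictor backends, keyed by name.
FEATURE_SPECS: dict[str, FeatureSpec] = {s.name: s for s in _REGISTRY_SPECS}

#: Features computed locally from the epitope sequence alone.
LOCAL_FEATURES = (
    "hydropathicity", "gravy", "half_life_hours", "isoelectric_point",
    "instability_index", "aliphatic_index",
)

#: Derived feature requiring the matched wild-type window's binding rank.
RANK_RATIO_FEATURE = "wt_mut_rank_ratio"
#: Rank predictor used for the ratio, per MHC class.
_RATIO_RANK_SOURCE = {MHC_I: "mhcflurry_rank", MHC_II: "netmhcii_rank"}


def rank_ratio(wt_rank: float, mut_rank: float) -> float:
    """Wild-type:mutant percentile-rank ratio; > 1 means the mutation
    improved binding (lower mutant rank)."""
    if wt_rank <= 0 or mut_rank <= 0:
        raise ValueError(
            f"percentile ranks must be positive, got wt={wt_rank}, mut={mut_rank}"
        )
    return wt_rank / mut_rank


# ---------------------------------------------------------------------------
# ACC antigenicity
# ---------------------------------------------------------------------------

def _load_zscales() -> dict[str, np.ndarray]:
    text = resources.files("episelect.data").joinpath("zscales.csv").read_text()
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    table = {}
    for rec in csv.DictReader(rows):
        table[rec["residue"]] = np.array(
            [float(rec["z1"]), float(rec["z2"]), float(rec["z3"])]
        )
    return table


#: Hellberg 3-descriptor z-scales per residue.
Z_SCALES: dict[str, np.ndarray] = _load_zscales()


def acc_terms(seq: str, lag: int = 1) -> np.ndarray:
    """Auto- and cross-covariance terms of the z-scale series.

    The three descriptor series are centred on their per-sequence means;
    term (l, j, k) is Σ_i z̃_j(i)·z̃_k(i+l) / (n − l).  Terms are flattened
    with lag as the outermost index, then descriptor j, then k — giving a
    fixed-length vector of 9·lag entries for any peptide longer than
    ``lag``.
    """
    n = len(seq)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if n <= lag:
        raise ValueError(f"peptide length {n} must exceed lag {lag}")
    z = np.array([Z_SCALES[aa] for aa in seq])       # (n, 3)
    z = z - z.mean(axis=0)
    out = []
    for l in range(1, lag + 1):
        head, tail = z[:-l], z[l:]
        cov = head.T @ tail / (n - l)                # (3, 3): rows j, cols k
        out.append(cov.ravel())
    return np.concatenate(out)


@dataclass(frozen=True)
class AccAntigenicityModel:
    """Linear read-out over ACC terms: score = intercept + w · terms."""

    lag: int = 1
    weights: Optional[np.ndarray] = None   # defaults to uniform 1/(9·lag)
    intercept: float = 0.0

    def score(self, seq: str) -> float:
        terms = acc_terms(seq, self.lag)
        w = self.weights
        if w is None:
            w = np.full(terms.size, 1.0 / terms.size)
        if len(w) != terms.size:
            raise ConfigurationError(
                f"ACC weight vector has {len(w)} entries, expected {terms.size}"
            )
        return float(self.intercept + np.dot(w, terms))


def acc_antigenicity(seq: str, lag: int = 1,
                     model: Optional[AccAntigenicityModel] = None) -> float:
    """Scalar ACC antigenicity score for one peptide."""
    if model is None:
        model = AccAntigenicityModel(lag=lag)
    return model.score(seq)


# ---------------------------------------------------------------------------
# Mock predictors
# ---------------------------------------------------------------------------

def _unit_hash(parts: Iterable[str], seed: int) -> float:
    """Deterministic value in (0, 1] from a SHA-256 of the joined parts."""
    key = "|".join(list(parts) + [str(seed)]).encode()
    digest = hashlib.sha256(key).digest()
    v = int.from_bytes(digest[:8], "big")
    return (v + 1) / float(2 ** 64)


def mock_predictor(spec: FeatureSpec, seed: int) -> PredictorFn:
    """A pure, seeded stand-in predictor for one feature.

    Reals are drawn uniformly in the feature's plausible range (lo, hi];
    categorical labels from a seeded Bernoulli.  The same
    (epitope, allele, feature, seed) always maps to the same value.
    """

    def predict(epitope_seq: str, allele_name: str):
        u = _unit_hash((epitope_seq, allele_name, spec.name), seed)
        if spec.value_kind == "real":
            lo, hi = spec.mock_range
            return lo + u * (hi - lo)
        p, positive, negative = spec.mock_range
        return positive if u <= p else negative

    return predict


def mock_registry(seed: int) -> dict[str, PredictorFn]:
    """Mock backends for every declared feature."""
    return {name: mock_predictor(spec, seed)
            for name, spec in FEATURE_SPECS.items()}


# ---------------------------------------------------------------------------
# Precomputed-score CSV adapter
# ---------------------------------------------------------------------------

_CSV_HEADER = ["epitope", "allele_name", "feature_name", "value"]


def registry_from_csv(path_or_buffer) -> dict[str, PredictorFn]:
    """Load a bring-your-own-scores table into predictor bindings.

    The CSV must have exactly the header ``epitope,allele_name,
    feature_name,value``; unknown feature names are rejected.  Lookups for
    (epitope, allele) combinations missing from the table raise
    :class:`ConfigurationError`.
    """
    if hasattr(path_or_buffer, "read"):
        fh = path_or_buffer
    else:
        fh = io.StringIO(open(path_or_buffer, encoding="utf-8").read())
    reader = csv.reader(fh)
    header = next(reader, None)
    if header != _CSV_HEADER:
        raise ConfigurationError(
            f"feature CSV header must be {_CSV_HEADER}, got {header}"
        )
    tables: dict[str, dict[tuple, object]] = {}
    for row in reader:
        if not row:
            continue
        epi, allele, feature, value = row
        if feature not in FEATURE_SPECS:
            raise ConfigurationError(f"unknown feature name in CSV: {feature!r}")
        kind = FEATURE_SPECS[feature].value_kind
        tables.setdefault(feature, {})[(epi, allele)] = (
            float(value) if kind == "real" else value
        )

    def make_lookup(feature: str, table: Mapping) -> PredictorFn:
        def predict(epitope_seq: str, allele_name: str):
            try:
                return table[(epitope_seq, allele_name)]
            except KeyError:
                raise ConfigurationError(
                    f"no precomputed {feature!r} value for "
                    f"({epitope_seq}, {allele_name})"
                ) from None
        return predict

    return {f: make_lookup(f, t) for f, t in tables.items()}


# ---------------------------------------------------------------------------
# Feature collection
# ---------------------------------------------------------------------------

def collect_features(
    pairs: Sequence[EhlaPair],
    registry: Mapping[str, PredictorFn],
    demanded: Sequence[str],
) -> list[EhlaPair]:
    """Populate every pair's feature map with every demanded feature.

    Local physicochemical descriptors are computed from the mutant window;
    ``wt_mut_rank_ratio`` uses the class-appropriate rank predictor applied
    to both the mutant and the matched wild-type window.  A demanded
    feature with no bound predictor, or one out of scope for a pair's MHC
    class, raises :class:`ConfigurationError` naming the feature.
    """
    demanded = list(demanded)
    for name in demanded:
        if name in LOCAL_FEATURES or name == RANK_RATIO_FEATURE:
            continue
        if name not in FEATURE_SPECS:
            raise ConfigurationError(f"unknown feature: {name!r}")
        if name not in registry:
            raise ConfigurationError(f"no predictor bound for feature {name!r}")

    out = []
    for pair in pairs:
        seq = pair.epitope.mutant_sequence
        allele = pair.allele.name
        values = {}
        local = None
        for name in demanded:
            if name in LOCAL_FEATURES:
                if local is None:
                    local = physchem.physchem_profile(seq).as_dict()
                values[name] = local[name]
            elif name == RANK_RATIO_FEATURE:
                source = _RATIO_RANK_SOURCE[pair.epitope.mhc_class]
                if source not in registry:
                    raise ConfigurationError(
                        f"feature {RANK_RATIO_FEATURE!r} needs a bound "
                        f"{source!r} predictor"
                    )
                wt = registry[source](pair.epitope.wildtype_sequence, allele)
                mut = registry[source](seq, allele)
                values[name] = rank_ratio(wt, mut)
            else:
                spec = FEATURE_SPECS[name]
                if pair.epitope.mhc_class not in spec.mhc_classes:
                    raise ConfigurationError(
                        f"feature {name!r} is not defined for MHC class "
                        f"{pair.epitope.mhc_class} pairs"
                    )
                values[name] = registry[name](seq, allele)
        out.append(pair.with_features(**values))
    return out
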