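"""Classification and ranking of class-I epitope–HLA pairs.

Two trainable models drive selection: a classifier assigns each pair a
binary ID (1 = predicted able to induce tumour-infiltrating lymphocytes,
0 = non-antigen) and a regression ranker assigns a continuous score used
to order pairs within each ID group.  Model families, the feature pool,
and the five-fold cross-validated feature-combination search are all
explicit so alternative families (SVM, Gaussian naive Bayes, MLP;
logistic, random-forest and gradient-boosting regression) can be compared
against the defaults (random-forest classifier, ordinary linear
regression fit on the 0/1 label).

The training table is expected to be heavily imbalanced (roughly 1:6
positive:negative); folds are stratified and classes are left unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .core import ConfigurationError, EhlaPair
from . import physchem
from .predictors import LOCAL_FEATURES, RANK_RATIO_FEATURE, PredictorFn

#: Candidate feature pool for the combination search.
CANDIDATE_FEATURE_POOL = (
    "mhcflurry_rank",
    "netmhcpan_rank",
    "stability_halflife",
    "wt_mut_rank_ratio",
    "immunogenicity",
    "antigenicity",
    "hydropathicity",
)

CLASSIFIER_FAMILIES = ("rf_classifier", "svm_classifier", "gnb_classifier",
                       "mlp_classifier")
REGRESSOR_FAMILIES = ("linear_regression", "logistic_regression",
                      "rf_regression", "gb_regression")

#: Default feature set for the shipped classifier and ranker: the
#: combination found most accurate for classification (binding rank, rank
#: ratio, stability, antigenicity, hydropathicity) and, for ranking, the
#: purely binding-derived subset.
DEFAULT_CLASSIFIER_FEATURES = (
    "antigenicity", "hydropathicity", "mhcflurry_rank",
    "wt_mut_rank_ratio", "stability_halflife",
)
DEFAULT_RANKER_FEATURES = (
    "mhcflurry_rank", "wt_mut_rank_ratio", "stability_halflife",
)


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its ordered feature list, hyperparameters and seed."""

    family: str
    feature_names: tuple
    hyperparameters: tuple = ()      # sorted (key, value) pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES + REGRESSOR_FAMILIES:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        if not self.feature_names:
            raise ConfigurationError("feature_names must be non-empty")

    @property
    def is_classifier(self) -> bool:
        return self.family in CLASSIFIER_FAMILIES

    def build(self):
        hp = dict(self.hyperparameters)
        seed = self.seed
        if self.family == "rf_classifier":
            hp.setdefault("n_estimators", 100)
            return RandomForestClassifier(random_state=seed, **hp)
        if self.family == "svm_classifier":
            return SVC(random_state=seed, **hp)
        if self.family == "gnb_classifier":
            return GaussianNB(**hp)
        if self.family == "mlp_classifier":
            hp.setdefault("max_iter", 1000)
            return MLPClassifier(random_state=seed, **hp)
        if self.family == "linear_regression":
            return LinearRegression(**hp)
        if self.family == "logistic_regression":
            hp.setdefault("max_iter", 1000)
            return LogisticRegression(random_state=seed, **hp)
        if self.family == "rf_regression":
            hp.setdefault("n_estimators", 100)
            return RandomForestRegressor(random_state=seed, **hp)
        hp.setdefault("random_state", seed)
        return GradientBoostingRegressor(**hp)


class TrainingDataset:
    """Labelled feature table: one row per class-I epitope–HLA pair."""

    def __init__(self, features: pd.DataFrame, labels: Sequence[int],
                 provenance: str = "unspecified"):
        labels = np.asarray(labels, dtype=int)
        if len(features) != len(labels):
            raise ValueError("features and labels length mismatch")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        self.features = features.reset_index(drop=True)
        self.labels = labels
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self) - self.labels.sum())

    def matrix(self, feature_names: Sequence[str]) -> np.ndarray:
        missing = [f for f in feature_names if f not in self.features.columns]
        if missing:
            raise ConfigurationError(f"training data lacks features: {missing}")
        X = self.features.loc[:, list(feature_names)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("training features contain NaN values")
        return X

    @classmethod
    def from_csv(cls, path, label_column: str = "label") -> "TrainingDataset":
        df = pd.read_csv(path)
        if label_column not in df.columns:
            raise ConfigurationError(
                f"training CSV lacks the {label_column!r} column"
            )
        labels = df[label_column].to_numpy()
        return cls(df.drop(columns=[label_column]), labels, provenance=str(path))

    def to_csv(self, path) -> None:
        df = self.features.copy()
        df["label"] = self.labels
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def classification_metrics(y_true, y_pred) -> dict[str, float]:
    """Accuracy, PPV and TPR from the 2×2 confusion matrix.

    PPV is NaN when no positive predictions were made (undefined ratio).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    acc = (tp + tn) / len(y_true)
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    tpr = tp / (tp + fn) if (tp + fn) else float("nan")
    return {"accuracy": acc, "ppv": ppv, "tpr": tpr}


def auc_roc(y_true, scores) -> float:
    """Area under the ROC curve of continuous scores against binary labels."""
    return float(roc_auc_score(np.asarray(y_true, dtype=int), scores))


@dataclass
class CvReport:
    """Per-fold and mean metrics for one cross-validated model spec."""

    spec: ModelSpec
    per_fold: dict[str, list]
    fold_assignments: np.ndarray

    @property
    def means(self) -> dict[str, float]:
        out = {}
        for name, values in self.per_fold.items():
            arr = np.asarray(values, dtype=float)
            if np.isnan(arr).any() and name == "ppv":
                valid = arr[~np.isnan(arr)]
                out[name] = float(valid.mean()) if valid.size else float("nan")
            else:
                out[name] = float(np.mean(arr))
        return out

    @property
    def selection_metric(self) -> float:
        return self.means["accuracy" if self.spec.is_classifier else "auc"]


def five_fold_cv(data: TrainingDataset, spec: ModelSpec,
                 n_folds: int = 5) -> CvReport:
    """Stratified k-fold cross-validation of one model spec.

    Classifiers report per-fold accuracy/PPV/TPR from their 0/1
    predictions; regressors report per-fold ROC AUC from their continuous
    predictions.  Requires at least ``n_folds`` rows per class so folds
    are stratifiable; a PPV fold with zero positive predictions is
    recorded NaN, excluded from the mean, and warned about.
    """
    if data.n_positive == 0 or data.n_negative == 0:
        raise ValueError("training data must contain both classes")
    if min(data.n_positive, data.n_negative) < n_folds:
        raise ValueError("too few rows per class to stratify")
    X = data.matrix(spec.feature_names)
    y = data.labels
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    assignments = np.empty(len(y), dtype=int)
    per_fold: dict[str, list] = (
        {"accuracy": [], "ppv": [], "tpr": []} if spec.is_classifier
        else {"auc": []}
    )
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        assignments[test_idx] = fold
        model = spec.build()
        model.fit(X[train_idx], y[train_idx])
        if spec.is_classifier:
            pred = model.predict(X[test_idx])
            m = classification_metrics(y[test_idx], pred)
            if np.isnan(m["ppv"]):
                warnings.warn(
                    f"fold {fold}: no positive predictions, PPV undefined "
                    "and excluded from the mean"
                )
            for k in per_fold:
                per_fold[k].append(m[k])
        else:
            scores = _regressor_scores(model, X[test_idx])
            per_fold["auc"].append(auc_roc(y[test_idx], scores))
    return CvReport(spec=spec, per_fold=per_fold, fold_assignments=assignments)


def _regressor_scores(model, X) -> np.ndarray:
    # LogisticRegression is used as a "regression" ranker: rank by the
    # positive-class probability rather than the hard 0/1 prediction.
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.predict(X)


def _nonempty_subsets(pool: Sequence[str]):
    pool = list(pool)
    for mask in range(1, 2 ** len(pool)):
        yield tuple(p for i, p in enumerate(pool) if mask >> i & 1)


def feature_combination_search(
    data: TrainingDataset,
    family: str,
    candidate_features: Sequence[str] = CANDIDATE_FEATURE_POOL,
    seed: int = 0,
    subsets: Optional[Sequence[Sequence[str]]] = None,
) -> tuple[list[CvReport], ModelSpec]:
    """Cross-validate one model family over feature subsets.

    Evaluates every non-empty subset of the candidate pool (127 subsets
    for the 7-feature pool) unless an explicit subset list is given.
    Returns all reports plus the best spec — highest mean accuracy for
    classifiers, highest mean AUC for regressors; ties broken by fewer
    features, then lexicographic feature names.
    """
    unknown = [f for f in candidate_features
               if f not in CANDIDATE_FEATURE_POOL]
    if unknown:
        raise ConfigurationError(f"features outside the candidate pool: {unknown}")
    if subsets is None:
        subsets = list(_nonempty_subsets(candidate_features))
    reports = []
    for subset in subsets:
        spec = ModelSpec(family=family, feature_names=tuple(subset), seed=seed)
        reports.append(five_fold_cv(data, spec))
    # Among subsets tied on the selection metric: fewest features first,
    # then lexicographically smallest feature-name tuple.
    top = max(r.selection_metric for r in reports)
    contenders = [r for r in reports if r.selection_metric == top]
    best = min(
        contenders,
        key=lambda r: (len(r.spec.feature_names), tuple(sorted(r.spec.feature_names))),
    )
    return reports, best.spec


def search_table(reports: Sequence[CvReport]) -> pd.DataFrame:
    """Flatten CV reports into a table (one row per feature subset)."""
    rows = []
    for r in reports:
        row = {"family": r.spec.family,
               "features": "+".join(r.spec.feature_names)}
        row.update(r.means)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Final models
# ---------------------------------------------------------------------------

@dataclass
class FittedModels:
    """The trained classifier/ranker pair applied to new epitope–HLA pairs."""

    classifier: object
    classifier_spec: ModelSpec
    ranker: object
    ranker_spec: ModelSpec
    feature_importances: Optional[dict] = None


def train_final_models(
    data: TrainingDataset,
    classifier_spec: Optional[ModelSpec] = None,
    ranker_spec: Optional[ModelSpec] = None,
    seed: int = 0,
) -> FittedModels:
    """Fit the final classifier and ranker on the full training table.

    Defaults: a 100-tree random-forest classifier on the five-feature
    default set, and an ordinary linear regression on the binding-derived
    subset, fit against the 0/1 label.  Random-forest impurity importances
    are normalised to sum to 1.
    """
    if classifier_spec is None:
        classifier_spec = ModelSpec("rf_classifier",
                                    DEFAULT_CLASSIFIER_FEATURES, seed=seed)
    if ranker_spec is None:
        ranker_spec = ModelSpec("linear_regression",
                                DEFAULT_RANKER_FEATURES, seed=seed)
    if not classifier_spec.is_classifier:
        raise ConfigurationError("classifier_spec must be a classifier family")
    if ranker_spec.is_classifier:
        raise ConfigurationError("ranker_spec must be a regression family")
    clf = classifier_spec.build()
    clf.fit(data.matrix(classifier_spec.feature_names), data.labels)
    rk = ranker_spec.build()
    rk.fit(data.matrix(ranker_spec.feature_names), data.labels)
    importances = None
    if hasattr(clf, "feature_importances_"):
        raw = np.asarray(clf.feature_importances_, dtype=float)
        total = raw.sum()
        norm = raw / total if total > 0 else np.full_like(raw, 1 / len(raw))
        importances = dict(zip(classifier_spec.feature_names, norm.tolist()))
    return FittedModels(classifier=clf, classifier_spec=classifier_spec,
                        ranker=rk, ranker_spec=ranker_spec,
                        feature_importances=importances)


def _pair_matrix(pairs: Sequence[EhlaPair], feature_names) -> np.ndarray:
    rows = []
    for p in pairs:
        missing = [f for f in feature_names if f not in p.features]
        if missing:
            raise ConfigurationError(
                f"pair {p.key} lacks features {missing}; run collect_features "
                "with them demanded"
            )
        rows.append([float(p.features[f]) for f in feature_names])
    return np.asarray(rows, dtype=float)


def classify_and_rank(pairs: Sequence[EhlaPair],
                      models: FittedModels) -> list[EhlaPair]:
    """Assign IDs and scores, then sort.

    Sort order: ID descending, score descending, then (epitope sequence,
    allele name) ascending for determinism.  Warns when the ranker emits
    degenerate near-binary scores (> 50% within 1e-6 of 0 or 1), the
    failure mode that makes a ranker unusable for prioritisation.
    """
    pairs = list(pairs)
    if not pairs:
        return []
    ids = models.classifier.predict(
        _pair_matrix(pairs, models.classifier_spec.feature_names))
    scores = _regressor_scores(
        models.ranker, _pair_matrix(pairs, models.ranker_spec.feature_names))
    near_binary = np.mean(
        (np.abs(scores) < 1e-6) | (np.abs(scores - 1) < 1e-6))
    if near_binary > 0.5:
        warnings.warn(
            "ranker scores are degenerate: most are exactly 0 or 1 and "
            "cannot be used to order pairs"
        )
    for p, i, s in zip(pairs, ids, scores):
        p.id_label = int(i)
        p.score = float(s)
    return sorted(
        pairs,
        key=lambda p: (-p.id_label, -p.score,
                       p.epitope.mutant_sequence, p.allele.name),
    )


def screen_epitope_list(
    epitopes: Sequence[str],
    panel,
    models: FittedModels,
    registry: dict[str, PredictorFn],
) -> tuple[dict[str, bool], float]:
    """Fraction of bare peptides with at least one positive pair.

    Screened peptides have no matched wild-type window, so the
    wild-type:mutant rank ratio defaults to 1.0 (binding unchanged).
    Returns the per-epitope verdicts and the aggregate fraction; an empty
    list is an error (the fraction is undefined).
    """
    epitopes = list(epitopes)
    if not epitopes:
        raise ValueError("cannot screen an empty epitope list")
    feature_names = models.classifier_spec.feature_names
    verdicts = {}
    for seq in epitopes:
        local = None
        rows = []
        for allele in panel:
            values = {}
            for name in feature_names:
                if name in LOCAL_FEATURES:
                    if local is None:
                        local = physchem.physchem_profile(seq).as_dict()
                    values[name] = local[name]
                elif name == RANK_RATIO_FEATURE:
                    values[name] = 1.0
                else:
                    if name not in registry:
                        raise ConfigurationError(
                            f"no predictor bound for feature {name!r}")
                    values[name] = registry[name](seq, allele.name)
            rows.append([float(values[f]) for f in feature_names])
        ids = models.classifier.predict(np.asarray(rows, dtype=float))
        verdicts[seq] = bool((ids == 1).any())
    fraction = sum(verdicts.values()) / len(epitopes)
    return verdicts, fraction
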