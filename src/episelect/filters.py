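"""Exclusion-criteria filtering of epitope–HLA pairs.

A pair survives only if it fails every exclusion rule.  Class-I pairs are
excluded when predicted toxic, short-lived (half-life ≤ 1 h), unstable
(instability index > 40), a probable allergen, or classified ID = 0.
Class-II pairs face the same safety rules plus IFN-γ negativity,
immunogenicity < 50 and antigenicity < 0.4.

Note on the half-life rule: the source criterion is printed as an
exclusion of "> 1 h", which would discard every long-lived peptide and
contradicts both the biology and the companion inclusion criteria; it is
implemented here as *retain* half-life > 1 h (exclude ≤ 1 h).  The
threshold, like every other one, is configurable.

Rules evaluate in a fixed order and a pair failing several is attributed
to the first, so audits are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import yaml

from .core import EhlaPair, EpiselectError
from .predictors import IFNG_NEGATIVE, PROBABLE_ALLERGEN, TOXIN


class MissingFeatureError(EpiselectError):
    """A pair lacks a feature a filter rule needs."""


@dataclass(frozen=True)
class FilterRule:
    """One exclusion criterion: reject when the predicate holds."""

    name: str
    applies_to: str            # "EHLA-I" | "EHLA-II" | "both"
    feature: str
    description: str
    rejects: Callable[[object], bool]
    enabled: bool = True

    def rejects_pair(self, pair: EhlaPair) -> bool:
        if self.feature == "id_label":
            value = pair.id_label
            if value is None:
                raise MissingFeatureError(
                    f"pair {pair.key} has no classifier ID; classify before "
                    "filtering"
                )
        else:
            if self.feature not in pair.features:
                raise MissingFeatureError(
                    f"pair {pair.key} lacks feature {self.feature!r} required "
                    f"by rule {self.name!r}"
                )
            value = pair.features[self.feature]
        return self.rejects(value)


def _toxicity_rule() -> FilterRule:
    return FilterRule(
        "toxicity", "both", "toxicity_label",
        f"exclude pairs labelled {TOXIN!r}",
        lambda v: v == TOXIN,
    )


def _half_life_rule(threshold: float = 1.0) -> FilterRule:
    return FilterRule(
        "half_life", "both", "half_life_hours",
        f"exclude pairs with half-life <= {threshold} h (retain > {threshold} h)",
        lambda v: not (v > threshold),
    )


def _instability_rule(threshold: float = 40.0) -> FilterRule:
    return FilterRule(
        "instability_index", "both", "instability_index",
        f"exclude pairs with instability index > {threshold}",
        lambda v: v > threshold,
    )


def _allergenicity_rule() -> FilterRule:
    return FilterRule(
        "allergenicity", "both", "allergenicity_label",
        f"exclude pairs labelled {PROBABLE_ALLERGEN!r}",
        lambda v: v == PROBABLE_ALLERGEN,
    )


def _ifng_rule() -> FilterRule:
    return FilterRule(
        "ifng", "EHLA-II", "ifng_label",
        f"exclude pairs with IFN-gamma output {IFNG_NEGATIVE!r}",
        lambda v: v == IFNG_NEGATIVE,
    )


def _immunogenicity_rule(threshold: float = 50.0) -> FilterRule:
    return FilterRule(
        "immunogenicity", "EHLA-II", "immunogenicity",
        f"exclude pairs with immunogenicity < {threshold}",
        lambda v: v < threshold,
    )


def _antigenicity_rule(threshold: float = 0.4) -> FilterRule:
    return FilterRule(
        "antigenicity", "EHLA-II", "antigenicity",
        f"exclude pairs with antigenicity < {threshold}",
        lambda v: v < threshold,
    )


def _id_rule() -> FilterRule:
    return FilterRule(
        "id", "EHLA-I", "id_label",
        "exclude pairs classified ID = 0",
        lambda v: v == 0,
    )


def default_class_i_rules() -> list[FilterRule]:
    """Class-I rule sequence, in evaluation (and audit-attribution) order."""
    return [_toxicity_rule(), _half_life_rule(), _instability_rule(),
            _allergenicity_rule(), _id_rule()]


def default_class_ii_rules() -> list[FilterRule]:
    """Class-II rule sequence, in evaluation order."""
    return [_toxicity_rule(), _half_life_rule(), _instability_rule(),
            _allergenicity_rule(), _ifng_rule(), _immunogenicity_rule(),
            _antigenicity_rule()]


def rules_from_yaml(path, mhc_class: str) -> list[FilterRule]:
    """Build a rule list from a YAML override file.

    Recognised keys per rule name: ``enabled`` (bool) and ``threshold``
    (float, for half_life / instability_index / immunogenicity /
    antigenicity).
    """
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    makers = {
        "toxicity": lambda o: _toxicity_rule(),
        "half_life": lambda o: _half_life_rule(o.get("threshold", 1.0)),
        "instability_index": lambda o: _instability_rule(o.get("threshold", 40.0)),
        "allergenicity": lambda o: _allergenicity_rule(),
        "ifng": lambda o: _ifng_rule(),
        "immunogenicity": lambda o: _immunogenicity_rule(o.get("threshold", 50.0)),
        "antigenicity": lambda o: _antigenicity_rule(o.get("threshold", 0.4)),
        "id": lambda o: _id_rule(),
    }
    base = (default_class_i_rules() if mhc_class == "I"
            else default_class_ii_rules())
    out = []
    for rule in base:
        override = cfg.get(rule.name, {})
        if not override.get("enabled", True):
            continue
        out.append(makers[rule.name](override))
    return out


@dataclass
class FilterAudit:
    """Per-rule rejection counts (first-rejecting-rule attribution)."""

    rule_names: list
    rejected_by_rule: dict
    n_input: int
    n_kept: int

    def __post_init__(self) -> None:
        assert self.n_kept + sum(self.rejected_by_rule.values()) == self.n_input

    def as_rows(self) -> list[dict]:
        rows = [
            {"rule": name, "rejected": self.rejected_by_rule[name]}
            for name in self.rule_names
        ]
        rows.append({"rule": "kept", "rejected": self.n_kept})
        return rows


def apply_filters(
    pairs: Sequence[EhlaPair],
    rules: Sequence[FilterRule],
) -> tuple[list[EhlaPair], FilterAudit]:
    """Apply a rule sequence; return survivors and the audit trail."""
    kept: list[EhlaPair] = []
    rejected = {r.name: 0 for r in rules}
    for pair in pairs:
        for rule in rules:
            if rule.rejects_pair(pair):
                rejected[rule.name] += 1
                break
        else:
            kept.append(pair)
    audit = FilterAudit(
        rule_names=[r.name for r in rules],
        rejected_by_rule=rejected,
        n_input=len(pairs),
        n_kept=len(kept),
    )
    return kept, audit


def filter_ehla_i(pairs: Sequence[EhlaPair],
                  rules: Optional[Sequence[FilterRule]] = None):
    """Filter class-I pairs by the default (or supplied) rule sequence."""
    return apply_filters(pairs, rules or default_class_i_rules())


def filter_ehla_ii(pairs: Sequence[EhlaPair],
                   rules: Optional[Sequence[FilterRule]] = None):
    """Filter class-II pairs by the default (or supplied) rule sequence."""
    return apply_filters(pairs, rules or default_class_ii_rules())
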