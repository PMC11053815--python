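"""Population coverage of an epitope–HLA set under an HWE genotype model.

An individual carries two alleles per HLA locus, drawn under
Hardy–Weinberg equilibrium from the regional allele frequencies; mass not
attributed to any listed allele is a residual "other" allele covering
nothing.  An individual's hit count is the number of (epitope, allele)
pairs whose allele is present in their genotype — presence-based, so a
homozygote does not double-count (switchable to dosage counting).
Per-locus hit distributions combine across loci by convolution
(independence between loci; no haplotype linkage).

From the hit distribution the report derives: coverage (probability of at
least one hit), the average hit count, and PC90 — the interpolated hit
count carried by at least 90% of the population.

A set-cover optimizer extracts the fewest pairs whose covered-allele set
(hence coverage) equals the full list's: greedy most-new-alleles-first
with redundancy pruning, replaced by exact branch-and-bound when the
allele universe is small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import EhlaPair, EpiselectError
from .filters import FilterRule, apply_filters


class CoverageError(EpiselectError):
    pass


class AlleleFrequencyTable:
    """Per-region, per-locus HLA allele frequencies.

    Backed by a tidy table with columns region, locus, allele, frequency.
    Frequencies within a locus may sum to less than 1; the shortfall is
    the residual mass of unlisted alleles.  Frequencies are used as given
    — no renormalisation.
    """

    COLUMNS = ["region", "locus", "allele", "frequency"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise CoverageError(f"frequency table lacks columns {missing}")
        table = table.loc[:, self.COLUMNS].copy()
        table["frequency"] = table["frequency"].astype(float)
        if (table["frequency"] < 0).any():
            raise CoverageError("allele frequencies must be >= 0")
        sums = table.groupby(["region", "locus"])["frequency"].sum()
        bad = sums[sums > 1 + 1e-9]
        if not bad.empty:
            raise CoverageError(
                f"per-locus frequencies sum above 1: {bad.to_dict()}"
            )
        self.table = table

    @classmethod
    def from_csv(cls, path) -> "AlleleFrequencyTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def regions(self) -> list[str]:
        return sorted(self.table["region"].unique())

    def loci(self, region: str) -> list[str]:
        sub = self.table[self.table["region"] == region]
        return sorted(sub["locus"].unique())

    def frequencies(self, region: str, locus: str) -> dict[str, float]:
        sub = self.table[
            (self.table["region"] == region) & (self.table["locus"] == locus)
        ]
        return dict(zip(sub["allele"], sub["frequency"]))

    def known_alleles(self, region: str) -> set[str]:
        sub = self.table[self.table["region"] == region]
        return set(sub["allele"])


@dataclass
class HitDistribution:
    """PMF over integer per-individual hit counts 0..H for one region."""

    pmf: np.ndarray
    region: str

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        if (self.pmf < -1e-12).any():
            raise CoverageError("negative probability mass")
        if abs(self.pmf.sum() - 1.0) > 1e-9:
            raise CoverageError(f"PMF sums to {self.pmf.sum()}, not 1")

    def survival(self) -> np.ndarray:
        """S(h) = P(hits >= h) for h = 0..H (S(0) = 1)."""
        return self.pmf[::-1].cumsum()[::-1]


@dataclass
class CoverageReport:
    """Coverage, average hit count and PC90 for one region."""

    region: str
    coverage: float
    average_hit: float
    pc90: float
    n_pairs_assessed: int = 0
    n_pairs_excluded: int = 0


def _locus_hit_pmf(hits_per_allele: dict[str, int],
                   freqs: dict[str, float],
                   dosage: bool = False) -> np.ndarray:
    """Hit-count PMF for one locus by diploid genotype enumeration.

    Genotype (i, j) has HWE probability p_i^2 on the diagonal and
    2·p_i·p_j off it; the residual allele (mass 1 − Σp) covers nothing.
    """
    alleles = sorted(freqs)
    p = np.array([freqs[a] for a in alleles])
    residual = 1.0 - p.sum()
    names = alleles + ["__other__"]
    probs = np.append(p, residual)
    hits = np.array([hits_per_allele.get(a, 0) for a in alleles] + [0])
    max_hits = int(hits.sum()) * 2 if dosage else int(hits.sum())
    pmf = np.zeros(max_hits + 1)
    for i in range(len(names)):
        for j in range(i, len(names)):
            w = probs[i] ** 2 if i == j else 2 * probs[i] * probs[j]
            if w == 0:
                continue
            if dosage:
                h = int(hits[i] + hits[j])
            elif i == j:
                h = int(hits[i])
            else:
                h = int(hits[i] + hits[j])
            pmf[h] += w
    return pmf


def hit_distribution(
    pairs: Sequence[EhlaPair],
    freqs: AlleleFrequencyTable,
    region: str,
    dosage: bool = False,
) -> tuple[HitDistribution, list[EhlaPair]]:
    """Hit distribution for a region; also returns excluded pairs.

    Pairs whose allele is absent from the region's frequency table cannot
    be assessed; they are excluded from the computation and returned so
    callers can report them.
    """
    if region not in freqs.regions:
        raise CoverageError(f"unknown region {region!r}")
    known = freqs.known_alleles(region)
    assessed = [p for p in pairs if p.allele.name in known]
    excluded = [p for p in pairs if p.allele.name not in known]

    # per-locus hit counts: number of assessed pairs at each allele
    per_locus: dict[str, dict[str, int]] = {}
    for p in assessed:
        locus_hits = per_locus.setdefault(p.allele.locus, {})
        locus_hits[p.allele.name] = locus_hits.get(p.allele.name, 0) + 1

    pmf = np.array([1.0])
    for locus in freqs.loci(region):
        locus_pmf = _locus_hit_pmf(
            per_locus.get(locus, {}), freqs.frequencies(region, locus),
            dosage=dosage,
        )
        pmf = np.convolve(pmf, locus_pmf)
    return HitDistribution(pmf=pmf, region=region), excluded


def coverage_metrics(dist: HitDistribution,
                     n_assessed: int = 0, n_excluded: int = 0) -> CoverageReport:
    """Coverage, average hits, and interpolated PC90 from a distribution.

    PC90 interpolates the complementary CDF S(h) = P(hits >= h): with k
    the largest integer where S(k) >= 0.9, PC90 = k + (S(k) − 0.9) /
    (S(k) − S(k+1)), taking S beyond the support as 0.
    """
    pmf = dist.pmf
    coverage = float(1.0 - pmf[0])
    average = float(np.dot(np.arange(len(pmf)), pmf))
    s = dist.survival()
    if coverage == 0.0:
        pc90 = 0.0
    else:
        # largest k with S(k) >= 0.9 (k = 0 always qualifies: S(0) = 1)
        k = int(np.max(np.nonzero(s >= 0.9)[0]))
        s_k = float(s[k])
        s_next = float(s[k + 1]) if k + 1 < len(s) else 0.0
        if s_k == s_next:      # degenerate plateau at exactly 0.9
            pc90 = float(k)
        else:
            pc90 = k + (s_k - 0.9) / (s_k - s_next)
        # the interpolation cannot promise more hits than the support holds
        pc90 = min(pc90, float(len(pmf) - 1))
    return CoverageReport(region=dist.region, coverage=coverage,
                          average_hit=average, pc90=pc90,
                          n_pairs_assessed=n_assessed,
                          n_pairs_excluded=n_excluded)


def region_report(pairs: Sequence[EhlaPair], freqs: AlleleFrequencyTable,
                  region: str, dosage: bool = False) -> CoverageReport:
    dist, excluded = hit_distribution(pairs, freqs, region, dosage=dosage)
    return coverage_metrics(dist, n_assessed=len(pairs) - len(excluded),
                            n_excluded=len(excluded))


@dataclass
class RegionalSummary:
    """Per-region coverage reports plus their unweighted averages."""

    reports: list
    average_coverage: float
    world: Optional[CoverageReport] = None


def regional_summary(
    pairs: Sequence[EhlaPair],
    freqs: AlleleFrequencyTable,
    regions: Optional[Sequence[str]] = None,
    world_region: str = "World",
) -> RegionalSummary:
    """Coverage per region and the unweighted mean of regional coverages.

    The world report, when the table has a world entry, comes from the
    world frequencies directly — never from averaging regions.
    """
    if regions is None:
        regions = [r for r in freqs.regions if r != world_region]
    if not regions:
        raise CoverageError("no regions to summarise")
    reports = [region_report(pairs, freqs, r) for r in regions]
    world = (region_report(pairs, freqs, world_region)
             if world_region in freqs.regions else None)
    avg = float(np.mean([r.coverage for r in reports]))
    return RegionalSummary(reports=reports, average_coverage=avg, world=world)


def summary_table(summary: RegionalSummary) -> pd.DataFrame:
    rows = [
        {"region": r.region, "coverage_pct": 100 * r.coverage,
         "average_hit": r.average_hit, "pc90": r.pc90}
        for r in summary.reports
    ]
    if summary.world is not None:
        rows.append({"region": summary.world.region,
                     "coverage_pct": 100 * summary.world.coverage,
                     "average_hit": summary.world.average_hit,
                     "pc90": summary.world.pc90})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Minimal-set optimization (set cover over covered alleles)
# ---------------------------------------------------------------------------

def _pair_sort_key(pair: EhlaPair) -> tuple:
    score = pair.score if pair.score is not None else float("-inf")
    return (-score, pair.epitope.mutant_sequence, pair.allele.name)


def _exact_min_cover(items: list[tuple[frozenset, int]],
                     universe: frozenset) -> list[int]:
    """Branch-and-bound exact minimum set cover; returns item indices.

    Items are (allele_set, original_index) and are pre-sorted by the
    greedy preference order, so the first optimum found respects the
    deterministic tie-break.
    """
    best: list[int] = [i for _, i in items]
    suffix_reach: list[frozenset] = [frozenset()] * (len(items) + 1)
    for pos in range(len(items) - 1, -1, -1):
        suffix_reach[pos] = suffix_reach[pos + 1] | items[pos][0]

    def recurse(chosen: list[int], covered: frozenset, start: int) -> None:
        nonlocal best
        if covered == universe:
            if len(chosen) < len(best):
                best = list(chosen)
            return
        # any completion needs >= 1 more item; prune if it cannot improve
        if len(chosen) + 1 >= len(best):
            return
        # prune if the remaining items cannot cover what is left
        if not (universe - covered) <= suffix_reach[start]:
            return
        for pos in range(start, len(items)):
            s, idx = items[pos]
            if s - covered:
                chosen.append(idx)
                recurse(chosen, covered | s, pos + 1)
                chosen.pop()

    recurse([], frozenset(), 0)
    return best


def minimal_cover(
    covers: Sequence[frozenset],
    order: Sequence[int],
    exact_threshold: int = 20,
) -> list[int]:
    """Indices of a minimum-cardinality subset whose union covers the union.

    ``order`` is the deterministic preference order used for tie-breaks.
    Exact branch-and-bound when the universe has at most
    ``exact_threshold`` elements; otherwise greedy most-new-first plus
    redundancy pruning.
    """
    if not covers:
        return []
    universe = frozenset().union(*covers)
    if not universe:
        return []

    if len(universe) <= exact_threshold:
        # items with identical cover sets are interchangeable; keep only
        # the first in preference order so the search stays small
        items, seen = [], set()
        for i in order:
            if covers[i] and covers[i] not in seen:
                seen.add(covers[i])
                items.append((covers[i], i))
        return _exact_min_cover(items, universe)

    chosen: list[int] = []
    covered: frozenset = frozenset()
    while covered != universe:
        # most new alleles first; ties resolved by the preference order
        gain = max(len(covers[i] - covered) for i in order)
        if gain == 0:
            break
        best_i = next(i for i in order if len(covers[i] - covered) == gain)
        chosen.append(best_i)
        covered = covered | covers[best_i]

    # redundancy pruning: drop items whose cover is contained in the rest
    pruned = list(chosen)
    for i in list(pruned):
        rest = frozenset().union(
            *[covers[j] for j in pruned if j != i]) if len(pruned) > 1 \
            else frozenset()
        if covers[i] <= rest:
            pruned.remove(i)
    return pruned


def optimize_minimal_set(
    pairs: Sequence[EhlaPair],
    exact_threshold: int = 20,
    group_by_epitope: bool = False,
) -> list[EhlaPair]:
    """Smallest subset of pairs covering the same allele set as the input.

    Because coverage is a function of the covered-allele set alone, the
    optimized subset has population coverage identical to the full input
    in every region.  By default each pair is a selectable unit covering
    its own allele; with ``group_by_epitope`` the unit is an epitope
    sequence covering every allele it pairs with, and all pairs of the
    chosen epitopes are returned.  Preference order for ties: higher
    score, then lexicographic (epitope, allele).
    """
    pairs = list(pairs)
    if not pairs:
        return []
    if group_by_epitope:
        groups: dict[str, list[int]] = {}
        for i, p in enumerate(pairs):
            groups.setdefault(p.epitope.mutant_sequence, []).append(i)
        keys = sorted(
            groups,
            key=lambda s: (min(_pair_sort_key(pairs[i]) for i in groups[s]), s),
        )
        covers = [frozenset(pairs[i].allele.name for i in groups[k])
                  for k in keys]
        chosen = minimal_cover(covers, range(len(keys)), exact_threshold)
        idx = sorted(i for c in chosen for i in groups[keys[c]])
        return [pairs[i] for i in idx]

    order = sorted(range(len(pairs)), key=lambda i: _pair_sort_key(pairs[i]))
    covers = [frozenset({p.allele.name}) for p in pairs]
    chosen = minimal_cover(covers, order, exact_threshold)
    return [pairs[i] for i in sorted(chosen,
                                     key=lambda i: _pair_sort_key(pairs[i]))]


def covered_alleles(pairs: Iterable[EhlaPair]) -> set[str]:
    return {p.allele.name for p in pairs}


# ---------------------------------------------------------------------------
# Stepwise filter-coverage audit
# ---------------------------------------------------------------------------

@dataclass
class StepwiseRow:
    rule: str
    n_pairs: int
    report: CoverageReport
    coverage_dropped: bool


def stepwise_filter_coverage(
    pairs: Sequence[EhlaPair],
    freqs: AlleleFrequencyTable,
    rules: Sequence[FilterRule],
    region: str = "World",
) -> list[StepwiseRow]:
    """Coverage after each cumulative exclusion rule.

    Row 0 is the unfiltered input; each subsequent row applies one more
    rule.  The first rule (if any) that reduces coverage relative to the
    previous step is flagged.
    """
    rows = []
    current = list(pairs)
    report = region_report(current, freqs, region)
    rows.append(StepwiseRow("(none)", len(current), report, False))
    prev_cov = report.coverage
    for rule in rules:
        current, _ = apply_filters(current, [rule])
        report = region_report(current, freqs, region)
        dropped = report.coverage < prev_cov - 1e-12
        rows.append(StepwiseRow(rule.name, len(current), report, dropped))
        prev_cov = report.coverage
    return rows


def stepwise_table(rows: Sequence[StepwiseRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"rule": r.rule, "n_pairs": r.n_pairs,
          "coverage_pct": 100 * r.report.coverage,
          "average_hit": r.report.average_hit,
          "pc90": r.report.pc90,
          "coverage_dropped": r.coverage_dropped}
         for r in rows]
    )
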