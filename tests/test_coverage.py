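"""Population coverage: HWE genotype model, PC90, set-cover optimizer."""

import itertools

import numpy as np
import pandas as pd
import pytest

from episelect.coverage import (
    AlleleFrequencyTable,
    CoverageError,
    HitDistribution,
    coverage_metrics,
    covered_alleles,
    hit_distribution,
    optimize_minimal_set,
    region_report,
    regional_summary,
    stepwise_filter_coverage,
)
from episelect.filters import default_class_i_rules

from conftest import make_pair


def freq_table(rows):
    return AlleleFrequencyTable(
        pd.DataFrame(rows, columns=["region", "locus", "allele", "frequency"]))


def single_locus_table(freqs, region="World", locus="A"):
    return freq_table([(region, locus, a, f) for a, f in freqs.items()])


def pair_on(allele, locus="A", score=None, seq="AAAACAAAA"):
    return make_pair(seq, allele_name=allele, locus=locus, score=score)


# ---------------------------------------------------------------------------
# Brute-force oracle: joint enumeration over multi-locus genotypes
# ---------------------------------------------------------------------------

def brute_force_pmf(hits_by_locus, freqs_by_locus):
    """Enumerate every combination of per-locus diploid genotypes."""
    loci = sorted(freqs_by_locus)
    genotype_sets = []
    for locus in loci:
        freqs = freqs_by_locus[locus]
        names = sorted(freqs) + ["other"]
        probs = {a: freqs[a] for a in sorted(freqs)}
        probs["other"] = 1.0 - sum(freqs.values())
        genos = []
        for i, a in enumerate(names):
            for b in names[i:]:
                w = probs[a] ** 2 if a == b else 2 * probs[a] * probs[b]
                genos.append((frozenset((a, b)), w))
        genotype_sets.append(genos)
    total_hits = sum(sum(h.values()) for h in hits_by_locus.values())
    pmf = np.zeros(total_hits + 1)
    for combo in itertools.product(*genotype_sets):
        weight = 1.0
        hits = 0
        for locus, (genotype, w) in zip(loci, combo):
            weight *= w
            hits += sum(hits_by_locus.get(locus, {}).get(a, 0)
                        for a in genotype)
        pmf[hits] += weight
    return pmf


class TestHitDistribution:
    def test_single_epitope_single_allele_analytic(self):
        table = single_locus_table({"X": 0.5})
        dist, excluded = hit_distribution([pair_on("X")], table, "World")
        assert excluded == []
        # genotypes {XX: .25, Xo: .5, oo: .25}; X present with prob .75
        assert dist.pmf == pytest.approx([0.25, 0.75])

    def test_two_epitopes_same_allele_presence_counting(self):
        table = single_locus_table({"X": 0.5})
        pairs = [pair_on("X", seq="AAAACAAAA"), pair_on("X", seq="CCCCACCCC")]
        dist, _ = hit_distribution(pairs, table, "World")
        assert dist.pmf == pytest.approx([0.25, 0.0, 0.75])

    def test_homozygote_double_counts_in_dosage_mode(self):
        table = single_locus_table({"X": 0.5})
        dist, _ = hit_distribution([pair_on("X")], table, "World",
                                   dosage=True)
        # XX -> 2 hits (.25), Xo -> 1 (.5), oo -> 0 (.25)
        assert dist.pmf == pytest.approx([0.25, 0.5, 0.25])

    def test_no_pairs_is_point_mass_at_zero(self):
        table = single_locus_table({"X": 0.5})
        dist, _ = hit_distribution([], table, "World")
        assert dist.pmf == pytest.approx([1.0])

    def test_unknown_allele_excluded_and_reported(self):
        table = single_locus_table({"X": 0.5})
        pairs = [pair_on("X"), pair_on("Y")]
        dist, excluded = hit_distribution(pairs, table, "World")
        assert [p.allele.name for p in excluded] == ["Y"]
        assert dist.pmf == pytest.approx([0.25, 0.75])

    def test_unknown_region(self):
        table = single_locus_table({"X": 0.5})
        with pytest.raises(CoverageError, match="region"):
            hit_distribution([], table, "Atlantis")

    def test_convolution_equals_joint_enumeration(self):
        rng = np.random.default_rng(123)
        loci = ["A", "B", "DQ"]
        for trial in range(60):
            n_loci = int(rng.integers(1, 4))
            freqs_by_locus = {}
            hits_by_locus = {}
            rows = []
            pairs = []
            for locus in loci[:n_loci]:
                n_alleles = int(rng.integers(1, 5))
                raw = rng.dirichlet(np.ones(n_alleles)) * rng.uniform(0.5, 1.0)
                names = [f"{locus}-{i}" for i in range(n_alleles)]
                freqs_by_locus[locus] = dict(zip(names, raw))
                hits_by_locus[locus] = {}
                rows += [("R", locus, n, f)
                         for n, f in freqs_by_locus[locus].items()]
                for i, name in enumerate(names):
                    k = int(rng.integers(0, 3))
                    if k:
                        hits_by_locus[locus][name] = k
                    for j in range(k):
                        pairs.append(make_pair(
                            f"AAAA{'CDEFGHIKL'[i]}AAAA" + ("AAAAAA" if locus == "DQ" else ""),
                            allele_name=name, locus=locus,
                            mhc_class="II" if locus == "DQ" else "I",
                            score=float(j)))
            table = freq_table([("R", l, a, f) for (_, l, a, f) in rows])
            dist, _ = hit_distribution(pairs, table, "R")
            oracle = brute_force_pmf(hits_by_locus, freqs_by_locus)
            n = max(len(dist.pmf), len(oracle))
            got = np.pad(dist.pmf, (0, n - len(dist.pmf)))
            want = np.pad(oracle, (0, n - len(oracle)))
            assert np.max(np.abs(got - want)) < 1e-12


class TestCoverageMetrics:
    def test_point_mass_at_zero(self):
        rep = coverage_metrics(HitDistribution(np.array([1.0]), "World"))
        assert (rep.coverage, rep.average_hit, rep.pc90) == (0.0, 0.0, 0.0)

    def test_analytic_single_epitope_case(self):
        table = single_locus_table({"X": 0.5})
        rep = region_report([pair_on("X")], table, "World")
        assert rep.coverage == pytest.approx(0.75)
        assert rep.average_hit == pytest.approx(0.75)
        assert rep.pc90 == pytest.approx((1 - 0.9) / (1 - 0.75))

    def test_exact_crossing(self):
        # S(1) = 1, S(2) = 0.9 -> PC90 = 2.0 exactly
        pmf = np.array([0.0, 0.1, 0.9])
        rep = coverage_metrics(HitDistribution(pmf, "World"))
        assert rep.pc90 == pytest.approx(2.0)

    def test_pc90_bounds_and_link_to_coverage(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            pmf = rng.dirichlet(np.ones(int(rng.integers(2, 8))))
            rep = coverage_metrics(HitDistribution(pmf, "r"))
            assert rep.pc90 <= len(pmf) - 1
            assert (rep.pc90 < 1) == (rep.coverage < 0.9)

    def test_coverage_monotone_in_added_pairs(self):
        table = single_locus_table({"X": 0.3, "Y": 0.4})
        base = [pair_on("X")]
        more = base + [pair_on("Y")]
        assert region_report(more, table, "World").coverage \
            >= region_report(base, table, "World").coverage

    def test_average_hit_additive_over_disjoint_allele_sets(self):
        table = single_locus_table({"X": 0.3, "Y": 0.4})
        a = [pair_on("X")]
        b = [pair_on("Y")]
        ra = region_report(a, table, "World").average_hit
        rb = region_report(b, table, "World").average_hit
        rab = region_report(a + b, table, "World").average_hit
        assert rab == pytest.approx(ra + rb, abs=1e-12)


class TestRegionalSummary:
    def test_single_region_average_is_itself(self):
        table = freq_table([("World", "A", "X", 0.5), ("Europe", "A", "X", 0.5)])
        summary = regional_summary([pair_on("X")], table)
        assert summary.average_coverage == pytest.approx(
            summary.reports[0].coverage)

    def test_average_is_unweighted_and_world_is_direct(self):
        table = freq_table([
            ("World", "A", "X", 0.5),
            ("R1", "A", "X", 0.1),
            ("R2", "A", "X", 0.9),
        ])
        summary = regional_summary([pair_on("X")], table)
        covs = {r.region: r.coverage for r in summary.reports}
        assert summary.average_coverage == pytest.approx(
            (covs["R1"] + covs["R2"]) / 2)
        assert summary.world.coverage == pytest.approx(0.75)

    def test_region_missing_locus_contributes_no_hits(self):
        table = freq_table([
            ("World", "A", "X", 0.5), ("World", "B", "Z", 0.5),
            ("R1", "A", "X", 0.5),
        ])
        pairs = [pair_on("X"), pair_on("Z", locus="B")]
        r1 = region_report(pairs, table, "R1")
        assert r1.n_pairs_excluded == 1       # the B pair cannot be assessed


# ---------------------------------------------------------------------------
# Minimal-set optimization
# ---------------------------------------------------------------------------

def exhaustive_min_cover_size(cover_sets):
    universe = frozenset().union(*cover_sets)
    for size in range(len(cover_sets) + 1):
        for combo in itertools.combinations(range(len(cover_sets)), size):
            if frozenset().union(*(cover_sets[i] for i in combo),
                                 frozenset()) == universe:
                return size
    return len(cover_sets)


class TestOptimizeMinimalSet:
    def test_epitope_covering_both_alleles_wins(self):
        # epitopes e1 -> {A1}, e2 -> {A2}, e3 -> {A1, A2}
        pairs = [
            pair_on("A1", seq="AAAACAAAA"),
            pair_on("A2", seq="CCCCACCCC"),
            pair_on("A1", seq="DDDDADDDD"),
            pair_on("A2", seq="DDDDADDDD"),
        ]
        minimal = optimize_minimal_set(pairs, group_by_epitope=True)
        assert {p.epitope.mutant_sequence for p in minimal} == {"DDDDADDDD"}
        assert covered_alleles(minimal) == covered_alleles(pairs)

    def test_identical_singleton_covers_pick_highest_score(self):
        pairs = [pair_on("X", score=0.1, seq="AAAACAAAA"),
                 pair_on("X", score=0.9, seq="CCCCACCCC")]
        minimal = optimize_minimal_set(pairs)
        assert len(minimal) == 1
        assert minimal[0].score == 0.9

    def test_empty_input(self):
        assert optimize_minimal_set([]) == []

    @pytest.mark.parametrize("exact_threshold", [20, 0])
    def test_matches_exhaustive_on_random_instances(self, exact_threshold):
        rng = np.random.default_rng(31)
        seqs = ["AAAA%cAAAA" % c for c in "CDEFGHIKLMNP"]
        for trial in range(60):
            n_alleles = int(rng.integers(1, 9))
            n_pairs = int(rng.integers(1, 13))
            alleles = [f"AL{i}" for i in range(n_alleles)]
            pairs = [pair_on(str(rng.choice(alleles)),
                             seq=seqs[i], score=float(rng.random()))
                     for i in range(n_pairs)]
            minimal = optimize_minimal_set(pairs,
                                           exact_threshold=exact_threshold)
            assert covered_alleles(minimal) == covered_alleles(pairs)
            optimum = exhaustive_min_cover_size(
                [frozenset({p.allele.name}) for p in pairs])
            if exact_threshold >= n_alleles:
                assert len(minimal) == optimum
            else:
                assert len(minimal) <= optimum + 1

    def test_optimized_coverage_equals_full_coverage(self):
        rng = np.random.default_rng(32)
        for trial in range(20):
            n_alleles = int(rng.integers(2, 7))
            raw = rng.dirichlet(np.ones(n_alleles)) * 0.9
            names = [f"AL{i}" for i in range(n_alleles)]
            table = single_locus_table(dict(zip(names, raw)))
            pairs = [pair_on(str(rng.choice(names)),
                             seq="AAAA%cAAAA" % "CDEFGHIKLM"[i])
                     for i in range(int(rng.integers(1, 11)))]
            minimal = optimize_minimal_set(pairs)
            assert region_report(minimal, table, "World").coverage \
                == pytest.approx(region_report(pairs, table, "World").coverage,
                                 abs=1e-12)


class TestStepwiseCoverage:
    def _pairs(self):
        clean = {"toxicity_label": "Non-Toxin", "half_life_hours": 5.0,
                 "instability_index": 20.0,
                 "allergenicity_label": "Probable Non-Allergen"}
        a = make_pair("AAAACAAAA", "X", features=dict(clean), id_label=1)
        b = make_pair("CCCCACCCC", "Y", features=dict(clean), id_label=1)
        return a, b

    def test_no_rejections_constant_rows(self):
        table = single_locus_table({"X": 0.3, "Y": 0.3})
        rows = stepwise_filter_coverage(list(self._pairs()), table,
                                        default_class_i_rules(), "World")
        assert len(rows) == 6
        assert len({round(r.report.coverage, 12) for r in rows}) == 1
        assert not any(r.coverage_dropped for r in rows)

    def test_rule_removing_sole_allele_pair_flagged(self):
        a, b = self._pairs()
        b.features["toxicity_label"] = "Toxin"      # only pair on allele Y
        table = single_locus_table({"X": 0.3, "Y": 0.3})
        rows = stepwise_filter_coverage([a, b], table,
                                        default_class_i_rules(), "World")
        by_rule = {r.rule: r for r in rows}
        assert by_rule["toxicity"].coverage_dropped
        assert by_rule["toxicity"].n_pairs == 1
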