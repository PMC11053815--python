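# Methods

This note records the models, conventions and numerical choices behind
`episelect`, and what the synthetic test regime does and does not
establish about real data.

## Epitope enumeration

A missense mutation at 1-based position *p* of a protein of length *N*
yields, for each window length *L*, the candidate windows with start
*s* ∈ [max(1, p−L+1), min(p, N−L+1)] — every window fully inside the
protein that contains the mutated residue. An interior mutation therefore
yields *L* windows per length; near a terminus the count shrinks. Each
candidate carries its matched wild-type window (identical except at the
mutation offset), which is what the wild-type:mutant rank ratio is
computed from.

Default lengths are {9, 10} for class I and {15} for class II, both
configurable. Class-I 9/10-mers are the dominant lengths bound by HLA-A/B
grooves and are consistent with published per-mutation candidate counts
(19 windows per interior mutation); 15-mers are the standard class-II
survey length. No authoritative length policy exists for the reference
analyses this pipeline descends from, so the defaults are explicit
configuration, not constants. Duplicate peptides arising from different
mutations (or the same mutation in two disease contexts) are retained:
each run is an independent analysis. Non-canonical residues (X, U, B, Z)
are rejected at parse time rather than skipped, and a wild-type mismatch
between a token and the protein aborts the run naming the token — it
almost always means a wrong isoform or off-by-one coordinates.

## Local descriptors

* **Hydropathicity** is the *positional* Kyte–Doolittle sum over residues
  4 … n−1 (1-based, inclusive), not the mean: the terminal anchor
  positions, which binding predictors already capture, are deliberately
  excluded. Sequences shorter than 5 residues are an error rather than 0;
  epitopes here are ≥ 9-mers, so the bound never binds in practice.
* **GRAVY, instability index, isoelectric point** follow the ProtParam
  conventions via Biopython (Kyte–Doolittle table, Guruprasad DIWV
  400-entry dipeptide table, Bjellqvist pKa set). The pI bisection runs
  over the full 0–14 pH bracket (the library default window [4.05, 12]
  clips strongly acidic or basic peptides) to a tolerance well below the
  1e-3 the tests assert.
* **Aliphatic index**: 100·X_Ala + 2.9·100·X_Val + 3.9·100·(X_Ile +
  X_Leu) over mole fractions.
* **N-end-rule half-life** is a lookup on the N-terminal residue from the
  mammalian-reticulocyte in-vitro table (shipped as CSV; proline's
  "> 20 h" is recorded as 20). Hours are the canonical unit because the
  downstream exclusion threshold is 1 h.
* **ACC antigenicity**: the three Hellberg z-scale series of a peptide
  are centred on their per-sequence means and the auto-/cross-covariance
  terms A_jk(l) = Σ_i z̃_j(i)·z̃_k(i+l)/(n−l) are flattened (lag
  outermost, then j, then k; default lag 1 for short peptides, giving 9
  terms). The scalar antigenicity score is a configurable linear read-out
  over the terms, defaulting to their mean. The read-out weights are a
  pluggable asset — the package makes no claim that the default
  reproduces any particular published antigenicity server, which is why
  the mock registry, not the ACC read-out, backs the `antigenicity`
  feature in default pipeline runs.

## Predictor registry

Binding rank/affinity, stability, immunogenicity, toxicity, allergenicity
and IFN-γ predictions come from specialised external tools whose
internals are out of scope here. Each feature is a contract
`(epitope_sequence, allele_name) → value` with three backends: seeded
SHA-256-hash mocks (pure, deterministic, values in each feature's
plausible range — ranks in (0, 100], stability in (0, 12] h, labels from
a seeded Bernoulli), a strict-schema CSV of precomputed scores, or a user
callable. With mocks and a fixed seed an end-to-end run is
byte-reproducible, which the tests assert. The class-II immunogenicity
score is treated as an opaque real filtered at 50, since its producing
tool and scale are not pinned down by the reference analyses.

## ML layer

The training table is ~1:6 positive:negative (defaults 109/654). Folds
are stratified (class ratio preserved within ±1 per fold) and classes are
left unweighted — no resampling is applied because none is documented for
the reference models. Classifier families report accuracy, PPV and TPR
from the 0/1 predictions; a fold with zero positive predictions has
undefined PPV, which is recorded as NaN, excluded from the fold mean, and
warned about. Regression families are scored by ROC AUC of their
continuous predictions against the binary labels; the linear-regression
ranker is fit on the 0/1 label directly (the only reading under which an
ROC of its predictions is meaningful) and its scores are not clipped to
[0, 1]. Logistic regression ranks by positive-class probability; its
known failure mode — nearly all scores exactly 0 or 1, useless for
ordering — is detected and warned about when > 50% of scores are within
1e-6 of a binary value.

The feature-combination search evaluates every non-empty subset of the
7-feature candidate pool (127 subsets) unless an explicit list is given;
the best subset maximises mean accuracy (classifiers) or mean AUC
(regressors) with ties broken by fewer features, then lexicographic
names. RF defaults: 100 trees, unlimited depth, seeded; MLP and logistic
get `max_iter` raised to 1000 so convergence is not seed-dependent.
Impurity-based RF importances are normalised to sum to 1.

Bare peptides screened without a matched wild-type window get a rank
ratio of 1.0 (binding unchanged by definition of "no mutation").

## Exclusion filters

Rules evaluate in a fixed order (toxicity, half-life, instability,
allergenicity, then ID for class I; the safety rules then IFN-γ,
immunogenicity, antigenicity for class II) and a pair failing several is
attributed to the first, making audits reproducible. Thresholds are
strict as printed — instability > 40 rejects, so 40.0 survives;
immunogenicity < 50 rejects, so 50.0 survives; antigenicity < 0.4
rejects, so 0.4 survives.

**Half-life caveat**: the source criterion table lists "half-life > 1 h"
in its exclusion column, which would discard every stable peptide. That
contradicts the biology (short-lived peptides are the undesirable ones)
and the same group's earlier inclusion criteria, so this package
implements *retain half-life > 1 h* (exclude ≤ 1 h). The interpretation
is configurable via the YAML rule overrides, as are all thresholds and
per-rule enable flags.

No binding-rank cutoff is applied to either class before filtering: class
I is gated by the classifier ID, and no class-II rank cutoff is
documented for the reference analyses.

## Population coverage

Per HLA locus, diploid genotypes follow Hardy–Weinberg equilibrium over
the regional allele frequencies: genotype (i, j) has probability p_i² on
the diagonal and 2·p_i·p_j off it. Listed frequencies at a locus may sum
to less than 1; the shortfall is an explicit residual allele covering
nothing (no renormalisation — an under-typed population really is
under-covered). An individual's hit count sums, over the alleles present
in their genotype, the number of selected pairs at each allele —
presence-based, so homozygotes do not double-count (a dosage-based switch
exists). Loci combine by convolution, i.e. independence; haplotype
linkage is not modelled. Class-I loci are A and B; class II pools DRB1/3/4/5
as separate loci of the DR region and treats paired α/β DP and DQ names
as single units at one locus each, matching how panel alleles are named.
Pairs whose allele a region's table does not type are excluded from that
region's computation and reported, mirroring the real situation where
class-II population data covers only part of a pair list.

Metrics: coverage = 1 − P(0 hits); average hit = E[hits]; PC90
interpolates the complementary CDF S(h) = P(hits ≥ h) — with k the
largest integer where S(k) ≥ 0.9, PC90 = k + (S(k) − 0.9)/(S(k) −
S(k+1)), with S beyond the support taken as 0. Two edge cases the formula
leaves open are resolved by the quantity's meaning: zero coverage gives
PC90 = 0, and the interpolated value is capped at the maximum hit count.
The exact interpolation used by the public population-coverage servers is
undocumented; this formula is a recorded dialect choice, and equality
with server-printed fractional PC90 values is not promised. The regional
average is the unweighted arithmetic mean of regional coverages; the
world figure always comes from the world frequency entry, never from
averaging regions.

**Minimal-set optimization** is set cover over covered alleles: the
smallest subset of pairs whose covered-allele set equals the full list's.
Because every coverage quantity is a function of that set (each pair
covers its one allele; hit counts differ but presence does not), the
optimized subset provably has identical coverage in every region — which
the tests verify against brute force. Greedy most-new-alleles-first with
redundancy pruning handles large universes; an exact branch-and-bound
(deduplicated by cover set, preference-ordered so ties resolve to higher
score then lexicographic pair key) runs whenever the universe has ≤ 20
alleles, which covers the shipped panels. An epitope-grouped mode treats
each epitope sequence as one unit covering all its alleles.

The stepwise audit re-evaluates coverage after each cumulative exclusion
rule and flags the first rule, if any, that reduces it.

## Synthetic study conditions

The training generator draws positives with log-normal binding ranks
centred near the 1st percentile (σ = 0.9), gamma-distributed stability
around 6 h, log-normal rank ratios centred near 2, and antigenicity /
immunogenicity shifted up by roughly 1.5 standard deviations; negatives
have uniform ranks on (0, 100], short stabilities and unshifted scores.
One percent of labels are flipped so the problem is not separable. Under
these defaults the cross-validated RF classifier averages ≈ 0.95–0.98
accuracy and ≈ 0.9 TPR across seeds — the same performance regime as the
experimentally trained reference models, attainable but not trivially
perfect. These distributions are a modelling choice, not an estimate of
the real data-generating process: passing the synthetic-regime tests
shows the pipeline machinery (folding, metrics, search, filtering,
coverage) is correct, not that the shipped defaults would reach the same
numbers on experimental TIL data. The generators do not model MHC binding
motifs, proteome background composition, or linkage between HLA loci.

Problem sizes in the test suite and acceptance script (proteins of
120–300 residues, 5–12 mutations, 1–3 loci with ≤ 4 alleles for the
brute-force coverage oracles, 200 random set-cover instances) were chosen
so every brute-force oracle remains exhaustively checkable; the pipeline
itself scales linearly in mutations × lengths × panel size.

## Known limitations

* Frameshifts, insertions and deletions are unsupported by design; only
  single-residue missense mutations are modelled.
* The default antigenicity read-out and all mock predictors are
  placeholders for real external predictions; scientific conclusions
  require the CSV registry filled from the actual tools.
* Coverage treats loci independently (HWE within, independence between);
  real populations show linkage disequilibrium across HLA loci.
* PC90 values are dialect-dependent near interpolation boundaries (see
  above).
* The reference-reproduction tests need the published experimental
  training table and mutation lists (journal supplementary material)
  under `data/external/`; without them they report failure with
  instructions rather than silently passing.
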