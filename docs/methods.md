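# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `barcodiv`.

## The synthetic survey generator

The generator (`barcodiv.simulate`) emulates the structure of a
singleton-heavy tropical barcoding survey so that every downstream stage
can be validated against known truth. It produces a community, a
genealogy, an aligned sequence set and error-perturbed morphospecies
labels. Every stage draws from its own generator seeded deterministically
from `SimParams.seed`.

**Community.** Rank abundances follow a geometric (Motomura) series
realized by largest-remainder rounding to the specimen total, with every
species forced to at least one specimen. The series parameter is found by
bisection until the singleton fraction lies within ±5 percentage points
of `target_singleton_fraction` (default 0.526); if the community is too
small for the target to be representable the generator fails loudly,
naming the best achieved fraction. Defaults — 266 species, 674
specimens — match the scale of a real montane leaf-beetle survey.
Species are confined to a single elevational level with probability
`turnover_prob` (default 0.92, i.e. near-complete turnover; the remainder
span two adjacent levels), levels weighted 0.23/0.55/0.22 to mimic uneven
sampling effort across 1000/2000/3000 m. Each level carries six sampling
units per standardized method (sweep-netting, beating, hand collection)
plus one light and one Malaise unit, exercising the method filter used by
the richness stage.

**Genealogy.** A Yule species tree (dendropy's birth–death simulator,
zero extinction) is normalized to root age 1. Speciation-node ages are
then mapped affinely onto [`min_species_age_fraction`, 1] (default floor
0.15): local communities of well-differentiated species show deep
interspecific divergence, and the floor realizes the "barcoding gap"
that a Yule process run to the present would blur. Within each species a
Kingman coalescent with Ne = `within_species_coalescent_scale`/2 is
grafted onto the terminal branch; its TMRCA is capped at 95% of the
attachment age so species subtrees are always younger than their stems.
The scale default (0.015, i.e. within-species depths ~1.5% of the tree
depth) was calibrated so that a survey-scale simulation reproduces the
haplotype-to-specimen ratio of real COI surveys (~0.63 distinct
haplotypes per specimen, with ~70% of haplotypes occurring once).

**Sequences.** Jukes–Cantor evolution of a uniform random root sequence:
on a branch of duration t each site changes with probability
(3/4)(1 − e^(−4μt/3)). The default rate μ = 0.15 per site per unit tree
depth yields intraspecific p-distances of a few tenths of a percent and
interspecific distances of ~4.5–25%, the regime of COI barcodes within
one family. Sequences are emitted already aligned; no indels are
simulated (real surveys analyse a fixed-length alignment).

**Morphospecies error.** Starting from the true partition, each
multi-specimen species is split into two labels with probability
`split_rate` (random bipartition, both halves non-empty) and disjoint
consecutive species pairs — consecutive in the genealogy's tip order, a
proxy for morphological similarity of close relatives — are merged with
probability `lump_rate` (defaults 0.10/0.10, giving morphospecies error
of the magnitude seen when parataxonomic sorting is checked against
molecular data). When a lumped partner was itself split, the partner is
absorbed into its first split label.

**What the generator does not emulate.** Sampling bias of trap types,
migration between levels, rate variation across sites or lineages,
indels, sequencing error, and tree-inference error: downstream methods
receive the *true* genealogy (time-scaled or substitution-scaled).
Passing tests therefore demonstrate correctness of the delimitation and
richness machinery under the stated model, not robustness to alignment
or phylogenetic error.

## Delimitation methods

**Connection limit.** The statistical-parsimony criterion is anchored by
a finite-sites uniform-hit model: j substitutions placed independently
and uniformly on m sites are homoplasy-free exactly when they strike j
distinct sites, P(j) = prod_{i=1}^{j-1} (1 − i/m); the limit is the
largest j with P(j) ≥ confidence (8 steps at 658 bp and 95%). Published
network programs use a related parsimony-probability calculation that
typically prints 9–10 steps at this length; a fixed `max_steps` override
reproduces any desired limit. Networks are connected components of the
haplotype graph under the step limit (steps = raw mismatches under
pairwise deletion); internal unsampled intermediates are not
reconstructed, since only the grouping matters here.

**Distance clustering** uses strict `<` against the threshold (following
the usual "distances below this threshold" phrasing) and transitive
closure; component labels are assigned by each component's smallest
specimen id for deterministic output.

**GMYC.** Candidate thresholds are midpoints between consecutive
distinct node ages, plus the boundary configurations (one entity;
every tip separate). The likelihood is the product of b·exp(−b·x) over
inter-event waiting intervals only; the interval straddling a candidate
threshold is split into two exposure segments at the threshold. The null
model is a single branching process b = λ[n(n−1)]^p over the whole tree;
because the one-entity configuration is part of the scan, LR ≥ 0 holds
structurally. Rates are log10-parameterized in [1e−8, 1e4] and exponents
bounded in [0.1, 2]; optimization is bounded Nelder–Mead with a
warm-start chain along the threshold scan (each candidate starts from
its neighbour's optimum, which tracks the likelihood ridge) followed by
5-start refinement of the ten best candidates. Ties are broken toward
fewer entities (older thresholds are scanned first and must be beaten by
more than 1e−9 log-units). The LRT p-value uses χ² with df = 3 by
default; the appropriate reference distribution for the single-threshold
test is unsettled in the literature, so `df` is an argument. Measured on
single-species coalescent genealogies (40 tips), the test's type-I error
at nominal 5% is ~6%.

**PTP.** The two-class exponential model's profile log-likelihood per
class is k(log(k/S) − 1); an empty class contributes nothing, and class
sums are floored at 1e−12 to tolerate zero-length branches. Trees with
all branch lengths equal are flagged degenerate and returned as one
species. Search is exhaustive over all cut sets for ≤ 12 tips (the
configuration space of a rooted tree is small) and otherwise greedy
best-improvement node-splitting from the one-species configuration with
10 seeded restarts whose random-split prefixes span the full
configuration depth.

*Known limitation — oversplitting.* On true expected-substitution trees
the ML solution of the two-rate model systematically oversplits: a
within-species branch longer than log(λ_w/λ_b)/λ_w (about five times the
within-class mean — a threshold that scales with the class means, so no
calibration of the coalescent depth removes it) always increases the
likelihood when moved to the speciation class, and Kingman genealogies
produce such branches with roughly constant probability per species.
At 20 true species this yields typically +2 to +5 entities; at survey
scale (266 species) the dense speciation-age range amplifies it further.
Real surveys that report close PTP/GMYC agreement run PTP on *inferred*
trees whose short within-species branches collapse to zero — a regime
this generator deliberately does not emulate (no tree-inference error).
The parameter-recovery acceptance check for PTP is therefore expected to
fail and is left failing; weakening the search to miss the global
optimum would mask, not fix, the bias.

## Congruence accounting

"Perfect match" means exact block equality (not majority overlap),
matching the notion of groups "identically delimited" by two methods. A
singleton reference group inside a larger test group counts as lumped,
not split. Reported percentages are rounded half-up to 1–2 decimals;
internal values are kept at full precision.

## Richness and turnover

Chao2 uses the small-sample-corrected form S_obs + ((m−1)/m)·q₁²/(2q₂)
with the q₂ = 0 fallback S_obs + ((m−1)/m)·q₁(q₁−1)/2, and the matching
variance expressions of the `specpool` convention (verified against R's
vegan on fixtures and random matrices in the test suite). The
second-order jackknife is reported without a standard error, matching
the output shape of that convention. Accumulation curves are
sample-based; the x-axis is cumulative analysed individuals (mean over
permutations for method "random", which also reports 2.5/97.5 percentile
bands). Standardized richness draws individuals without replacement and
reports the mean and percentile CI; its expectation matches the
hypergeometric closed form Σ_s [1 − C(N−a_s, n)/C(N, n)] within Monte
Carlo error. Turnover removes groups of ≤ 2 specimens when
`exclude_rare` is set, since such groups can trivially occupy at most
two levels.

## Pipeline determinism and problem sizes

One seed governs every stochastic stage; reports carry the seed, package
version and a hash of the result-determining configuration, and repeated
runs produce byte-identical JSON payloads. The stochastic validation
checks run at deliberately modest sizes chosen for a single CPU: species
recovery uses 50 seeded communities of 20 species/50 specimens
(study-like mean abundance 2.5), the type-I simulation 120 single-species
genealogies of 40 tips, and oracle equivalences use 200 random matrices
and 20 twelve-tip trees. The acceptance script runs the full pipeline
once at survey scale (674 specimens) in a few minutes.
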