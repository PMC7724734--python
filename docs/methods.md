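# Methods

This note documents the models and procedures implemented in `cophylo`,
the choices made where the design was genuinely open, and what the test
suite does and does not establish.

## Sequence distances

Input alignments are normalized to the alphabet `{A,C,G,T,-,?}`
(lowercase uppercased, `U → T`, every IUPAC ambiguity code mapped to `?`
and treated as missing everywhere downstream). Sequences with fewer than
`min_length` ungapped sites (default **500**, the usual cutoff for short
unreliable marker reads) are dropped on read and reported.

The Kimura two-parameter distance for a pair is

    d = −1/2 · ln(1 − 2P − Q) − 1/4 · ln(1 − 2Q)

with P and Q the transition and transversion difference proportions over
the columns compared for that pair. Column policy ("internal-as-indel"):

* terminal gap runs and `?` are **missing** — the column is skipped;
* internal gaps are **indels** — skipped for P/Q but tallied per pair
  (`DistanceMatrix.indel_columns`);
* a pair with zero comparable columns is an error.

Saturated pairs (log argument ≤ 0) receive a sentinel of **twice the
largest finite distance** in the matrix, are flagged in
`DistanceMatrix.saturated`, and trigger a warning. The sentinel keeps the
matrix usable by neighbour-joining while making the affected pairs
visibly extreme; any other convention (dropping taxa, +inf) would either
lose data or break the agglomeration arithmetic.

## Neighbour-joining and bootstrap

Classic Saitou–Nei agglomeration on the Q criterion. Determinism rules,
needed so results are bit-reproducible:

* Q-ties are broken by the lexicographically smallest pair of cluster
  names, a cluster being named by its smallest member tip.
* Negative branch-length estimates are clamped to zero with the deficit
  moved to the sibling edge, preserving the joined pair's distance.

Bootstrap support resamples alignment columns with replacement,
re-estimates the tree per replicate, and scores each internal edge of
the full-data tree by the fraction of replicates containing the same
*unrooted* bipartition (whether replicate trees are rooted first is
immaterial under this counting). One pseudo-random stream is consumed
replicate by replicate, so the first k replicates of a longer run equal
a k-replicate run at the same seed. Replicates whose resampled
alignment leaves some pair incomparable are skipped (they support no
split). Fewer than four sequences: support is undefined; the tree is
returned without support values, with a warning. Default replicates:
**1000**.

Rooting: midpoint (root at the half-way point of the longest tip-to-tip
path, first pair in leaf order on ties; when the midpoint falls exactly
on a node that node becomes the root) or outgroup (root halfway along
the edge separating a monophyletic outgroup; non-monophyly is an error
naming the offending split). Both preserve patristic distances exactly.
Support values are stored as fractions in [0,1] on nodes and re-attached
by bipartition after any rerooting; Newick output writes integral
percents as integers (`90`), other values as fractions.

## Strain typing

Given a supported symbiont tree containing *study* sequences and
labelled *reference* sequences:

1. Maximal study-only clades whose subtending edge support is ≥ the
   primary threshold (default **0.97**) become strains.
2. Each uncaptured study sequence merges with the members of its
   smallest enclosing study-only clade if that clade's support is ≥ the
   secondary threshold (default **0.90**); otherwise it is a singleton
   strain.

The two-threshold rule is a deterministic operationalization of
"case-by-case between 90% and 97%": reproducibility demands a rule, and
the only stated criterion in that band is high support. Raising the
primary threshold can only refine the partition, never merge blocks
(verified by test). Strains are numbered "Wol 1", "Wol 2", … in tip
preorder of the input tree.

Supergroup assignment: a strain inherits label X when the smallest clade
containing any of its members plus at least one reference holds
references of supergroup X only; mixed nearest references → `UC` with a
warning; strains whose members are all shorter than
`min_classifiable_length` (default **400** ungapped sites) → `UC`.
"Alignment issues" as a UC cause cannot be operationalized from data, so
a per-strain manual override is available in the config
(`supergroup_overrides`). Specialist = exactly one host species in the
association matrix; generalist = two or more; a strain with zero hosts
violates the association invariant and is rejected at load time.

## Phylogenetic host specificity (PS / SPS)

PS of a strain = mean patristic distance over all unordered pairs of its
host species (so it needs ≥ 2 hosts). SPS standardizes PS against a
permutation null: each of `n_null` (default **999**) replicates draws
the same number of host species uniformly *without replacement* from the
host-tree tips, giving

    SPS = (PS − mean(PS_null)) / sd(PS_null),
    P   = (#{PS_null ≤ PS} + 1) / (n_null + 1).

The null preserves per-strain host richness and is marginally equivalent
to shuffling tip labels; both namings (`uniform`, `tipshuffle`) are
accepted. The P-value is lower-tailed with the add-one estimator: small
PS (clustered hosts, low host flexibility) gives small P; P > 0.95 flags
overdispersed (highly flexible) strains. No multiple-testing correction
is applied across strains. Degenerate nulls (SD = 0, e.g. a star tree)
set SPS to NaN with a flag. SPS is invariant to rescaling all branch
lengths (tested); PS is not, so PS values are only comparable within one
tree.

## ParaFit congruence tests

Principal coordinates are computed by classical scaling; when negative
eigenvalues exceed `1e-8` × the leading eigenvalue, the Cailliez
constant (largest real eigenvalue of the standard 2n × 2n companion
matrix) is added to all off-diagonal distances first — this matches
`ape::pcoa(..., correction="cailliez")`, and the test suite verifies the
global statistic against `ape::parafit` via Rscript on tiny fixtures.
Axes with eigenvalue ≤ tolerance are discarded.

With B (hosts × axes) and C (symbionts × axes) the corrected
coordinates and A the symbionts × hosts incidence matrix, the global
statistic is the sum of squared entries of CᵗAB. The null permutes,
independently within each symbiont row of A, its host incidences
(default **5000** permutations); P uses the add-one upper-tail count.
Per-link statistic: global minus global-with-the-link-removed
(contribution form); its permutation P tracks the permuted image of the
link within the same permutation stream. A link whose removal would
leave its strain hostless still gets a contribution statistic, but its
permutation test is reported undefined. Input distances default to
patristic distances from the trees; raw sequence distances are a config
switch.

## Event-based reconciliation

Five events with default costs **cospeciation 0, duplication 1,
duplication-with-host-shift 2, loss 1, failure-to-diverge 1**.
Reconciliation is untimed: a host shift may land on any host lineage
neither ancestral nor descendant to the source edge, which excludes
single-event time paradoxes but does not enforce global cross-shift
time consistency (no divergence-time input exists).

A symbiont tip observed in several hosts is expanded to cover the
spanning host subtree of its hosts: each covered host speciation with
both daughters covered charges one failure-to-diverge; each with one
daughter covered charges one loss. This is the only source of
failure-to-diverge events, matching the event's definition (a host
speciates under a single persisting symbiont lineage).

* **Exact mode** is a dynamic program over (symbiont node, host node)
  states with `in` (cheapest placement at-or-below, charging one loss
  per edge) and `out` (cheapest placement on an incomparable lineage)
  tables — O(|S|·|H|²) — plus backtracking to a full event list. It is
  provably minimal over the placement-mapping space and is verified
  against a pure brute-force enumerator (no DP, exhaustive over
  mappings) on hundreds of random small instances.
* **Heuristic mode** is a genetic search over placement mappings
  (population **300**, **100** generations, 10% elitism, tournament
  selection, uniform crossover, per-gene mutation 1/n) that shares the
  mapping-scoring semantics; it reports `optimal=False` and can never
  beat the exact optimum (tested). It mirrors the search shape of the
  usual GA-based reconciliation tools without claiming to replicate any
  particular tool's trajectories.

Ties among co-optimal reconciliations resolve to the first in
deterministic DP order (cospeciation tried before duplication before
host shift; host children in postorder). Returned objects always satisfy
total cost = Σ count(e)·cost(e), enforced by the result type.

Random tip mapping: each of `n_iter` (default **50**) iterations redraws
every strain's host set (same size, uniform without replacement),
reconciles, and the reported fraction is the share of randomizations
with *strictly* lower cost; ≤ 5% is the conventional support criterion
for cospeciation.

## Prevalence, tissue tropism, and the sex effect

Specimen records carry per-tissue calls (leg/gut/reproductive ∈
positive/negative/not-assessed), an internal-control flag, and a derived
overall call (positive iff any tissue positive). Specimens whose
internal control failed are excluded from all paired-tissue statistics;
records with any not-assessed tissue are excluded from the paired tests
as incomplete. Percentages are reported as 100·infected/screened rounded
to one decimal.

Cochran's Q uses the textbook formula
`Q = (k−1)[k·ΣC² − (ΣC)²] / [k·ΣR − ΣR²]` with a χ²(k−1) upper tail;
subjects with constant rows contribute nothing, and when *no* subject is
informative the degenerate convention Q = 0, P = 1 is returned with
`n_informative = 0` as the flag. McNemar post hoc tests default to the
two-sided exact binomial on the discordant counts (variants: chi-square
with or without continuity correction, via statsmodels); b = c = 0 gives
P = 1 with a degeneracy flag; no adjustment across the three pairs by
default (Bonferroni/Holm by flag).

The sex effect is a binary logistic regression `infection ~ 1 + male`
fitted by IRLS (statsmodels Logit; deviance tolerance 1e-8, ≤ 100
iterations), reporting OR = exp(β), Wald Z, two-sided P, and df = n − 2.
It is fitted on the subset of species whose minority sex is at least
**60%** of the majority sex (inclusive boundary; single-sex species
dropped) — the balance rule that guards the estimate against
sex-confounded species sampling. Complete separation (an empty
sex × outcome cell) raises a dedicated error rather than returning a
divergent estimate. The upstream description of this model is
ambiguous about which variable is the outcome; infection is modelled as
the outcome, which is the only direction under which the reported
odds ratio for males is defined.

## Synthetic-data generators

`simulate_cophylogeny` grows a host tree as a Yule process (rate 1,
exponential waiting times; no host extinction) and tracks symbiont
lineages along it. At each host speciation every resident single-copy
lineage draws cospeciate / track-one-side-with-loss / fail-to-diverge
(probabilities summing to 1; defaults **0.05 / 0.75 / 0.20**, echoing
the loss-dominated, rarely-cospeciating regime reported for *Wolbachia*
in wild mosquito communities), and every single-copy lineage then gets
independent duplication (default **0.05**) and host-shift (default
**0.15**, uniform target among other extant host lineages)
opportunities. A lineage that has failed to diverge (multiple copies)
only tracks/loses or spreads further, so the symbiont genealogy stays
strictly binary and multi-host tips carry exactly the
failure-to-diverge semantics the reconciler assumes. The full event log
and counts are returned; the generating history is one feasible
reconciliation, so the reconstructed minimal cost can never exceed its
cost (tested). Symbiont lineages cannot go globally extinct under these
semantics (loss always tracks one side), so realized associations always
cover every surviving lineage.

`simulate_sequences` evolves sites independently along the tree under
the two-parameter rate matrix, time-rescaled so branch lengths are in
expected substitutions/site (defaults: transition 0.5, per-target
transversion 0.25 → total rate 1, κ = 2), making K2P a consistent
estimator of patristic distance (tested at 20 000 sites).

`simulate_specimens` draws sex ~ Bernoulli(½), infection with log-odds
`logit(prevalence) + male·ln(OR)`, tissue calls conditional on infection
and overall status derived from the tissues, plus independent
internal-control failures. Defaults mirror the screening survey the
pipeline targets: prevalences spanning 0–0.9 (overall ≈ 0.44), male OR
**0.434**, tissue probabilities **0.95 / 0.12 / 0.07**
(reproductive/gut/leg), control failure rate **0.41**. Note the tissue
layer slightly attenuates the realized overall prevalence
(P(any tissue | infected) ≈ 0.996 at the defaults).

What the generators do *not* emulate: host extinction and sampling
effort; rate heterogeneity across sites and lineages; within-host strain
dynamics and superinfection; locality structure beyond a label; the
study's actual trees and sequences. Passing tests therefore establish
the statistical correctness and calibration of each method under its own
model, not agreement with any particular field dataset.

## Problem sizes used by the test suite

The calibration tests run at sizes chosen to give stable rates while
keeping the suite quick on one CPU: 200 random small instances for the
exact-solver oracle; 200 null systems × 999 permutations (type-I) and
50 congruent systems (power) for ParaFit; 500 null draws × 999
replicates for SPS uniformity; 300 specimen simulations for logistic
coverage and 100 sequence simulations (8 taxa × 5000 sites) for NJ
topology recovery.

## Known limitations

* The exact reconciliation is minimal over *placement mappings* under
  per-node event semantics; multi-shift global time consistency is not
  enforced (standard for untimed reconciliation).
* ParaFit link tests use the contribution form; the alternative
  per-link statistic family is not implemented.
* The bundled survey counts are species × locality aggregates; they
  support prevalence tabulation exactly but carry no individual-level
  sex or tissue data, so the survey's own Q and OR statistics are not
  recomputable from them.
* Saturated K2P pairs make downstream NJ topology locally arbitrary;
  the sentinel keeps them maximally distant but no more.
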