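# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does
not emulate, and the known limitations.

## Settlement quantification

A tetrapod's settlement fraction is its settled-larvae count divided by
the total settled in its tank, so fractions within a tank sum to 1 and
are invariant to rescaling all counts in a tank. Category schemes are
*inputs*: ordered labels over a partition of [0, 1] into half-open
intervals [a, b) with the top interval closed. The bundled schemes use
interior cut points 0.33/0.63 (aquarium conditioning) and 0.33/0.56
(reef), the fraction equivalents of integer-percent bins 0–32/33–62/
63–100 and 0–32/33–55/56–100. Histogram-based threshold selection is
deliberately not automated — the bins are an analyst's choice — so the
scheme is configuration, not inference.

Control (unconditioned, time-0) tetrapods are included in the tank
denominator by default; `exclude_controls` removes them from both
numerator and denominator. Category merging takes a table of pairwise
community-test p-values and merges any pair with p > α (default 0.05),
closing transitively with a warning when the pairwise results are not
themselves transitive; a merged group keeps its highest-settlement
constituent's label and reports its min–max fraction range. The
category × time association uses Pearson's chi-square without
continuity correction, df = (r−1)(c−1).

## Ordination and PERMANOVA

Compartment samples (surface, crevice, bottom) are pooled by summation
into one sample per tetrapod before any dissimilarity computation.
The abundance transform is ln(x+1): the +1 handles zeros and the base
is irrelevant to rank-based ordination. Bray–Curtis is
d(x,y) = 1 − 2·Σmin(xᵢ,yᵢ)/Σ(xᵢ+yᵢ) (scipy's implementation).

nMDS minimises Kruskal stress-1 by SMACOF majorisation: at each
iteration the disparities are the isotonic regression of configuration
distances on the rank order of the input dissimilarities, rescaled so
Σd̂² = Σd², followed by a Guttman transform. Iteration stops at the
first non-improvement (tolerance 1e-7), so the recorded stress trace is
non-increasing by construction and the returned configuration is the
one whose stress is reported. The first restart starts from classical
(Torgerson) scaling, later restarts from random normal configurations;
the best of `n_restarts` (default 4) is returned.

PERMANOVA is the distance-based one-way pseudo-F:
SS_total = (1/n)Σ_{i<j}d²ᵢⱼ, SS_within the within-group analogue scaled
per group size, F = (SS_among/(g−1))/(SS_within/(n−g)), with
p = (#{F_perm ≥ F_obs}+1)/(n_perm+1) over raw label permutations
(999 by default). Labels are permuted without strata: the tank
structure is ignored, which makes the test exchangeable under the null
the generator implements but ignores any tank-level dependence in real
data. Pairwise PERMANOVA runs the same test on each group pair's
sub-matrix with Bonferroni adjustment. A multi-factor model is not
implemented; the single factor is whichever grouping is passed.

## Core microbiome

Within one settlement category, an ASV is core iff it is nonzero in at
least ⌈prevalence_min · n⌉ of the category's pooled samples (default
2/3, rounded up) and its mean relative abundance across those samples
is ≥ abundance_min (default 10⁻⁴, i.e. 0.01%). The mean-abundance
convention is the default; `abundance_mode="any-sample"` switches to a
per-sample threshold. Prevalence is computed on pooled tetrapod
samples, consistent with pooling preceding all statistics. Recombination
takes the union of the category cores over *all* of the dataset's
samples with raw counts untouched, tagging each ASV with the categories
whose core holds it. Filtering is monotone: relaxing either threshold
can only grow the retained set.

## Network inference

Counts are CLR-transformed per sample (pseudocount 1), removing
compositional closure. The learner is a PC-style two-stage procedure:

* Stage 1 (marginal screen): Pearson correlations between all taxon
  pairs, Fisher-z tested at n−3 degrees-equivalent, Benjamini–Hochberg
  corrected; pairs with q < α (default 0.01) become candidate edges.
* Stage 2 (conditional pruning): for conditioning sizes k = 1..max_k,
  with neighbourhoods frozen per level (PC-stable), each surviving edge
  (i, j) is tested against every size-k subset of
  adj(i) ∪ adj(j) \ {i, j}; the edge is removed the first time the
  partial correlation (computed by inverting the correlation submatrix)
  is *not* significant at raw α with the Fisher-z test at n−k−3. The
  seed only shuffles the order in which subsets are tried.

Edge weights are the signed partial correlation of the endpoints given
their final joint neighbourhood (falling back to the marginal
correlation when the conditioning set is degenerate); the sign is kept
as an attribute.

`infer_network` defaults to max_k = 2, appropriate for sparse
graphical-model recovery at n ≈ 200 samples. The *pipeline* default is
max_k = 1: with ~50 pooled samples and latent-factor (module) structure,
depth-2 conditioning on module mates destroys within-module edges whose
partial correlations are genuinely small-but-nonzero, fragmenting
modules, while depth-1 still removes indirect chains and compositional
artefacts. Both are configuration.

## Modularity

Partition quality is weighted Newman–Girvan modularity
Q = Σ_m (W_m/W − (S_m/2W)²) on absolute edge weights; signed
association weights keep their sign as an edge attribute but contribute
|w| to Q and to node roles, the least-surprising contract when a signed
network feeds a Q-maximiser.

The optimiser is functional-cartography simulated annealing: per
temperature, n² Metropolis single-node moves (ΔQ in closed form from
module strength sums) and n collective moves alternating module merges
with splits (random bipartition refined by one greedy sweep, accepted
or reverted as a whole). The schedule is geometric: T₀ = 1/(2n) by
default, cooling factor 0.995 (0.95 in the pipeline, where networks are
larger and strongly modular), floor T₀·10⁻³. Each connected component
is annealed independently against the *global* total weight W — a
modularity-optimal module never spans components, since splitting a
cross-component module leaves ΣW_m unchanged and strictly reduces the
Σ(S_m)² penalty. A final greedy hill-climb polishes the best state
visited. The annealer is bit-reproducible per seed; equal-Q ties go to
the first state visited.

The exact oracle enumerates all set partitions (restricted-growth
strings) for n ≤ 12. Node roles follow the cartographic definitions:
z_i standardises within-module strength over the module (sd 0 → z 0);
P_i = 1 − Σ_m (κ_im/k_i)², with z = P = 0 for isolated nodes.

## Annotation

"Normalised read counts" means per-sample relative abundance
(total-sum scaling). A node's settlement fraction for category c is its
summed normalised abundance over c's samples divided by its sum over
all samples; module compositions are the same quantity summed over
members, hence exactly the abundance-weighted mean of member fractions.
A module is labelled with its dominant category when that fraction
reaches the purity threshold (default 0.75, configurable — reported
purities in this kind of analysis straddle any single cutoff), else
"mixed". The simplified module graph has one node per module and edge
weights equal to the count of parent edges crossing each module pair.
Bridging nodes are exactly the endpoints of cross-module edges.
Betweenness is unnormalised shortest-path betweenness on the unweighted
topology (networkx/Brandes; a `weighted` option uses distance 1/|w|),
so node-of-interest thresholds are path counts: betweenness ≥ 3 and
degree in [2, 4] by default, intersected with the bridging set.
Exclusivity is sample-level: a taxon (or family, after aggregating
member ASVs — so a family split across categories is not exclusive) is
exclusive to the only category whose samples carry its nonzero counts.
Rare families are those with overall mean relative abundance below 0.1%.

## Synthetic data

The generator mirrors the conditioning design: 12 tanks per
conditioning type, 3 conditioned tetrapods (times 1/2/3 months) plus
one unconditioned control (time 0) per tank, three compartments per
tetrapod — 48 tetrapods, 144 samples per conditioning type. Taxon
log-abundances follow a latent-factor model: each module is a standard
normal factor per tetrapod with loading 1.5 (log scale) on its 12 member
taxa; bridging taxa load 1.5/√2 on each of two adjacent modules;
category-exclusive taxa (5 per category) are hard-gated to zero outside
their category's tetrapods and share a per-category factor so they
co-occur; rare taxa get base levels offset (with a lognormal-mean
correction) to an expected relative abundance of 0.02%, safely below
the 0.1% rarity cutoff; residual log-noise sd is 0.5. Compositions are
closed per tetrapod, read depth is negative-binomial (mean 50 000,
shape 10), split over compartments by a symmetric Dirichlet(5) and
sampled multinomially — so compartment triplets sum to the tetrapod
total exactly, and counts carry realistic compositional and
over-dispersion noise.

Settlement: per tank, categories are drawn i.i.d. from `category_probs`
(uniform by default) with rejection until jointly feasible; settled
counts start each tetrapod at the smallest count reaching its
interval's lower bound and allocate the remaining larvae randomly
within capacities, so realised within-tank fractions always lie in
their category intervals. Tank totals are binomial (350 larvae,
settlement rate 0.4). Hard gating of exclusive taxa is intentional —
sample-level exclusivity is only recoverable under exactly this
structure.

What the generator does *not* emulate: taxon-specific amplification or
copy-number bias, time-dependent community succession (categories are
independent of conditioning time, so the chi-square stage is null
here), tank-level community effects, compartment-specific community
differences, and phylogenetic correlation between taxa. Passing
recovery tests therefore demonstrates correctness of the algorithms
under the stated statistical structure, not performance on real reads.

`planted_ggm` provides the complementary benchmark for the network
learner alone: a sparse precision matrix (density 0.05, partial
correlations ±0.3 before the diagonal-dominance rescale) over 60 taxa,
sampled at 200 multivariate-normal samples.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 100 random graphs
(n ≤ 8) for the annealing-vs-enumeration check, 50 graphs (n ≤ 7) for
betweenness, 200–500 null simulations × 999 permutations for PERMANOVA
calibration, 10 seeds for graphical-model recovery, and 5–10 full
pipeline runs for planted-module recovery — sizes at which every oracle
is exact or the Monte-Carlo error is well below the asserted margins.
Every stochastic stage takes an explicit seed; the pipeline derives and
records a sub-seed per stage, and a rerun with the same config is
bit-identical (artifact checksums are in the manifest).

## Limitations

* The network learner assumes roughly Gaussian CLR abundances and uses
  a single test family (Fisher-z); heterogeneous presence/absence plus
  continuous test switching and environmental-covariate conditioning
  are out of scope.
* PERMANOVA ignores strata, so p-values on real tank-structured data
  are anti-conservative to the extent tanks induce dependence.
* Modularity on |w| discards the distinction between positive and
  negative associations at partition time.
* Brute-force modularity beyond n = 12 is intractable (Bell numbers);
  the annealer's optimality is only verified exhaustively at small n.
* The 18S copy-number issue in mixed eukaryote data is deliberately not
  corrected for; abundances are taken as sequenced.
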