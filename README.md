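# settlenet

Settlement-stratified co-occurrence network analysis for microbial
biofilm amplicon data.

Coral larvae choose where to settle partly in response to the microbial
biofilms coating a substrate. Given an ASV × sample count table from
biofilm amplicon sequencing, per-substrate ("tetrapod") larval
settlement counts and sample metadata (conditioning type, conditioning
time, tank, compartment), `settlenet` runs the full analysis that links
community structure to settlement success:

1. **Settlement** — per-tetrapod settlement fraction
   (settled ÷ tank total), binned into low/medium/high categories by
   configurable fraction intervals, with category merging when a
   pairwise community test cannot separate two categories, and a
   chi-square test of category × conditioning-time covariation.
2. **Community statistics** — compartment pooling, ln(x+1) transform,
   Bray–Curtis dissimilarity, nonmetric MDS (SMACOF with isotonic
   disparities), one-way and pairwise PERMANOVA with a permutation
   pseudo-F.
3. **Core microbiome** — per-category prevalence (≥ 2/3 of samples) and
   relative-abundance (≥ 0.01%) filtering, recombined across categories.
4. **Network inference** — CLR transform, then a PC-style
   local-to-global conditional-independence learner: Fisher-z tests on
   marginal correlations (BH-corrected), pruned by partial-correlation
   tests given small conditioning subsets of the endpoints'
   neighbourhoods.
5. **Modularity** — weighted Newman–Girvan modularity
   `Q = Σ_m (W_m/W − (S_m/2W)²)` maximised by functional-cartography
   simulated annealing (single-node plus merge/split moves), with an
   exact brute-force oracle for small graphs and per-node cartographic
   roles (within-module degree z, participation coefficient P).
6. **Annotation** — per-node and per-module settlement-category
   fractions, module purity labels, module-collapsed simplified
   networks, bridging nodes, betweenness/degree screening for
   high-betweenness low-degree nodes of interest, category-exclusive
   taxa and rare-family summaries.

A synthetic-data module generates experiments with planted modules,
bridging taxa, category-exclusive taxa and rare taxa — plus a truth
file — so every stage is verifiable without raw sequencing data.

## Worked example

```bash
settlenet run --seed 1 --out run1
```

simulates the default conditioning design (12 tanks × 3 conditioned
tetrapods + 1 control, 3 compartments each, 100 taxa with 5 planted
modules) and runs every stage. The printed summary includes:

```
"permanova": { "pseudo_F": 9.71, "df_among": 2, "df_within": 45, "R2": 0.30, "p": 0.001 }
"chi_square": { "X2": 3.86, "df": 4, "p": 0.43 }
"core_sizes": { "high": 80, "low": 88, "medium": 87 }
"network":   { "nodes": 98, "edges": 177, "components": 16 }
"modularity": { "Q": 0.87, "n_modules": 16 }
```

Reading this: the communities of the three settlement categories are
strongly separated (PERMANOVA p = 0.001, R² = 0.30), while settlement
category does not covary with conditioning time in this simulation
(χ² p = 0.43, as expected — the generator draws categories
independently of time). Each category keeps a core of 80–88 ASVs; the
recombined core yields a 98-node network whose annealed partition is
highly modular (Q = 0.87). `run1/module_composition.tsv` labels each
module's settlement purity, and `run1/node_annotation.tsv` carries
per-node settlement fractions, degree, betweenness, bridging and
node-of-interest flags. `run1/truth.json` holds the planted labels for
comparison.

Every stage is also exposed as a library function
(`settlenet.infer_network`, `settlenet.anneal_partition`, …) and as its
own subcommand (`settlenet simulate|settle|ordinate|permanova|core|
network|modules|annotate`).

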