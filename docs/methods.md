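# Methods

`wildgut` re-implements, as a tested library, the analytical chain used to
compare gut microbiomes across lifestyle groups (forest forager, settled
forager, farming village): from MAG quality control and species-level
dereplication through community statistics, co-abundance network topology,
metabolic key-species identification for wild-plant substrates,
exclusive-feature prevalence screening, and strain-sharing detection.  A
synthetic-data package generates cohorts with planted ground truth so every
stage can be validated end-to-end without sequencing data.

## MAG quality control and dereplication (`wildgut.qc`)

MAGs are retained when completeness exceeds 50% **and** contamination is
below 5%; both bounds are strict, matching the usual CheckM-based gating.
Retained MAGs are clustered into species-level genome bins (SGBs) by
single-linkage at genome distance ≤ 0.05 (5% genetic diversity, the
conventional species boundary): clusters are exactly the connected
components of the thresholded distance graph, which the test suite verifies
against a brute-force component search.  Distances may be supplied
precomputed or derived from k-mer sketches via the Mash formula
`d = -(1/k) ln(2j/(1+j))` (Jaccard index `j`, default `k = 21`, capped at 1
for disjoint sketches).  Within each cluster the representative maximises
the dRep-style score `Q = completeness - 5 × contamination`, with ties
broken by larger genome size and then lexicographic MAG id so output is
deterministic.  Alignment-coverage filters of two-stage dereplicators
(Mash-then-ANI) are out of scope; the sketch backend has no alignment
coverage to threshold.

## Community statistics (`wildgut.community`)

*UniFrac.*  Unweighted UniFrac is the branch length unique to one sample's
presence set divided by the branch length covered by either sample.
Weighted UniFrac is the normalized variant,
`Σ_b ℓ_b |p_A(b) − p_B(b)| / Σ_b ℓ_b (p_A(b) + p_B(b))`, where `p(b)` is
the relative abundance subtended by branch `b`; both variants are bounded
in [0, 1].  Note that the *normalized* weighted variant is a semimetric:
because its denominator depends on the sample pair, the triangle inequality
can fail (violations up to ~0.03 on random fixtures).  The unweighted
variant is a true metric, and the tests assert the full metric axioms for
it only.  Our values agree with scikit-bio's implementations to machine
precision, which the suite checks.

*Ordination.*  Principal coordinates analysis is classical scaling of the
double-centered squared-distance matrix.  Negative eigenvalues (possible
for non-Euclidean dissimilarities) are reported but their axes dropped.

*PERMANOVA.*  Anderson's pseudo-F from among/within sums of squared
distances, `SS_total = Σ d²/n` over all pairs and `SS_within` from
within-group pairs.  The permutation p-value uses the +1 correction,
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, so p is never reported as 0;
at the default `n_perm = 999` (the vegan default; the number of
permutations is not otherwise pinned down) the attainable floor is 0.001.
Permutations are drawn from a seeded generator.

*Per-SGB tests.*  Kruskal-Wallis H with tie correction per SGB, chi-square
p on k−1 degrees of freedom, and Benjamini-Hochberg q-values over all
tested SGBs (FDR 0.05 is the conventional significance gate).  SGBs
constant across all samples get p = 1 by convention.  Two-group
comparisons (cluster sums, module sums) reuse the same machinery: for two
groups the KW ranking is equivalent to a Wilcoxon rank-sum test up to the
tie convention, which is fixed here to KW-with-ties.

## Co-abundance network (`wildgut.coabundance`)

SGBs enter the network when they reach ≥ 10 gcpm in at least two samples.
Pairwise association is Kendall's tau-b (tie-corrected); SGBs constant
across samples have undefined tau, recorded as 0 with a warning.  Clusters
come from average-linkage hierarchical clustering on `1 − tau`, cut to a
requested cluster count (default 7) or height; rows are sorted by SGB id
before linkage so the partition is order-independent.  The graph keeps
edges with `|tau| ≥ 0.3` by default, retaining the correlation sign for
reporting but ignoring it in shortest-path topology (no signed-path
semantics is implied by connectivity metrics).  Closeness centrality uses
the Wasserman-Faust component-size correction `(n_c − 1)/(n − 1)`;
betweenness is normalized by `(n−1)(n−2)/2`; both are computed on the full
graph rather than per cluster (the choice is documented because either
reading is defensible).  A keystone taxon requires closeness ≥ 0.45,
betweenness ≥ 0.02, degree ≥ 20 and mean abundance > 50 gcpm; only the
abundance gate is externally fixed — the centrality cut-offs are
configuration defaults sized for a dense ≈150-SGB cohort network and
should be rescaled for smaller networks.

## Metabolic key species (`wildgut.metabolism`)

Per-species genome-scale reaction networks use boolean network-expansion
semantics rather than flux balance: a reaction fires when all its
substrates are reachable, adding its products, iterated to a fixpoint
("scope").  This matches the reachability formalism of community-level
metabolic complementarity tools, is monotone in both seeds and community,
and is exactly testable.  Reversible reactions are encoded as two directed
reactions.

For a substrate profile (seed metabolites of the plant food, target
degradation products), the community-producible targets are fixed first
from the full-community scope.  Minimal communities are inclusion-minimal
species subsets (size ≤ `max_size`, default 8) whose combined scope covers
those targets, enumerated by increasing size with superset pruning;
enumeration is restricted to species that fire at least one reaction under
the full-community scope (a safe reduction, since every member of a minimal
community must contribute a firing reaction).  *Essential* species belong
to every minimal community, *alternative* species to some but not all.
Above 20 candidate species the search degrades gracefully: essentiality
stays exact via the leave-one-out rule (`s` is essential iff the full
community minus `s` loses a producible target — equivalent to membership
in every minimal cover); if the essential set alone covers the targets it
is the unique minimal community; otherwise each remaining candidate is
tested by a greedy set cover forced to include it and pruned to
minimality, so interchangeable degraders are still labelled alternative.
This heuristic can miss alternatives on pathological instances; the result
carries an `exhaustive` flag and a warning.

The wild-plant module (wpSGBs) is the union over the five substrate
profiles of essential ∪ alternative species ("involved in the metabolism of
at least one" plant food); an `essential_only` switch restricts to
essential species, since either reading of "involved" is defensible.

## Exclusive features and prevalence (`wildgut.screen`)

Module-exclusive genes are present in at least one module SGB, absent from
every non-module SGB, and annotated in a degradation-relevant category
(CAZy-like carbohydrate-active enzymes or xenobiotic-degradation
annotations).  Prevalence across external metagenome panels uses RPKM,
`counts / ((length_bp/1000) × (total_mapped_reads/10⁶))`, with presence
defined as RPKM above a threshold whose default is 0 (any aligned read):
no hidden presence cut-off is invented, the threshold is configurable, and
raw RPKM is emitted alongside binary presence.  BGC prevalence shares the
same code path with results additionally grouped by product class
(terpene, arylpolyene, NRPS, T1PKS, RiPP-like, ...).

## Strain sharing (`wildgut.strains`)

Eligible SGBs need ≥ 5 MAGs and abundance > 5 gcpm in at least one sample
of *each* of the two designated groups.  Marker genes are private core
genes of the SGB (present there, absent from every other SGB) whose
coverage validity holds: at least 90% of the SGB's MAGs (inclusive) cover
more than 50% of the gene length (strict).  The normalized phylogenetic
distance between two individuals' strains is nGD = leaf-to-leaf path length
divided by total tree branch length, a scale-free pseudometric in [0, 1].

The per-SGB sharing threshold maximizes Youden's `J = sensitivity +
specificity − 1` over candidate thresholds (midpoints of consecutive
distinct pooled nGD values, plus one candidate below the pooled minimum so
the constraint set is never empty), subject to at most 5% of unrelated
pairs falling at or below the threshold (the false-sharing bound — the
constraint is on the unrelated-pair acceptance fraction, which the
terminology "false discovery rate" refers to here).  Ties break toward the
smaller threshold; if the bound excludes the unconstrained optimum the
result is flagged `constrained`.  A sharing event is called when a query
pair's nGD is ≤ the threshold (inclusive: the threshold is the largest
accepted distance).  Marker-tree inference itself (read alignment,
consensus calling, tree building) is upstream; the module consumes trees.

## Synthetic data (`wildgut.simulate`)

Every generator is a pure function of its spec, seed included, and returns
a ground-truth record sufficient to score the downstream stage.

*Cohorts.*  Defaults mirror a lifestyle-contrast field cohort: 161 SGBs;
three groups of 16 (forest), 10 (settled) and 18 (village) samples;
per-sample sequencing depth ~ N(8.1M, 1.9M) reads.  Per-SGB baseline
log-abundances are N(0, 3) in natural log (≈1.3 decades spread, as real
gcpm profiles show); sample values add log-normal noise (σ = 1) and
multiplicative group effects: 12 gradient SGBs change 2 log2-fold per group
step (half up, half down along the gradient) and a 26-SGB module is
elevated 1 log2-fold per step toward the forest group.  Planted SGBs are
drawn from the above-median-baseline half of the universe, because the
trends being emulated concern well-detected taxa.  Columns are closed to a
constant total (10⁶ gcpm), values below a 5 gcpm detection limit are
zeroed (producing the abundance-coupled zero pattern of real tables), and
columns are re-closed.  The SGB tree is a random coalescent-style binary
tree with exponential branch lengths.  What this does *not* emulate:
phylogenetic signal in abundances, overdispersed counts, batch effects, or
hub structure in the co-abundance network — so passing tests demonstrate
statistical correctness of the machinery, not effect sizes on real data,
and keystone cut-offs need rescaling on these cohorts.

*Pangenomes.*  `n_exclusive` annotated genes are planted only in module
SGBs (1–3 owners each); background genes are scattered at 30% presence,
with annotated background genes forced into at least one non-module SGB so
the planted set is exactly the module-exclusive annotated set.

*Metabolic networks.*  One obligate cross-feeding guild per plant profile:
the seed → intermediates → target chain is split across guild members, so
each member is essential.  Default guild sizes (6, 6, 5, 5, 4) across the
five profiles yield a 26-species module out of 161, the same scale as the
cohort generator.  Distractor reactions consume seeds or junk metabolites and produce
only junk metabolites, so they can never complete a chain; generation
audits this by checking that the community without a guild cannot reach
that guild's target.

*Strain pairs.*  Each pair lives on its own three-leaf tree (a cherry whose
two branches sum to the desired path plus an outgroup branch tuning total
length to 1), so requested nGDs are realized exactly; draws are truncated
into (0, 0.94] where the construction is feasible.  Defaults: 30 related
pairs at nGD ~ N(0.01, 0.005) and 30 unrelated at N(0.5, 0.05) — well
separated, as same-group strain retention versus unrelated backgrounds is
in practice.

*Mapping counts.*  Poisson counts with expected coverage proportional to
feature length and library size; features planted as "rural-only" get zero
counts in the industrialized panel.

## Numerical conventions

- All permutation and simulation randomness flows through
  `numpy.random.default_rng(seed)`; identical seeds give identical results,
  and the CLI pipeline's TSV/JSON output is byte-stable (`%.10g` floats,
  sorted JSON keys).
- Distance matrices are symmetrized and zero-diagonal-enforced after a
  1e-9 tolerance check; PCoA drops eigenvalues below a relative 1e-10
  threshold; degenerate inputs (constant SGBs, empty clusters, singleton
  groups, zero within-group scatter) raise validation errors or take the
  documented conventions (p = 1, tau = 0).
- Hierarchical-clustering ties and cluster numbering are made deterministic
  by sorting SGB ids and renumbering clusters in order of first appearance.

## Problem sizes used in the shipped checks

The test suite and the acceptance script exercise the pipeline at desk
scale, chosen so planted signals are comfortably detectable with the
nonparametric tests: cohorts of 60 SGBs × 44 samples (the generator's
group sizes), 161-species metabolic networks, 2000-gene
pangenomes with 29 planted exclusive genes, 200 random dereplication
instances of ≤ 20 genomes, and 30 + 30 strain pairs.  Exhaustive oracles
(subset enumeration, full permutation enumeration) run on instances of
≤ 12 species or ≤ 6 samples where they are tractable.

## Known limitations

- The greedy key-species branch may miss minimal communities (and hence
  alternatives) on instances with deeply nested redundancy; essentiality is
  exact in both branches.
- The normalized weighted UniFrac semimetric issue above.
- Single-linkage dereplication with a sketch-only backend has no analogue
  of alignment-coverage filtering; very fragmented genomes may chain
  clusters together at the margin.
- The synthetic cohort's compositional closure means planted effects induce
  opposite-signed apparent changes in unplanted SGBs; this is a property of
  relative-abundance data itself, and the null-calibration check therefore
  uses cohorts with no planted effects at all.
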