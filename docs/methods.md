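# Methods

`islephylo` implements a temporal community-phylogenetics analysis for
island floras observed at two time slices: a **pre-European** flora (the
native species of each island, including those that later went extinct)
and a **current** flora (surviving natives plus naturalized exotics).
All indices are computed against a single regional chronogram with branch
lengths in millions of years (My); only assemblage membership changes
between periods.

## Diversity indices

For an assemblage *S* on a rooted chronogram:

* **Faith's PD** — total branch length of the minimal subtree connecting
  *S* *and the root*. The root-inclusive convention makes PD well defined
  for a single species (its root path) and monotone under adding species;
  it matches the default of the picante reference implementation, against
  which the package is cross-checked in the test suite.
* **MPD** — mean patristic distance over all unordered pairs in *S*;
  sensitive to deep (order/family-level) phylogenetic structure.
* **MNTD** — mean distance of each member of *S* to its nearest
  co-occurring relative; sensitive to terminal structure. Both require
  |S| ≥ 2 and are presence-weighted (no abundances).
* **PhyloSor** — 2·BL_shared/(PD_A + PD_B), with BL_shared the length of
  edges lying in both root-inclusive spanning subtrees; 1 − PhyloSor is
  the phylogenetic beta diversity (0 = homogenization, 1 = turnover).
  Because the spanning subtrees include the root path, two disjoint clades
  reach dissimilarity 1 exactly when the edges they share toward the root
  have zero length (e.g. a zero-length root edge at the angiosperm crown).

Indices are evaluated on the full regional tree without per-assemblage
pruning; pruning preserves patristic distances and spanning subtrees (a
tested invariant), so the results are identical and one cached set of
per-tree arrays (`TreeMetrics`) serves all assemblages and all null
randomizations.

## Null model and standardized effect sizes

The null randomizes the **phylogeny tip labels** while holding the
occurrence matrix fixed, preserving any spatial structure in the data.
SES = (observed − null mean)/null sd with 999 randomizations by default.
Implementation note: the image of a fixed species set under a uniform
label permutation is a uniform random tip subset of the same size, so
per-assemblage null values are generated by re-evaluating the index on
random subsets — identical in distribution to relabelling the tree and
much cheaper. When several assemblages are scored together
(`ses_profile`), one permutation per randomization is shared by all of
them, mirroring a single relabelled regional tree; for SES of PhyloSor the
same permutation is applied to both assemblages of a pair, preserving
their intersection (the "matrix-preserving" null).

Raw SES is reported with the convention that negative MPD/MNTD values
mean phylogenetic clustering; the sign-flipped NRI = −SES(MPD) and
NTI = −SES(MNTD) are reported alongside, so either sign convention found
in the literature can be read off directly. Classification uses
|SES| > 1.96 (the two-sided 5% normal threshold); the looser "|value|>1"
rule sometimes quoted is not implemented. A pooled check over islands
(mean ± 1.96·SE of the per-island SES values) accompanies the
per-assemblage classifications. Degenerate nulls (sd ≈ 0, e.g. the full
tip set, where every relabelling yields the same index) are flagged with
SES unset rather than raising.

## BLADJ age calibration

`bladj` fixes the ages of named internal nodes from a two-column
`node_name,age` table, sets tips to age 0, and spaces undated nodes evenly:
for a maximal chain of *u* undated nodes between a dated ancestor (age *a*)
and the nearest dated descendant or tip (age *b*), node *j* (counted from
the ancestor) gets age *a* − *j*(*a* − *b*)/(*u* + 1). Branch lengths are
parent age minus child age, so output is ultrametric (checked to 1e-9) and
the procedure is idempotent.

Order of resolution when constraints interact: regions headed by dated
nodes are processed oldest first; within a region, dated boundaries are
processed oldest first and, at equal age, by the path with the fewest
intervening nodes. An undated node therefore takes its age from its
minimum-intervening-node path among equal-aged constraints, while a deep
old calibration point is honoured before a nearer-but-younger one — which
avoids age inversions that a purely nearest-path rule would produce.
Inconsistent tables (undated root, a dated descendant at least as old as a
dated ancestor, a tip with nonzero age) are rejected with the offending
node names.

## Contrast layer

Percent change is 100·(after − before)/before per island; summaries are
mean ± SE (standard error). Deviation of per-island percent changes from
μ = 0 uses a two-tailed one-sample t-test; SES values are compared between
periods with a paired t-test (one-sample t on differences). Temporal beta
(per-island 1 − PhyloSor between periods) is likewise contrasted against
μ = 0. The Mantel test between beta matrices and great-circle distance
(haversine, Earth radius 6371 km) uses Pearson correlation of off-diagonal
entries with joint row/column permutation of one matrix,
p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm); one-tailed by default (the
distance-decay hypothesis is directional), two-sided available. The Mantel
permutation loop is implemented in-package so that it can be seeded; the
r statistic is cross-checked against scikit-bio in the tests. Degenerate
inputs (zero variance anywhere) yield flagged results, never crashes.

## Synthetic data generator

`simulate_system` emulates the study design: an ultrametric Yule
chronogram over a regional pool (natives + exotics), natives scattered on
islands by independent per-island occupancy probabilities (a native
landing nowhere is placed on one random island so the pool size is exact),
per-island extinction draws, and per-island exotic introduction draws.
Defaults are the envelope of the real six-island system: 205 natives, 756
exotics, per-island occupancy equal to observed native richness (9–100)
over 205, extinction fractions (0, 0, 0.35, 0.02, 0, 0.03), introduction
counts (6, 6, 340, 477, 41, 148), the six real island coordinates, and a
140-My crown age (which yields MPD values in the 200–270 My range the real
chronogram produces). The Yule model is deliberately the only tree model:
a death rate adds parameters without changing any property the analysis
is sensitive to. Trees are grown from a crown split conditioned on the tip
count and rescaled to the crown age; an unscaled fixed-duration mode
exists and is checked against the pure-birth expectation E[N(t)] = 2e^(λt).

`clade_bias` concentrates extinction/introduction draws in one randomly
chosen clade of roughly 10% of the pool (members weighted e^bias),
emulating invasion by a few widespread clades (grasses, daisies, legumes)
and clade-structured extinction. Extinction is a *global* species flag
drawn per island: a species shared between islands that goes extinct in
one island's draw disappears from every island's current flora. This
matches a species-level notion of regional extinction but means per-island
observed extinction fractions are slightly above the configured value when
occupancy overlaps (the parameter-recovery test budgets ~3 percentage
points for this leakage at low occupancy).

What the generator does **not** emulate: distance-structured dispersal
(island assignments are independent), nestedness of real island floras,
unresolved polytomies of grafted megatrees, and abundance structure.
Passing tests therefore demonstrate the correctness and calibration of the
estimators under a clean neutral model, not the ecological realism of any
particular empirical dataset.

## Problem sizes and numerical choices

The test and acceptance workloads use: exhaustive oracle comparisons on
trees of ≤ 10 tips (every assemblage, against direct edge/path
enumeration); SES null calibration with 500 random assemblages of 8
species on a 64-tip tree at 99 randomizations; Mantel type-I calibration
with 500 independent 6×6 matrices at 199 permutations; and 100 replicates
per condition for the clade-bias contrast. Production defaults remain 999
randomizations/permutations. Ultrametricity and idempotence tolerances are
1e-9 absolute; degenerate null detection uses a relative sd threshold of
1e-12. Newick output uses 6 decimal places by default and omits unset
branch lengths entirely (absence is not zero).

## Known limitations

* No abundance-weighted index variants, UniFrac-family measures, or
  community-matrix-shuffling null models (the tip-label null is the
  method's stated design).
* BLADJ behaviour on pathological age tables that are consistent but
  force zero-length branches is clamped to 0 rather than rejected.
* The generator's extinction leakage described above; configure
  non-overlapping occupancies when exact per-island extinction fractions
  matter.
* Species present in occurrence data but absent from the tree are an
  error by default (silent drops would corrupt SES); `skip_missing=True`
  drops them loudly and reports `n_matched`.
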