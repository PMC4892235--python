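# Methods

## The audit

The package answers two questions about a clade, given a reference
phylogeny, a taxonomy and lists of "scored" OTUs (taxa with at least one
coded character in a discrete morphological matrix):

1. *How much* of the clade is scored, at species, genus and family level?
2. *Where* on the tree are the scored taxa — random, clustered, or
   overdispersed?

Both matter for total-evidence phylogenetics: low coverage means fossils
have few living anchors, and clustered coverage biases fossil placement
toward the well-scored clades.

## Name standardization and filtering

Raw OTU labels from morphological matrices are messy. `normalize_name`
canonicalizes to `Genus` or `Genus epithet`: underscores to spaces,
whitespace collapsed, parentheticals, authority strings, years and
open-nomenclature markers (`sp.`, `cf.`, `indet.`, ...) stripped by a
configurable regex list, genus capitalized, epithet lower-cased, tokens
beyond the binomial dropped. This is a deliberate simplification of full
synonym resolution against a reference taxonomy — no synonym dictionary is
consulted — so the normalizer fixes orthography, not nomenclature. After
normalization, scored names absent from the taxonomy (fossils, failed
resolutions) are excluded, with every exclusion logged.

OTUs coded above species rank are common in matrices. A genus-rank OTU
certifies the genus and its family as scored but no particular species;
a family-rank OTU only the family. `lift_to_level` implements exactly
that.

## Coverage classes

Coverage of a clade at a level is `n_scored / n_total` over the taxonomy's
reference set. Classes follow strict thresholds: low when *p* < 0.25,
high when *p* > 0.75, medium otherwise — exactly 25% or 75% is medium, a
literal reading of "less than"/"more than". The thresholds are
configurable (`AuditConfig.low/high`); 0.75 is the level of living-taxon
coverage below which simulation studies report substantial topological
damage from missing data in total-evidence analyses.

## Dispersion statistics

All distances are patristic (sum of branch lengths along the unique
unrooted path between two tips), computed once per tree and reused as
submatrices — pruning a tree never changes tip-to-tip path lengths, which
the test suite checks exactly. Polytomies and zero-length branches are
accepted unmodified.

For a focal set of n tips in a pool of T:

* MPD = mean of d(i,j) over all unordered focal pairs;
* MNTD = mean over focal tips of the distance to the nearest other focal
  tip.

The null draws n tips uniformly without replacement from the pool,
independently for each of `reps` replicates (default 1000), and records
both metrics. NRI/NTI are the negated z-scores of the observed metric
against the null (sample sd, n−1 denominator); the sign convention makes
clustering positive. The class-wide test pools all orders (full tree);
each order's test uses the order-pruned tree, so an order's result is
about structure *within* the order.

Degenerate cases are reported as NA with a logged reason, never ±inf:
fewer than 2 focal tips in the pool, a focal set spanning the whole pool,
or a zero-spread null. A null whose replicates are identical up to
floating-point summation noise (relative spread ≤ 1e−12) counts as
zero-spread.

**Significance.** The randomization p-value is two-tailed with a +1
continuity correction: with r = #{null ≤ obs} and q = (r+1)/(reps+1),
p = 2·min(q, 1−q+1/(reps+1)), capped at 1. This is symmetric between
clustering and overdispersion, never exactly 0, and calibrated (the
acceptance suite verifies a ~5% rejection rate under random sampling).
Reports flag p < 0.05 with `*` and p < 0.01 with `**`; no multiple-testing
correction is applied across clades — rows are reported raw, as per-order
results.

**Genus/family-level dispersion.** The reference tree has species at its
tips, but genus- and family-level focal sets contain group names. The
audit collapses the species matrix to one exemplar species per group (the
alphabetically first present in the tree) and relabels rows with the group
names, so the pool is "one tip per genus/family" and the focal set is the
scored groups. Alternatives (group centroids, all-pairs group distances)
complicate the null's exchangeability; the exemplar approach keeps the
null draw exactly analogous to the species-level one. Exemplar choice is
deterministic, so runs reproduce byte-identically.

**Determinism.** One top-level seed; each (clade, level, metric) gets its
own substream derived from (seed, CRC32(clade), CRC32(level), metric), so
adding or removing a clade never shifts another clade's draws. Identical
configs byte-reproduce the report TSV (sorted rows; proportions printed to
4 decimals, indices to 2, p-values to 4).

## Synthetic data

The generator emulates the audit's study conditions, not mammalian biology:

* **Trees** are Yule (pure-birth): exponential waiting times with rate
  (birth rate × lineage count), uniform choice of splitting lineage, a
  final exponential extension so no pendant edge is zero — giving
  ultrametric, clock-like trees like a dated supertree. Default birth rate
  1.0 (time units are arbitrary; only relative branch lengths matter to
  the indices).
* **Taxonomies** chunk the tips, in tree order, into contiguous genera
  (sizes 1 + Poisson(mean−1), default mean 3 species) nested into families
  (default mean 3 genera) under a single order, so higher taxa are
  monophyletic blocks and totals partition exactly.
* **Scored sets** at coverage c have size round(c·n), floored at 2:
  *random* is a uniform subset; *clustered* is one uniformly chosen seed
  tip plus its n−1 nearest tips by patristic distance (neighbourhoods, not
  clades, so any target size is achievable exactly); *overdispersed* is a
  greedy maximin — start from the most distant pair, repeatedly add the
  tip with the largest minimum distance to the chosen set. Ties break by
  label, so both structured samplers are deterministic given the seed tip.

Defaults used throughout the recovery analyses: 64 tips, 25% coverage,
1000 null replicates, 200 trees per regime; the null-calibration analysis
uses 500 datasets of 32 tips with 8-tip focal sets. These sizes give
standard errors small enough that the regime ordering (clustered > random
> overdispersed mean NTI) is separated by well over two pooled standard
errors.

What the synthetic data does *not* emulate: extinction (no birth–death),
rate variation, supertree polytomies, non-monophyletic genera, or the
correlated, matrix-driven way real scored sets accumulate (one matrix
scores a whole subclade at once). Passing recovery tests therefore show
the statistics behave correctly under known regimes — not that any real
clade's coverage is random or clustered.

## Bundled census

`datasets.mammal_census()` ships the published per-order counts of scored
living mammal taxa (28 orders × 3 levels, plus class-wide rows). Feeding
them through the coverage classifier yields, under the strict thresholds:
10 orders low and 7 high at species level, 1 low and 16 high at genus
level, 0 low and 26 high at family level, and class-wide species coverage
of 847/5017 = 16.9%. The survey these counts come from reports slightly
different headline tallies (11, 15 and 25 for three of those six numbers);
those tallies are not reproducible from its own printed counts under any
consistent boundary rule — the borderline rows are Hyracoidea species 1/4
(exactly 25%), Cetartiodactyla genera 97/128 (75.8%) and Soricomorpha
families 3/4 (exactly 75%). This package reports what the counts and the
stated rule imply.

## Known limitations

* The normalizer does no synonym resolution; names that differ
  nomenclaturally from the taxonomy are excluded rather than mapped.
* Exemplar collapsing makes genus/family dispersion depend (weakly) on
  which species represents a group; with strongly non-monophyletic genera
  the collapsed matrix is not a genus-level tree metric.
* Only the uniform-draw null is implemented (no abundance weighting, no
  independent-swap); it matches the audit's question — where would n
  scored taxa fall by chance — but not community-matrix use cases.
* NEXUS ingestion reads taxon names only (TAXLABELS or MATRIX row labels)
  and expects well-formed files; character data are never interpreted.
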