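# Methods

This note documents the models, conventions and design choices behind
`alienphylo`, in the spirit of a statistical methods appendix: what is
computed, under which assumptions, with which defaults, and what the tests
on synthetic data do and do not establish about real data.

## Phylogenetic relatedness metrics

**Distances.** All metrics operate on patristic distances — sums of branch
lengths along tip-to-tip paths — computed in a single postorder pass
(d(i,j) = depth(i) + depth(j) − 2·depth(MRCA)). Branch-length units are
arbitrary (typically millions of years for dated trees); NRI/NTI are
invariant to uniform rescaling because observed and null statistics scale
identically.

**MPD and MNTD.** Presence-only MPD is the mean of d(i,j) over unordered
pairs; abundance weighting multiplies each pair by the product of the two
taxa's abundances. MNTD averages each taxon's distance to its nearest
co-occurring neighbour, abundance-weighted by the focal taxon's abundance.
These weightings follow the Phylocom lineage of implementations, the de
facto standard for these indices.

**Null model.** The tip shuffle permutes species labels across all tips of
the supplied phylogeny, preserving community size and abundance structure.
Because only the community's k labels matter after relabeling, a shuffle is
realized as a uniformly random ordered k-subset of tip indices; replicates
are drawn vectorized (argsort of i.i.d. uniform keys) and evaluated in
memory-bounded chunks. One set of shuffles per assemblage feeds both the
MPD and MNTD nulls, so NRI and NTI of a row share replicates (their nulls
are correlated, which affects no marginal inference and halves the cost).
The null pool is always the whole tree, not a per-scale species pool — the
documented behaviour of the "shuffle labels across the phylogeny" model.

**Standardized effect sizes.** NRI = −(MPD_obs − mean_null)/sd_null with
the population (N-denominator) sd; NTI likewise from MNTD. Positive values
indicate clustering. When the null has zero spread (e.g. the community is
the whole pool) the index is undefined and reported as NaN — flagged, never
silently zero, so downstream means are not biased. For unweighted
statistics on small trees, `ses_exhaustive` enumerates all k-subsets and
returns exact null moments; it is the oracle against which the Monte-Carlo
null is validated (on the 4-tip worked tree the exact NRI of a cherry pair
is √2).

**A property of z-scores worth knowing.** Because sd_null shrinks with
community size k (roughly ∝ 1/k for MPD under the tip shuffle), NRI
magnitudes grow with richness for a fixed degree of clustering. Comparing
mean NRI between groups of assemblages that differ systematically in
richness (e.g. spatial scales whose units differ 2× in species count)
therefore conflates clustering strength with statistical power. In the
synthetic world this richness dependence dominates the scale comparison:
coarse units hold about twice the species of fine units and come out with
higher mean NRI even though their per-species climate filtering is weaker.
The package reports the per-scale means as measured; interpreting them
requires richness-aware caution, which is equally true of published NRI
comparisons across scales.

**Anomalies.** anomaly = metric(All) − metric(subset) by default
(`all_minus_subset`). The verbal definition of the anomaly and the usual
narrative reading of "including invasive species created negative
anomalies" imply opposite signs; both conventions are implemented behind a
flag and every output row records which was used.

## Mega-tree grafting

Species absent from a backbone phylogeny are attached at their genus, in
the style of the standard mega-tree workflow: the genus basal node is the
MRCA of the genus' largest monophyletic cluster of tips (ties broken by the
shallower cluster, then alphabetically — a deterministic reading of the
"largest cluster" rule); the new tip joins it as a polytomy child with
pendant length equal to the node height, so ultrametric trees stay
ultrametric and distances among existing tips are untouched. A single-tip
genus has its pendant branch bisected; a genus absent from the backbone
attaches at a user-supplied family node by the same polytomy rule (this
family-level fallback is a documented simplification — the packaged
mega-tree tools place such species at fractional points of family branches,
behaviour they do not specify precisely; attachments at the family node are
logged). Genus is inferred from the `Genus_species` tip-label convention
unless an explicit tip set is supplied.

## Synthetic world

The generator produces data with the statistical structure the analysis
assumes, so every stage is testable without downloads:

- **Tree:** pure-birth (Yule) tree conditioned on the tip count. The
  underlying simulator stops at the n-th birth, which leaves the newest
  cherry with zero-length pendants; the final Exp(nλ) waiting interval is
  added to all pendant edges to complete the draw. One parameter
  (birth rate, default 1.0) suffices for ultrametric test trees.
- **Niches:** a temperature optimum per species evolved by Brownian motion
  (default rate σ² = 8 units²/branch-length unit from a root optimum of
  12 °C-like units) — close relatives prefer similar climates (niche
  conservatism). Niche breadth is a Gaussian tolerance (default 2.0).
- **Climate:** a lattice of cells with a temperature surrogate (BIO1)
  declining linearly with latitude (−0.7 °C/degree from 25 °C at the
  southern edge, cell noise sd 1.0) and a precipitation surrogate (BIO12)
  rising with longitude (+20 mm/degree from 200 mm, noise sd 50) — a
  China-like monotone climate field over a 73–135° E × 18–54° N extent.
- **Statuses:** introduced/naturalized/invasive in the emulated study
  proportions 165 : 222 : 319 (largest-remainder rounding). In
  `clade_biased` mode (the default) invasive labels are confined to the
  smallest clade covering the invasive share — invasion success is
  phylogenetically non-random, which gives the invasive subset its
  clustering signal. `random` mode scatters all labels.
- **Regions:** each spatial scale is an independent rectangular-lattice
  partition of the extent (unit counts default 7/16/34/47, mirroring
  habitat types, climate classes, provinces and ecoregions); interior
  breakpoints are jittered so scales cross-cut rather than nest.
- **Occurrences:** each species places points (default 124 per species,
  the emulated dataset's per-species average) in cells with probability
  proportional to its Gaussian niche density at the cell's BIO1 (log-space
  shift keeps far-from-optimum species numerically placeable), uniform
  within the cell. Temperature is the only filter by default; BIO12
  filtering is available via `use_precip`.

What this emulates: environmental filtering of conserved niches, hence
phylogenetic clustering that strengthens with the climate coherence of a
spatial unit. What it deliberately omits: dispersal limitation, biotic
interactions, sampling bias, spatial point-process structure below the
cell, coastline/ocean masking (dropping out-of-region points plays that
role), and realistic niche shapes. Tests passing on this world show the
*machinery* detects filtering when present and reports calibrated nulls
when absent; they do not validate ecological conclusions about any real
flora.

## Cleaning and communities

Occurrences are deduplicated on exact (species, lon, lat); spatial
rarefaction is greedy in input order with a fixed (species, lon, lat)
pre-sort for determinism: a record is kept iff it is ≥ 5 km (haversine,
R = 6371 km) from every previously kept record of the same species.
Thinning is per-species (the common default of thinning tools) and
idempotent. Points are assigned to the disjoint units of each scale;
boundary points go to the lexicographically smallest unit id, points in no
unit are dropped and counted. Per unit, seven community types are built by
status subsetting (Inv/Nat/Int, the three pairwise unions, and All);
assemblages with fewer than two species are emitted but flagged unusable.

## Statistics layer

Gaussian OLS is the default family for metric regressions (the response is
an unbounded z-score), with AIC recomputed as −2ℓ + 2k where k counts
intercept, slopes and the residual variance, and
AICc = AIC + 2k(k+1)/(n−k−1) (undefined, flagged, when n ≤ k+1). Presence
vs abundance scoring is chosen by the summed AICc of metric ~ community
type + scale fits, ties going to abundance. The two-way ANOVA uses Type-II
sums of squares (main-effect-focused, identical to Type-I in balanced
designs — asserted in tests); post hocs are Welch t by default (pooled t
available) with Holm step-down adjustment, implemented directly (sorted
ascending, running max of min(1, (m−i+1)p(i))) and cross-checked against
statsmodels. Spearman correlations use mid-ranks with the t-approximation
p-value.

## Problem sizes and numerical conventions

The test suite and the acceptance script run desk-scale configurations
chosen to exercise every code path with stable statistics: a 100-tip tree
with 500 communities × 999 shuffles for SES calibration; 500 random
tree/community/abundance triples (≤ 12 taxa) for oracle agreement; a
150-species world at 124 points/species and 499 shuffles for the
end-to-end run; 1000 simulated datasets for ANOVA type-I calibration;
10,000 points for the thinning contract. Production defaults remain
706 species, 9999 replicates, 5-km thinning. Seeds: every generator and
the null model take explicit integer seeds; the pipeline derives stage
seeds from the master seed, records them in the manifest, and identical
configs produce byte-identical CSVs. Floating point: distances and metrics
are float64 throughout; the exhaustive-null enumerator refuses more than
10⁶ subsets; ultrametricity checks default to tol 1e-9.

## Known limitations

- The family-node fallback for genera absent from a backbone is coarser
  than fractional-branch placement; flagged in logs per graft.
- Abundance = occurrence count is a crude abundance proxy inherited from
  the study design this pipeline serves.
- NRI/NTI comparisons across groups with different richness inherit the
  z-score scaling discussed above.
- The rectangular-lattice region generator produces area-based partitions;
  it cannot emulate climate-defined (non-contiguous, climatically
  coherent) region classes, whose filtering behaviour differs from equal
  -area tilings.
- Greedy thinning is order-dependent by construction; the fixed pre-sort
  makes it reproducible, not optimal (it does not maximize retained
  records).
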