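# alienphylo

Community phylogenetics of plant invasion stages.

Alien floras are mixtures of species at different points on the invasion
continuum — **introduced** (not yet self-sustaining), **naturalized**
(self-sustaining, not spreading) and **invasive** (spreading). Whether the
species of one stage are more closely related to each other than chance
predicts, and whether that relatedness changes with spatial scale and with
climate, speaks directly to how environmental filtering and niche
conservatism shape community assembly during invasion. `alienphylo`
implements the full analysis pipeline for this question: it builds
communities of alien species inside the spatial units of one or more region
partitions, scores each community's phylogenetic structure against a
tip-shuffle null model, and runs the comparative statistics — either on
user-supplied data (a newick phylogeny, an occurrence CSV, GeoJSON region
polygons, a climate table) or on a fully synthetic world whose generative
assumptions are explicit and testable.

## The statistics at the core

For an assemblage of $k$ taxa with pairwise patristic distances $d_{ij}$
(sums of branch lengths on the tree path between tips) and abundances
$a_i$:

- **MPD** (mean pairwise distance):
  $\mathrm{MPD} = \sum_{i<j} a_i a_j d_{ij} \big/ \sum_{i<j} a_i a_j$
  (unweighted: all $a_i = 1$).
- **MNTD** (mean nearest-taxon distance):
  $\mathrm{MNTD} = \sum_i a_i \min_{j \ne i} d_{ij} \big/ \sum_i a_i$.
- **Null model** (tip shuffle): species labels are permuted uniformly
  across *all* tips of the phylogeny and the statistic is recomputed for
  the relabeled community, preserving community size and abundance
  structure. The default is 9999 shuffles.
- **NRI / NTI** (net relatedness / nearest taxon index):
  $\mathrm{NRI} = -\,(\mathrm{MPD}_{obs} - \overline{\mathrm{MPD}}_{null})
  / \mathrm{sd}(\mathrm{MPD}_{null})$, and NTI likewise from MNTD.
  Positive values mean phylogenetic clustering, negative values
  overdispersion. The null sd uses the population ($N$-denominator) form.
- **Phylogenetic anomaly**: the difference between a metric computed on a
  unit's full three-status community and on one of its six status subsets
  (Inv, Nat, Int, InvNat, InvInt, NatInt).

Downstream, the package selects presence vs abundance scoring by AICc,
compares community types and spatial scales by two-way (Type-II) ANOVA with
Holm-adjusted Welch post hocs, regresses the metrics on temperature (BIO1)
and precipitation (BIO12) surrogates, and correlates the metrics between
community types (Spearman).

## Worked example

The 4-tip tree `((A:1,B:1):1,(C:1,D:1):1);` has d(A,B) = d(C,D) = 2 and
all other pairs at distance 4. For the community {A, B} the tip-shuffle
null over 2-taxon subsets takes the value 2 with probability 1/3 and 4 with
probability 2/3, so the exact null mean is 10/3 and the exact NRI is
$\sqrt{2}$:

```python
from alienphylo import (NullModelConfig, null_distribution, parse_newick,
                        patristic_distances, ses, ses_exhaustive)

tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
pm = patristic_distances(tree)
obs = pm.distance("A", "B")
mean, sd = ses_exhaustive(pm, community_size=2, stat="mpd")
null = null_distribution(pm, ["A", "B"], stat="mpd",
                         config=NullModelConfig(replicates=9999, seed=1))
print(f"observed MPD     = {obs}")
print(f"exact null       = {mean:.4f} +/- {sd:.4f}")
print(f"exact NRI        = {-(obs - mean) / sd:.4f}")
print(f"Monte-Carlo NRI  = {ses(obs, null):.4f}   (9999 tip shuffles)")
```

```
observed MPD     = 2.0
exact null       = 3.3333 +/- 0.9428
exact NRI        = 1.4142
Monte-Carlo NRI  = 1.4290   (9999 tip shuffles)
```

The positive NRI says A and B are closer relatives than a random pair from
the tree — phylogenetic clustering.

A small synthetic world, end to end (80 species with Brownian-motion
temperature niches, invasion statuses concentrated in one clade, two region
partitions):

```python
import pandas as pd
from alienphylo import RunConfig, run_all

cfg = RunConfig(seed=42, outdir="demo", replicates=999,
                simulation=dict(n_species=80, points_per_species=40,
                                units_per_scale={"habitat": 7,
                                                 "ecoregion": 47}))
run_all(cfg)
res = pd.read_csv("demo/metrics.csv")
ab = res[res.data_mode == "abundance"].dropna(subset=["NRI"])
print(ab.groupby("community_type")[["n_taxa", "NRI", "NTI"]].mean().round(2))
```

```
                n_taxa   NRI   NTI
community_type
All              33.68  3.54  1.28
Int               9.78  2.03  1.38
Inv              17.18  6.79  2.40
InvInt           24.46  3.31  1.19
InvNat           25.87  4.38  1.03
Nat              10.79  2.29  1.63
NatInt           19.07  2.84  2.15
```

Environmental filtering on conserved niches makes every community type
clustered on average (NRI > 0), and the invasive subset — concentrated in
one clade by construction — is by far the most clustered (NRI 6.8 vs 2.0
for the introduced subset). `demo/` also receives the anomaly table, the
per-stage statistics (`stats/*.csv`) and a JSON manifest with seeds and
row counts.

The same pipeline is available from the shell:

```sh
alienphylo run-all --seed 42 --out demo --replicates 999
alienphylo simulate --out demo        # or stage by stage:
alienphylo thin --out demo
alienphylo communities --out demo
alienphylo metrics --out demo
alienphylo anomalies --out demo
alienphylo stats --out demo
```

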