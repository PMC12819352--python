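# motifturnover

Comparative regulatory genomics asks how much of a lineage's cis-regulatory
code survives deep evolutionary time. `motifturnover` is a Python toolkit for
measuring transcription-factor binding-site (TFBS) turnover in gene-proximal
upstream windows across hundreds of genome assemblies on a shared phylogeny,
and for asking whether motif gains and losses track ecological niche. It is
aimed at plant and comparative genomicists who have, or can simulate, a set
of orthologous upstream sequences, a species tree, and per-species
environmental descriptors.

The pipeline has four stages, each usable on its own:

1. **Motif scanning** (`motifturnover.scan`) — position weight matrices are
   scored as log2-odds against a uniform background and thresholded at an
   exact p-value (default p < 1e-4) computed by dynamic programming over the
   discretized null score distribution. Both strands are scored at every
   position and the better one kept, so at most one hit is reported per
   position. Overlapping hits from motifs in the same matrix cluster are
   collapsed into single intervals; the count of merged intervals per
   500 bp upstream window is the currency of all downstream analysis.
2. **Enrichment** (`motifturnover.enrichment`) — candidate regulatory regions
   are dinucleotide-shuffled (exact Altschul–Erikson Eulerian-path shuffle)
   100 times; Poisson or negative-binomial nulls are fitted to the shuffled
   counts by maximum likelihood and selected by AIC; two-tailed p-values with
   Benjamini–Hochberg FDR (< 0.01) flag over- and under-represented motifs,
   and intersection patterns summarize enrichment shared across species.
3. **Shared occupancy** (`motifturnover.occupancy`) — for each target
   assembly and orthogroup, sharing relative to a reference is the
   capped-minimum fraction

   S_g = Σ_m min(n_target,m , n_ref,m) / Σ_m n_ref,m

   over motif clusters m present in the reference. Its decline with genetic
   distance x is summarized by nonlinear least squares as
   y = a·exp(−b·x) + c, with the asymptote c the deep-time sharing floor,
   against a random-gene-pair baseline; quartile classes and a two-sample
   Kolmogorov–Smirnov comparison (e.g. TF vs non-TF genes) characterize
   heterogeneity across orthogroups.
4. **Phylogenetic association** (`motifturnover.plmm`, `.assoc`) — motif
   counts or occurrence rates are regressed on 10 environmental principal
   components with the species tree's shared-branch-length matrix (phyloK)
   as a random-effect covariance:

   y = Xβ + u + e,  u ~ N(0, σ²_phylo·K),  e ~ N(0, σ²_resid·I)

   fitted by REML via a single spectral decomposition of K with the variance
   ratio profiled on a log grid — fast enough for batteries of hundreds of
   thousands of models. Wald χ²(1) tests per envPC term are FDR-pooled, and
   *permulations* (rank-matching observed trait values to Brownian-motion
   simulations on the tree) provide phylogenetically honest empirical nulls.

A synthetic-data generator (`motifturnover.simulate`) produces birth–death
trees, gain/loss motif-count evolution with a known Poisson(γ/δ) stationary
law, upstream sequences with the counts physically embedded as consensus
instances, and environmental traits with Brownian structure plus planted
linear effects — so every stage can be validated offline against ground truth.

## Worked example

```python
import numpy as np
import motifturnover as mt

# the capped-minimum sharing arithmetic on one orthogroup:
so = mt.shared_occupancy_orthogroup(target_counts={"A": 1, "B": 0, "C": 2},
                                    ref_counts={"A": 1, "B": 1, "C": 1})
# per-cluster shared occupancy: {'A': '100%', 'B': '0%', 'C': '100%'}
# shared instances: 2 / 3  overall: 67%

# a synthetic cohort with one planted motif-environment association:
sim = mt.simulate_dataset(mt.SimConfig(
    n_taxa=60, n_orthogroups=40, n_clusters=3, master_seed=7,
    effect_map={("og0003", "cluster01"): ("envPC2", 0.5)}))
K = mt.phylo_k(sim.tree)
shared = mt.global_shared_occupancy(sim.counts, ref_assembly="t001")
bat = mt.run_orthogroup_models(sim.counts, sim.env, K,
                               min_motif_taxa=5, min_og_taxa=40)
print(bat.results.sort_values("q").iloc[0])
```

Fitting the decay of mean shared occupancy against tree distance from the
reference tip prints:

```
Exponential decay fit: y = a*exp(-b*x) + c
  n_obs      59
  a          0.151456
  b          0.245291
  c          0.63457   (asymptote)
  rss        0.0644679
  converged  True
```

so sharing drops with divergence toward a floor of about 63% — close to the
analytic stationary sharing level for the generator's gain/loss rates
(`mt.stationary_shared_fraction(1.0, 0.5)` ≈ 0.66). The association battery
(120 models) ranks the planted pair first:

```
120 models; top association: cluster01:og0003 envPC2 beta=0.426 q=5.68e-06
```

Every number above is produced by the code as shown.

There is also a thin CLI (`motifturnover simulate|scan|enrich|occupancy|
assoc|permulate`) over the same functions; `motifturnover --help` lists the
subcommands and the YAML config keys their flags override.

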