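# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `motifturnover`, in the order the pipeline runs.

## Motif scanning

Motifs are position frequency matrices over {A, C, G, T}. Scoring is
log2-odds against a background base composition b:

    score(i, base) = log2((p_i,base + pc·b_base) / ((1 + pc)·b_base))

with pseudocount pc (default 0.1; pc = 0 maps zero probabilities to a large
negative finite sentinel rather than −∞ so the dynamic program stays
well-defined). The default background is uniform (0.25 per base), chosen to
keep detection thresholds comparable across assemblies with different
compositions.

**Exact p-value threshold.** The null distribution of the window score under
the background model is computed exactly on a discretized grid: each
column's scores are shifted to nonnegative integers on a common scale
(default 1000 bins per column, round-down) and the per-column integer score
distributions are convolved. The reported threshold is the minimal grid
score whose survival probability is ≤ the p threshold (default 1e-4). The
discretization error of any window score is bounded by w/scale (exposed as
`ScoreDistribution.step`); tests compare the scanner to exhaustive 4^w
enumeration and treat only scores within one step of the threshold as
borderline. Low-information motifs for which even the maximum score has tail
probability above the threshold are assigned an unreachable threshold and
simply never match — mirroring how short/degenerate motifs drop out of any
exact-p scan.

**Strand handling.** Both strands are scored at every start position and the
better kept (ties go to the forward strand), so at most one hit per
position. Windows containing any N are skipped rather than averaged — the
conservative choice, consistent with the ≥5%-N discard rule for whole
windows.

**Windows.** Upstream regions are the `window_bp` (default 500, 1000
supported) bases 5′ of the translation start: `[start − window_bp, start)`
on the plus strand, the reverse complement of `[end, end + window_bp)` on
the minus strand. Regions with insufficient contig sequence or more than 5%
N are rejected with a machine-readable reason. All coordinates are 0-based
half-open; BED6 is the only interval export.

**Cluster collapsing.** Hits from motifs in the same matrix cluster whose
intervals share at least one base are merged transitively, strand-blind
(the merge policy is our choice; strand-aware merging would only split
near-coincident palindromic hits). The instance count per (window, cluster)
is the number of merged intervals. Counts of merged intervals — presence
multiplicity, not match strength — are the only downstream currency.

## Enrichment against dinucleotide-shuffled backgrounds

Each region is shuffled by the Altschul–Erikson algorithm: a uniform random
Eulerian path on the dinucleotide multigraph, so the output preserves the
dinucleotide count multiset exactly and the terminal bases; runs of N split
the sequence into independently shuffled segments. Default 100 shuffles per
region; per-replicate total motif counts form the background sample.

Backgrounds are fitted by maximum likelihood as Poisson and negative
binomial (mean fixed at the sample mean, dispersion profiled) and selected
by AIC; constant or otherwise unfittable counts fall back to the empirical
distribution. These two families cover equi- and over-dispersed motif
counts. The test is two-tailed, p = min(1, 2·min(P(X ≤ obs), P(X ≥ obs))),
with log2 fold change log2((obs + 0.5)/(mean + 0.5)) (the +0.5 continuity
term handles zero counts). FDR is Benjamini–Hochberg within species across
motifs at 0.01; FDR is applied per species rather than pooled, a choice we
document rather than assert. A pooled 2×2 Fisher's exact test (hit vs
non-hit scan positions, real vs mean-shuffled) is reported alongside for
parity with count-based over-representation testing. Cross-species
summaries count motifs per species-subset membership pattern (upset-style)
plus the union and the all-species intersection.

## Shared motif occupancy

For one orthogroup, with target counts n_t,m and reference counts n_r,m per
cluster m:

    s_m = min(n_t,m, n_r,m) / n_r,m
    S_g = Σ_m min(n_t,m, n_r,m) / Σ_m n_r,m

Clusters absent from the reference are excluded from numerator and
denominator — turnover is measured with respect to the reference's
instances only — and a target count above the reference contributes exactly
the reference count, so all quantities live in [0, 1]. Orthogroups whose
reference total is zero are excluded with a reason. Per assembly we report
both the unweighted mean of S_g over shared orthogroups and the pooled
ratio Σ min / Σ ref; the two can differ when orthogroups vary in motif
content, so both are always emitted rather than silently picking one.

The random-pair baseline treats one reference gene as "target" and another
as "reference" over n ordered pairs (default 100,000) sampled uniformly
with replacement across pairs; it estimates the sharing expected between
unrelated genes.

**Decay fit.** Mean sharing vs genetic distance is fitted as
y = a·exp(−b·x) + c by bounded nonlinear least squares
(`scipy.optimize.curve_fit`), initialized at a₀ = max(y) − min(y),
c₀ = min(y), and b₀ from a log-linear regression of y − c₀, with b ≥ 0 and
c ∈ [0, 1]. Flat inputs short-circuit to a = 0, c = mean(y) with a `flat`
diagnostic since b is then unidentified; non-convergence is reported
honestly on the results object. At least 4 points and non-degenerate x are
required.

**Stratifications.** Quartile classes of mean sharing are computed after
requiring an orthogroup in ≥ 200 taxa (to avoid lineage-specific-gene
bias); values tied at either quartile boundary go to the more extreme
class, which makes the classification deterministic and idempotent. Group
contrasts (e.g. TF vs non-TF orthogroups) use the asymptotic two-sample
Kolmogorov–Smirnov test. Occurrence rates are instances per upstream
region; cluster-level variability across assemblies is the median rate and
the coefficient of variation using the sample (n − 1) standard deviation.

## Phylogenetic distances and covariance

K81 (Kimura three-substitution-type) distances between aligned sequences
use pairwise deletion of non-ACGT columns and

    d = −¼ [ln(1−2P−2Q) + ln(1−2P−2R) + ln(1−2Q−2R)]

with P the transition proportion and Q (A↔T, G↔C) and R (A↔C, G↔T) the two
transversion classes; a nonpositive log argument flags saturation and
returns d = ∞. The phyloK matrix holds, per tip pair, the root-to-MRCA path
length (diagonal: root-to-tip length); under Brownian motion it is the
trait covariance up to rate, and it is positive semidefinite by
construction. A ridge of 1e-8 × mean(diag) is added before decomposition to
absorb zero-length terminal branches.

## The phylogenetic linear mixed model

y = Xβ + u + e with u ~ N(0, σ²_phylo·K) and e ~ N(0, σ²_resid·I), fitted
by REML. With K = U·diag(s)·Uᵀ computed once per taxa set, the rotated
model has independent errors with variances λ·s_i + 1 where
λ = σ²_phylo/σ²_resid; σ²_resid is profiled out analytically and the
restricted likelihood is maximized over λ on a 100-point log grid spanning
1e-5..1e5 refined by golden-section search. β̂ and its standard errors come
from GLS at the optimum. The single-decomposition design is what makes
half-million-model batteries tractable; decompositions are cached per taxa
set across models. Collinear design columns are dropped greedily
left-to-right (earlier terms win) and reported. Counts are modeled as
Gaussian responses — fidelity to standard practice with commercial mixed
model engines over distributional purity; no GLMM is attempted.

Wald tests use (β̂/se)² against χ²(1). FDR is Benjamini–Hochberg, pooled
across all envPC terms within a battery; non-converged models are excluded
from FDR with a count reported. Missing data are handled complete-case per
model.

**Batteries.** Global: one model per motif cluster, response = occurrence
rate, fixed effects = 10 envPCs + global motif density + 5 mono/dinucleotide
composition PCs (computed from background sequences such as short introns:
4 + 16 frequencies, each block normalized, centered PCA with a
deterministic sign convention). Orthogroup-specific: one model per
(cluster, orthogroup) pair with response = motif count, fixed effects = the
10 envPCs, filtered to motifs present in ≥ 10 taxa at the orthogroup and
orthogroups present in ≥ 200 taxa (model instability filters).

**Permulations.** A Brownian trait (root 0, rate 1) is simulated on the
tree and the observed values of the focal predictor are reassigned by
matching observed ranks to simulated ranks — a permutation of the data that
retains phylogenetic signal. Only the focal envPC column is replaced
("holding the other envPCs constant" is read as fixing the other columns);
the model is refitted per replicate (default 1000) and the empirical p uses
the add-one rule (1 + #{null ≥ obs})/(n + 1). Results are flagged when more
than 10% of refits fail to converge. RNG streams are child-seeded from a
master seed.

## Synthetic data

The generator's defaults are the study conditions the tests run under:
300 taxa, pure-birth tree (birth 1.0), 200 orthogroups, 5 clusters, root
count 2 per cluster, gain rate γ = 1 per branch-length unit, per-copy loss
rate δ = 0.5, Brownian rate 1, i.i.d. noise sd 0.5, 500 bp windows at 50%
GC, width-8 motifs with 0.97 consensus dominance. These give a tree deep
enough (height ≈ ln n) for substantial turnover with a stationary count law
Poisson(γ/δ) = Poisson(2), environmental traits dominated by phylogenetic
structure, and planted effects of β = 0.5 that are detectable but not
trivial at these sample sizes.

Trees come from an explicit Gillespie birth–death sampler started from the
two daughters of the root and stopped the instant the n-th extant lineage
appears (tips cut at that time, hence ultrametric); replicates where a root
subtree dies out are rejected. This conditioning makes the pure-birth
height expectation Σ_{k=2}^{n−1} 1/(kλ) exact, which the tests use as an
analytic oracle. Counts evolve per branch by Gillespie simulation of the
gain/loss chain, with every event logged so that tip count = root count +
gains − losses holds exactly along each root path. Sequences realize the
counts as non-overlapping consensus embeddings at uniform positions on an
i.i.d. background, so scanning the simulated FASTA must reproduce the
simulated table up to scanner false positives. Environmental traits are
envPC_j = BM_j + Σ β·count + noise for planted (orthogroup, cluster) →
(envPC, β) effects.

What the generator does **not** emulate: realistic grass genome
composition, indels, motif (PWM) evolution, correlated environmental axes,
unequal assembly quality, or missing orthologs. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
model's own assumptions, not that real upstream regions satisfy those
assumptions.

## Problem sizes used by the test suite

The suite exercises the statistics at sizes chosen to make Monte Carlo
standard errors small while keeping the whole run in minutes: null
calibration of the mixed model uses 1000 models on a 100-taxon tree
(fraction of envPC terms with p < 0.05 asserted within [0.03, 0.07]);
heritability and effect recovery use 50 replicates at 200 taxa (median
within ±0.1 of truth); the planted-association battery uses the generator
defaults (300 taxa × 200 orthogroups × 5 clusters = 1000 models, 10,000
envPC terms) with five planted effects, asserting ≥ 4/5 recovered at
q < 0.01 and ≤ 1% false terms on one master seed; permulation concordance
uses 100 null models × 200 permulations (Spearman ρ between permulation and
parametric p > 0.9 — the library default remains 1000 permulations);
scanner-vs-enumeration equivalence covers widths 2–8 on 200 random
100-mers per width; the dinucleotide shuffle is checked exactly on 1000
random 200-mers.

## Known limitations

- The Gaussian response is an approximation for low counts; a count GLMM
  could sharpen orthogroup-level inference but would not reuse the
  spectral-decomposition trick.
- The exact-p scanner matches enumeration only up to the discretization
  step; motifs whose score spectrum is coarse near the threshold can differ
  from an un-discretized scanner on borderline windows.
- The decay fit treats per-assembly mean sharing values as independent
  observations; phylogenetic pseudo-replication among closely related
  target assemblies is not modeled.
- Enrichment FDR is within-species; pooling across species would change
  borderline calls.
- The permulation null assumes the focal predictor is well described by
  Brownian motion on the tree; traits with strong selection regimes may
  need other null processes.
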