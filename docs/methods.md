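# Methods

This document records the models, estimators, default constants, numerical
choices and known limitations behind every module. Units are stated
explicitly everywhere; internally, times in demographic models are in
generations before present, rates in the dating arithmetic are per year.

## 1. Sequence data and distances

Alignments are ungapped nucleotide matrices (`HaplotypeAlignment`) with a
per-sequence population label and per-population site metadata (latitude,
longitude, sample size). Ragged FASTA input is rejected, not padded.

Pairwise distances: uncorrected p-distance, and Tamura–Nei (1993) with the
standard two-transition-rate correction; when the TN93 logarithm argument
is non-positive (saturation) the pair is flagged and capped at twice the
largest finite distance in the matrix rather than silently dropped.
Geographic distances are great-circle kilometres on a spherical Earth
(R = 6371.0088 km). `pool_to_threshold` merges populations below a minimum
sample size into their nearest (great-circle) neighbor, deterministically.

## 2. Diversity and neutrality statistics

- Haplotype diversity Hd = n/(n−1)(1 − Σp̂ᵢ²); nucleotide diversity π is
  the mean pairwise p-distance; Watterson's θ from S segregating sites is
  returned per site, per locus, and with the harmonic number a_n.
- Fu's F_S uses the exact Ewens sampling formula through the Stirling
  recursion for P(K ≥ k | θ̂ = k̄), computed in log space; F_S = ln(S'/(1−S')).
- R² (Ramos-Onsins & Rozas 2002) from singleton counts and k̄.
- Fay & Wu's H needs an outgroup sequence to polarize derived states; sites
  where the outgroup carries a third state are skipped.
- Significance for F_S and R² comes from coalescent simulation under the
  standard neutral model conditioned on the observed n and θ̂_π
  (`simulation_pvalue`), reporting the lower-tail probability, which is the
  tail where expansion pushes both statistics.

## 3. Mismatch distribution and expansion dating

### Model and fit

The sudden-expansion model (Rogers & Harpending 1992) gives the expected
mismatch distribution F_j(τ, θ₀, θ₁). The fit minimizes the sum of squared
deviations (SSD) between observed and expected relative frequencies with
`scipy.optimize` (L-BFGS-B) from a deterministic multi-start grid:
τ ∈ {0.5, …, 10}, θ₀ ∈ {0, k̄/2}, θ₁ ∈ {k̄, 10k̄, 1000}, bounds
τ ∈ [0, 60], θ₀ ∈ [0, 100], θ₁ ∈ [10⁻⁶, 5000]. Ties are broken by lowest
SSD, then lowest τ, so fits are reproducible.

### Goodness of fit and confidence interval

SSD and the raggedness index r are referred to a parametric bootstrap:
datasets are re-simulated by coalescent under the fitted parameters, refit,
and the p-value is the fraction of simulated statistics at least as extreme
(upper tail). The τ confidence interval is the 2.5/97.5 percentile of the
bootstrap τ̂ distribution. Bootstrap refits start from three representative
points (the original fit, and two data-driven starts with θ₀ at zero and at
k̄/2) rather than from the original fit alone: the SSD surface has distinct
local minima — θ₀ can be absorbed into τ, and θ₁ can collapse to a corner
"spike" solution — and warm-starting every refit at one of them understates
the estimator's sampling noise and produces falsely tight intervals.

### Known estimator limitations

- τ and θ₀ are only weakly separately identifiable: for moderate θ₀ the
  fitted τ̂ tends toward τ + θ₀, so dating is biased upward when the
  pre-expansion population was not small. Calibration experiments therefore
  use θ₀ = 0.5; at θ₀ = 5 interval coverage collapses (this is a property
  of the model, not of this implementation).
- The raggedness test is conservative-to-nominal at moderate θ; at large θ
  overfit boundary solutions can smooth the bootstrap reference
  distribution and inflate rejections.

### Dating arithmetic

`expansion_time(tau, rates, mode="study")` converts τ to years as
t = τ · T / (2 μ L T) with μ the per-site per-year rate. Defaults:
μ = 7.12×10⁻⁹/site/yr, L = 1140 sites, T = 1/3 yr, giving
≈ 20 534 years per τ unit. The CI in years is the τ CI passed through the
same linear map. `mode="generations"` returns τ/(2u) generations instead.

## 4. Spatial structure

- **AMOVA** (Excoffier et al. 1992): two- or three-level variance
  decomposition from pairwise distances, treating the supplied distances
  directly as squared Euclidean distances (the molecular convention).
  Φ statistics are tested by permutation: individuals among populations
  (Φ_ST, Φ_SC within groups) and whole populations among groups (Φ_CT).
  A brute-force independent implementation in the test suite checks the
  variance components on random small designs.
- **SAMOVA**: maximizes Φ_CT over spatially contiguous K-partitions
  (contiguity on the Delaunay graph of site coordinates) by simulated
  annealing with multiple random starts; the best partition's Φ_CT is then
  permutation-tested. `permutations=0` skips the test for speed in
  recovery experiments.
- **Monmonier barriers**: on the Delaunay triangulation, the barrier grows
  from the edge with the largest (population-pairwise Φ_ST) distance and
  extends across the triangulation perpendicular to successive maxima.
  Edge support is estimated by bootstrapping alignment columns and
  recomputing the barrier.
- **Mantel**: matrix correlation with permutation p-value; the canonical
  isolation-by-distance form correlates Φ_ST/(1−Φ_ST) with ln km.

## 5. Statistical parsimony networks

The 95% connection limit is the largest number of mutational steps j such
that the probability of parsimony (Templeton–Crandall–Sing) exceeds 0.95
for the given sequence length. Haplotypes are connected in order of
increasing distance up to the limit, inserting unsampled intermediate nodes
on multi-step connections. `classify_and_root` ranks sampled haplotypes as
root candidates by (connectivity, frequency) — the outgroup-weight
heuristic — and classifies haplotypes as tips (degree 1) or interior.
Star-like networks (many tips radiating from few interiors) indicate
expansion.

## 6. Allozyme analyses

Allele-frequency tables per population × locus. Expected heterozygosity
He = 1 − Σp², optionally with the 2N/(2N−1) correction. Private-allele
richness counts alleles present in exactly one group, averaged over loci.
Nei's (1978) unbiased D corrects within-population identities by
(2N Σp² − 1)/(2N − 1); because that correction can push the identity above
1 for very similar populations, D is clamped at 0. Complete fixation on
different alleles gives infinite D, flagged and capped as in §1.
Neighbor joining follows Saitou & Nei with optional midpoint rooting;
principal coordinates use Gower double-centering (negative eigenvalues
reported, excluded from the variance denominator). Cline regression is OLS
of a per-population statistic on latitude with the exact t-test.
Two-sample comparisons use Mann–Whitney U (exact for n+m ≤ 12 without
ties) and Kolmogorov–Smirnov.

## 7. Coalescent simulation in population trees

A `PopulationTreeModel` is a rooted tree of branches, each spanning a time
interval (generations before present) with piecewise-constant Ne. Gene
trees are simulated by the standard coalescent within each branch segment
(exponential waiting times with rate C(k,2)/Ne), with surviving lineages
merged at population splits. Sequences evolve on the gene tree under TN93.

Calibration: for a single constant-size population the simulator reproduces
E[T₂] = Ne, E[T_MRCA] = 2Ne(1 − 1/n), and E[S] = θ a_{n−1} within Monte
Carlo error (checked in the test suite).

`build_hypothesis_model` constructs the competing demographies used
throughout, parameterized by overall Ne (default from θ = 2NeμL),
colonization start (default 15 ka), LGM start (default 18 ka), glacial
bottleneck fraction (default 0.1), generation time and tip Ne proportions:

- `expansion_contraction`: tips exist from 0 back to the colonization
  time, each at a proportion of the overall Ne; the single ancestor runs to
  the total species time with the bottleneck between colonization and LGM.
- `four_refugia`: the tip lineages are separate for the entire history.

## 8. Deep-coalescence hypothesis testing

`count_deep_coalescences` fits a gene tree into a population tree by the
minimum-extra-lineages embedding and returns nDC, the total number of extra
lineages summed over population-tree edges. Polytomies in the gene tree are
resolved arbitrarily (consistently) before counting. The implementation is
checked against an independent brute-force oracle that enumerates every
embedding; the test suite and acceptance script verify exact agreement over
an exhaustively enumerated family of gene-tree/population-tree pairs
(all gene topologies on up to 6 leaves, generated by leaf insertion on
every edge, against all rooted population topologies on 2–4 populations).
Full enumeration beyond that size is combinatorially infeasible; the bound
is a choice of problem size, not of correctness.

The hypothesis test simulates `reps` genealogies under the null
demographic model, counts nDC of each against the null population tree,
and reports the one-tailed p = (1 + #{sim ≥ obs})/(reps + 1). Because nDC
is integer-valued, the achievable test size is granular: probability mass
≈ 0.1 can sit on single atoms near the 5% tail, so the realized size of a
nominal 5% test depends on the sample configuration and typically lands
between 0.02 and 0.09. A precomputed null distribution can be shared
across tests of many observed trees (`null_distribution=`), which is
statistically valid because the null does not depend on the observed data.

Power against old subdivision: a genealogy generated under long-isolated
refugia and scored with a population grouping that cuts across the isolated
lineages forces nDC far above the null range. If instead the grouping is
aligned with the isolated lineages, nDC is near zero — old subdivision with
perfectly sorted lineages is invisible to an upper-tail nDC test. The
package's power experiments use the cross-cutting (round-robin) grouping
for exactly this reason.

`mdc_species_tree` searches all rooted population topologies (feasible to
7–8 populations) for the minimize-deep-coalescence tree.

## 9. Synthetic data

All generators are seeded (`numpy.random.default_rng`) and deterministic.

- `make_sequence_dataset(SyntheticSpec)`: coalescent sequences under a
  structured model — populations optionally partitioned into groups with a
  given divergence time, optional growth. Planted effects are recovered by
  the package's own estimators in the test suite (expansion signal,
  spatial grouping).
- `make_expansion_dataset`: single population under sudden expansion with
  true (τ, θ₀, θ₁), for mismatch calibration.
- `make_allozyme_dataset`: Beta-distributed major-allele frequencies whose
  expectation follows a latitudinal He cline, plus extra private alleles in
  refugial (southern) populations. With `cline_slope=0` and
  `private_allele_freq=0` the generator is flat in latitude; the private
  allele mechanism by itself shifts He south, so calibration tests of the
  cline regression disable it.

What the synthetic data does **not** show: it is not a reanalysis of any
empirical dataset; effect sizes are chosen so that planted effects are
recoverable at small-to-moderate sample sizes, and recovery rates reported
by the tests are properties of those configurations, not of any organism.

## 10. Numerical and reproducibility choices

- All stochastic entry points take explicit integer seeds; derived seeds
  are drawn below 2³¹.
- Optimization uses deterministic multi-start grids with explicit
  tie-breaking (§3); annealing uses a fixed geometric cooling schedule.
- Permutation and bootstrap p-values use the (1 + #extreme)/(N + 1)
  convention, never exactly zero.
- Monte-Carlo experiment sizes in the test suite were chosen so that
  asserted thresholds sit ≥ 2–3 standard errors from measured rates.

## 11. Limitations

- Single-locus genealogical inference: all sequence-based conclusions rest
  on one realization of the coalescent; the hypothesis-testing machinery
  accounts for this (the null distribution is over genealogies), but
  parameter estimates (τ, θ) inherit the full genealogical variance.
- The mismatch estimator's τ/θ₀ confounding (§3) limits dating accuracy
  when the pre-expansion population was large.
- The nDC test is one-tailed and blind to subdivision whose lineages are
  already sorted into the tested grouping (§8).
- SAMOVA and Monmonier depend on the Delaunay graph of the sampled sites;
  sparse or collinear sampling changes the reachable partitions.
- TN93 distances saturate for deeply diverged pairs; capped values are
  flagged but still approximate.
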