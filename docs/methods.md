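# Methods

`phylodemo` tests competing demographic histories for a subdivided
population — here shaped like a Neotropical seasonally-dry-forest tree
sampled in 17 populations — by simulating each hypothesis under a
structured coalescent, evolving sequences on the simulated genealogies,
and scoring the observed sequence diversity against the simulated
distributions. A companion set of spatial analyses relates diversity to
habitat suitability through glacial time.

## Demographic scenarios

Each hypothesis is a set of deme trajectories over the interval from
the present (t0) back to a horizon placed at the Last Glacial Maximum:
21,000 years at 15 years per generation, i.e. 1,400 generations.
Deme sizes interpolate exponentially between the present size N0
(default 10,000 lineage copies per deme) and the horizon size N1, with
rate g = ln(N1/N0)/t, so N(tau) = N0·e^{g·tau} backward in time. This is
the standard serial-coalescent growth parameterization: a negative g
read forward in time is a population expansion.

Backward in time, every lineage outside the source deme (deme 1)
migrates into it with probability 0.01 per generation — a finite-island
model in which all present demes descend from lineages in the source. A
deme flagged *extinct before the horizon* shrinks linearly from N0 to a
single lineage copy at the horizon (the schedule of the shrink is not
constrained by anything observable, so the simplest monotone schedule
over the full horizon is used; the window is configurable).

The four hypotheses differ in which demes persist at the horizon and in
the horizon sizes. The per-deme N1/N0 ratios are explicit configuration
(defaults: 0.1 for expansion-type scenarios, 10 for the retraction),
because no published numeric values exist for them. Because after the
horizon all surviving lineages coalesce inside the source deme, the
source deme's horizon size is the single most informative quantity of a
scenario; it is set to the total ancestral population each hypothesis
implies:

| hypothesis | non-source demes | source deme N1 | reading |
|---|---|---|---|
| PLAH | all persist at 0.1·N0 | D·0.1·N0 | widespread connected glacial arc |
| PPPH | extinct backward | 0.1·N0 | range shift into a single source region |
| BOTH | half persist, half extinct | (1+8)·0.1·N0 | arc expansion plus shift |
| RETRACTION | extinct backward | 10·N0 | larger past population, glacial retraction |

This geometry makes the four hypotheses statistically distinguishable
in pooled diversity: a design requirement, since with identical horizon
sizes the 1 %/generation migration empties every deme long before the
extinction shrink has any effect, and expansion scenarios would be
observationally identical.

The mutation-parameter conversion Ne = theta/(c·mu) uses c = 2 for
haploid-transmitted loci (chloroplast) and c = 4 for diploid nuclear
loci.

## Coalescent simulator

The simulator runs discrete generations backward in time, which matches
the per-generation definition of migration and the short (1,400
generation) structured phase. Within a deme holding k lineages of
current size N, the number of coalescing pairs per generation is
Binomial(k(k−1)/2, 1/N), the Wright–Fisher small-sample limit; if
sampled mergers would involve a lineage twice, the mergers are resolved
by random disjoint pairing with at most one merger per lineage per
generation. For two lineages this gives exactly the geometric waiting
time with mean N; for larger samples the discretization bias is O(k²/N).
Migration is applied before coalescence within each generation. At the
horizon all surviving lineages move to the source deme, which then
persists at its horizon size until the MRCA; in this constant-size
phase, generations with no event are skipped by a geometric draw (an
exact acceleration, not an approximation). The per-generation loop is
JIT-compiled (numba); a 257-lineage, 17-deme replicate takes ~1 ms.

Validation: mean pairwise coalescence time matches the analytic N, mean
TMRCA for n = 10 matches 2N(1 − 1/n) within Monte-Carlo error, and the
full TMRCA distribution is indistinguishable (two-sample KS) from
msprime's continuous-time simulator at matched parameters.

Recombination is not modelled, and samples are contemporaneous. A
per-partition deme-size multiplier is exposed (default 1) to express
organellar/nuclear effective-size differences if desired.

## Sequence evolution

HKY85 and TIM1 are materialized as constrained GTR generators (TIM1
uses the 012230 exchangeability pattern: AC=GT, AT=CG, AG and CT free),
scaled to one expected substitution per unit of mu·t at stationarity.
Among-site rate variation uses the discrete-gamma approximation with
four equiprobable categories by default (configurable); each site
carries its category's mean rate, and category means are computed from
the incomplete-gamma identity and renormalized to average exactly 1.
The study-like shape parameters are extreme (alpha = 0.017 for the
chloroplast partition, 0.010 for ITS), concentrating nearly all change
in a small fraction of sites.

Mutations are placed by uniformization: virtual events arrive as a
Poisson process at the dominating rate mu·r_s·qmax per site, and each
event applies the jump kernel I + Q/qmax. This samples the exact
continuous-time chain — stationarity is preserved without matrix
exponentials — while touching only sites that actually mutate, which is
what makes 2,000-replicate scenario distributions affordable. The root
sequence is drawn from the stationary frequencies.

Mutation rates per site per generation are required configuration with
no authoritative published value; the synthetic-study defaults (5e-7
for cpDNA, 1.2e-6 for ITS) were chosen once so that pooled diversities
under the generating scenario fall in the empirically typical range
(h ≈ 0.87, pi of order 1e-3), and are recorded in every output's truth
metadata. Indels and mononucleotide microsatellites are not simulated.

## Diversity statistics

Columns containing a gap or ambiguity in any sequence are removed
alignment-wide before any statistic is computed; haplotype identity is
exact string equality on the remaining columns. Haplotype diversity is
Nei's unbiased h = n(1 − Σp_i²)/(n − 1); nucleotide diversity is the
mean pairwise proportion of differing sites; phi_ST follows the
Excoffier AMOVA variance decomposition on squared pairwise distances
(number of differing sites), with significance from permutation of
individual population labels. The permutation p is the plain proportion
of permuted statistics at or above the observed (no +1 correction),
mirroring Arlequin. Negative variance components are reported as
computed; a [−1, 1]-clamped phi_ST is carried in a separate field.
Standard deviations of h and pi, when requested, come from a bootstrap
over sites rather than analytic variance formulas.

## Model selection

For each scenario × partition, n_sim (default 2,000) replicates of
genealogy + alignment are simulated and pooled-sample h and pi are
computed by the same code used for observed data. Scores:

* two-tailed probability P = min(1, 2·#{sim > obs}/n_sim), strict
  inequality, ties counting below; P can only exceed 1 by the raw
  formula, so it is capped.
* empirical log-likelihood ln L = ln(height of the histogram bin
  containing the observed value / maximum bin height). The ratio (not
  product) reading is used because a product of a frequency by the
  modal frequency has no likelihood interpretation and exceeds 1;
  the ratio is bounded in [0, 1] and preserves ranking by closeness to
  the simulated mode. An observed value outside the simulated range
  gives ln L = −inf and an infinite AIC rather than an exception.
  Histograms use the Freedman–Diaconis rule, falling back to 50 equal
  bins when the IQR is zero; the rule is recorded in the results.
* AIC = −2 ln L + 2K with K = 2; delta-AIC and normalized Akaike
  weights follow, and scenarios within delta-AIC < 2 of the best are
  flagged equally plausible.

Where a single winning hypothesis is needed (the recovery experiment),
the h and pi log-likelihoods are summed per scenario before forming the
AIC — the two statistics treated as independent lines of evidence — so
a hypothesis must fit both to win.

All replicate streams derive from one master seed through named
`SeedSequence` spawns; the full comparison is bit-reproducible.

## Spatial analyses

Geodesic distances are great-circle (haversine) on a sphere of radius
6,371 km. Isolation by distance is a Mantel test of Slatkin-linearized
phi/(1 − phi) against log10 distance; zero distances are floored at
half the smallest positive distance before the log. The Mantel p is
two-sided (|r_perm| ≥ |r_obs|) by simultaneous row/column permutation,
default 10,000 permutations; an exact-enumeration variant exists for
small fixtures.

Climate stability per cell is minus the mean absolute pairwise
difference of suitability across the time slices (0 = perfectly
stable), so regressions of diversity on stability read naturally; the
historical-refugium mask is the intersection of suprathreshold cells
across slices. Range centroids are unweighted means of suprathreshold
cell centers (suitability-weighting would blur the thresholded-map
reading). Quantile regressions of diversity against suitability,
stability, or centroid distance minimize the pinball loss, solved
exactly as a linear program (HiGHS), which is deterministic and handles
perfect fits and the tau = 0.5 least-absolute-deviation case without
iteration-tolerance concerns; any list of quantiles can be fit.

## Synthetic data

The generator reproduces the study's *shape*: 17 populations with the
published per-population sample sizes (totalling 257; the summary
count of 235 individuals quoted elsewhere disagrees with the
per-population table, and the table's sum is used), three regional groups, a 1,742 bp chloroplast
partition under HKY+Gamma and a 518 bp ITS partition under TIM1+Gamma,
fictional but regionally clustered coordinates on a 0.5° grid, and
smooth random suitability rasters with a controllable eastward
displacement of the LGM slice so centroid shifts and stability
gradients are non-trivial. It does not attempt to mimic real haplotype
network topology, geographic realism of the maps, or clustering
structure; passing tests demonstrate the correctness and power of the
machinery under the declared generating model, not conclusions about
the real species.

## Problem sizes in the shipped checks

The shipped acceptance checks use 2,000 replicates for the analytic
coalescent/Watterson comparisons, 20 repetitions × 500 simulations per
scenario for hypothesis recovery, and 1,000–10,000 permutations for the
permutation tests; the acceptance script uses 10 × 200 for the recovery
rate. These sizes give Monte-Carlo error comfortably below the assertion
tolerances.

## Known limitations

* Discrete-generation coalescence is biased O(k²/N) when deme sizes are
  small relative to sample sizes; extinct-deme shrink phases rely on
  the one-merger-per-lineage cap near size 1.
* The empirical likelihood depends on the histogram binning; the
  Freedman–Diaconis choice is recorded but other rules give different
  absolute AICs (rankings are far less sensitive).
* The scenario geometries encode one defensible reading of hypotheses
  that are defined geographically rather than numerically; all ratios
  are configuration, and conclusions only hold under the declared
  geometry.
* Site rates are category means, not continuous gamma draws, and
  partitions evolve independently (no linkage between them).
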