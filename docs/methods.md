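# Methods

This note documents the models and procedures implemented in
`phenosignal`, the choices made where the design was genuinely open, and
what the synthetic-data validation does and does not demonstrate.

## Phenological trait extraction

Eleven traits are computed per (site, species) occurrence from flowering
censuses and hourly temperatures.

**Calendar traits** (days).  FF_DOY is the day of year of the first
census with at least one plant in flower; FF, PFP and PFA are days from
the site's snowmelt date to first flowering, to the census with the
maximum number of plants in flower, and to the census with the maximum
number of open flowers; FSL is the number of days between the first and
last flowering censuses (0 when a species flowered on a single census).
Peak ties break to the earliest census — conservative and reproducible.
FSL is defined observationally (last minus first flowering census), not
augmented by the census interval; with a 5-day census grid all calendar
traits are quantised to that grid, an irreducible observation error of up
to one interval.

**Thermal-sum traits** (degree days).  Growing degree days accumulate
from the snowmelt biofix (inclusive) through each milestone day
(inclusive), at base temperatures 0 and 5 °C.  Daily accumulation uses
the double-sine formulation: the day's temperature course is modelled as
a half-sine rising from the day's minimum to its maximum over half a
day, then a half-sine falling from the maximum to the *next* day's
minimum; the degree-day contribution is the area of that curve above the
base, with a horizontal cutoff below the base and no upper threshold.
Each half-day has a closed form: with m = (Th+Tl)/2, a = (Th−Tl)/2,

* base ≤ Tl:  (m − base)/2
* base ≥ Th:  0
* otherwise:  [(m − base)(π/2 − θ) + a·cos θ]/(2π),  θ = arcsin((base−m)/a)

verified against fine-grid numerical integration to < 1e-10 degree-days.
The final season day pairs with its own minimum (no next day exists).  A
falling half whose next-day minimum exceeds the current maximum is
clamped to an isothermal half-day.  Days are civil calendar days;
day-of-year is 1-based.

**Synchrony.**  Augspurger's index on the flowering presence/absence
matrix: X_i = (1/(n−1)) Σ_{j≠i} e_ij/f_i with e_ij the number of
censuses on which both species flowered and f_i the number on which i
flowered; the site value is the mean over species.  Censuses on which
nothing flowers do not affect the index; species that never flower are
excluded with a warning.

## Functional trait space and indices

The eleven traits are strongly collinear, so functional structure is
measured on principal components of the z-scored (ddof = 1) trait matrix.
The PCA is fitted once on the pooled occurrence matrix — all sites'
rows together, species present at several sites contributing one row per
occurrence with locally measured values.  Pooled fitting is required for
the null model to be coherent: randomised communities are drawn from the
pooled occurrence list and must live in the same coordinate system as
the observed ones.  Three components are retained by default (a
cumulative-variance rule is available).

Per community: FRic is the convex-hull volume of its points (area in
2-D); when a community has too few members to span the space (S ≤ k) the
hull is recomputed in the leading S−1 axes, the fallback used by the
standard functional-diversity toolchain.  FDis is the mean Euclidean
distance to the unweighted centroid (presence data).  RaoQ is the full
double sum Σ_ij d_ij p_i p_j with uniform p by default.

## Null models and effect sizes

All structure metrics are standardised against richness-preserving
uniform draws without replacement: occurrence rows from the pooled trait
space for functional indices, tip labels from the tree's species pool
for phylogenetic metrics.  SES = (observed − null mean)/null SD.  Two
p-value conventions coexist deliberately: functional indices use the
literal two-tailed proportion of null values deviating from the null
mean at least as much as the observation (no add-one correction), while
phylogenetic SES uses the add-one rank p, (1 + #{null ≤ obs})/(n+1), on
the clustering side — the convention of the R community-phylogenetics
toolchain this mirrors.  A degenerate null (SD = 0, e.g. a community
equal to the whole pool) yields SES = NaN and p = 1 with a warning
rather than an exception, so a whole-table pipeline survives one
degenerate site.

Default replicate counts: 9,999 for functional nulls, 999 for
phylogenetic nulls, 999 permutations for signal tests.  Every
randomised quantity records its seed; one named numpy Generator drives a
pipeline run, so a manifest (seed + parameters) reproduces every table
bit-identically.

## Blomberg's K and the permutation test

K is the ratio of the observed MSE₀/MSE to its Brownian expectation,
with MSE₀ the ordinary mean squared deviation from the phylogenetic GLS
mean â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1) and MSE the C⁻¹-weighted one; the
expectation is [tr C − n/(1ᵀC⁻¹1)]/(n−1).  Both MSEs carry denominator
n−1 (they cancel; kept explicit).  All solves go through a Cholesky
factorisation of C — C is never inverted explicitly, and factorisations
are shared across traits and permutations (the permutation test
evaluates all shuffles as columns of one triangular solve).

The permutation test statistic is the phylogenetic MSE itself, not K:
the two rank identically under tip shuffles (K's other ingredients are
permutation-invariant) and MSE is cheaper.  p = (1 + #{MSE_perm ≤
MSE_obs})/(n_perm + 1).  Verified against exhaustive enumeration on
small trees and calibrated (uniform p) under white noise.  K requires
n ≥ 3, non-constant traits, and a non-singular C (duplicate zero-length
tips are rejected).

When a community is a subset of a larger tree, restriction moves the
root to the subset's most recent common ancestor: the induced covariance
is the submatrix minus its smallest off-diagonal entry.  This avoids
repeated tree pruning in rarefaction loops and equals the covariance of
the pruned tree exactly.

## Trait-evolution models

All three models are Gaussian, x ~ N(μ1, σ²V(θ)):

* **BM**: V = C, the shared root-to-MRCA path lengths (2 parameters).
* **OU**: single-optimum, root at the optimum (non-stationary), the
  standard comparative-methods form for ultrametric trees:
  V_ij = (1/(2α)) e^{−2α(T−s_ij)} (1 − e^{−2α s_ij}), s_ij the shared
  time, T the height (3 parameters).  α → 0 recovers BM.
* **EB**: rates decay as e^{rt}, so each shared epoch contributes its
  integral: V_ij = (e^{r·s_ij} − 1)/r, r ≤ 0 (3 parameters); r = 0 is BM
  exactly.

μ (GLS mean) and σ² (ML, denominator n) are profiled analytically; the
single remaining parameter is optimised by bounded scalar search — α in
log space on [1e-8, 50/T], r on [−10/T, 0].  OU and EB require an
ultrametric tree (relative tolerance 1e-6, since sequence-derived trees
are never exactly ultrametric).  Model choice is by AIC = −2lnL + 2k
(k = 2, 3, 3; no small-sample correction), ties breaking toward fewer
parameters.  BM log-likelihoods match direct dense multivariate-normal
evaluation to 1e-8; on strong-effect simulations (αT ≈ 3, or r = −5/T,
n = 100) AIC recovers the generating model in a large majority of
replicates, and under BM the nested alternatives gain < 2 AIC on
average.

## Richness rarefaction and community merging

To separate weak signal from weak power, a community is subsampled
without replacement to each of a ladder of richness levels
(n_subsamples per level, default 999); K and its permutation p are
recomputed per subsample on the restricted covariance, and each level is
summarised by the median K and the proportion of subsamples with
p < 0.05 (the threshold is a reporting convention, configurable).  A
subsample with a constant trait has undefined signal and is recorded as
NaN, excluded from the proportion.  Under Brownian traits the proportion
significant falls monotonically with richness; under white noise it
stays at the nominal 5% at every level — so a community whose signal
disappears only below its observed richness has a power problem, not an
absence of signal.  Complementarily, two low-richness communities can be
merged: species union, shared species taking the arithmetic mean of each
trait.

## Synthetic data: what it emulates

The generator produces every input the pipeline consumes with known
ground truth: pure-birth ultrametric trees (forward Yule construction on
a seeded numpy Generator; one extra exponential interval after the last
split so no pendant edge is degenerate), BM/OU traits drawn through a
Cholesky factor of the model covariance, hourly temperatures (sine ramp
from winter to summer mean + diurnal sinusoid with 03:00/15:00 extremes
+ Gaussian noise; snowmelt = first day the trend crosses 2 °C), and
censuses sampled from triangular flowering-intensity windows — plants in
flower Binomial(10, intensity), mirroring a 10-individual marked cohort,
open flowers Poisson.

The two-belt scenario mirrors a four-site campaign: an 86-species pool;
subalpine communities of 36 and 33 species assembled uniformly, their
flowering onsets a linear map of a conserved BM trait (mean 45 d after
snowmelt, spread 18 d); high-alpine communities of 20 and 23 species
filtered to the central 35% of a labile OU trait (≈ 30 eligible
species), their onsets mapped from that same trait with a compressed
spread (mean 22 d, spread 8 d) — convergence on rapid post-snowmelt
flowering.  The labile trait uses αT = 0.6: sister-species correlations
stay near 0.85 while correlations across the deepest splits decay to
near zero, which is precisely the regime in which window filtering
co-selects close relatives (terminal clustering, negative MNTD SES)
without producing basal structure.  Flowering durations vary across
species (mean 30 d, SD 7 d, floor 10 d); onsets carry 2 d of
observation noise.

What passing the end-to-end test shows: the full stack — census
extraction through GDD integration, PCA, SES machinery, K, and MNTD —
recovers a known assembly contrast in ≥ 80% of 100 scenario replicates.
What it does not show: robustness to the features of real data the
generator omits — sensor gaps and drift, non-triangular and multimodal
flowering curves, interannual variation, detection failure of rare
species, quadrat-vs-count heterogeneity, and phylogenetic error (the
tree is treated as known).

## Numerical and interface conventions

Branch-length units are opaque (time or substitutions); all derived
quantities inherit them.  A root edge length is dropped with a warning —
it would add an uninterpretable constant to every covariance entry.
Zero-length branches and polytomies are allowed.  Species names are
matched exactly; dates are ISO-8601.  GDD₅-based traits are computed
throughout but reported in a supplementary table (they track the GDD₀
traits almost exactly).  Pipeline CSVs are written with %.10g floats so
reruns from the manifest are byte-identical.

## Known limitations

Measurement error and within-species variation are not modelled in K or
the evolutionary fits; only single-optimum root-at-optimum OU is
implemented (no stationary or multi-regime variants); functional
distances are plain Euclidean on PC scores (all traits numeric — no
Gower handling); the deepest rarefaction levels (< ~10 species) have
intrinsically unstable K estimates, visible as widening subsample
distributions.
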