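# phenosignal

Phylogenetic signal, functional structure, and community phylogenetics of
flowering phenology along elevation gradients.

Alpine plant communities face short, cold growing seasons.  Do the species
that flower together at high elevation do so because environmental
filtering admitted only lineages pre-adapted to cold (conserved traits,
phylogenetically clustered communities), or because unrelated lineages
converged on similar flowering schedules under shared selective pressure
(labile traits, weak phylogenetic signal)?  `phenosignal` implements the
full analytical stack needed to ask that question from field data — and a
synthetic-data generator with known ground truth to validate every stage.

The package is aimed at community ecologists and evolutionary biologists
working with flowering censuses, temperature loggers, and a community
phylogeny.

## What it computes

**Phenological traits** (per species per site, from censuses at ~5-day
intervals and hourly temperatures): day of year of first flowering
(FF_DOY), days from snowmelt to first flowering (FF), to peak number of
flowering plants (PFP), to peak floral abundance (PFA), flowering season
length (FSL), and growing degree days to each milestone at base
temperatures 0 and 5 °C (GDD₀FF … GDD₅PFA), accumulated from the snowmelt
biofix by the double-sine method with no upper threshold.  Community
flowering overlap is summarised by Augspurger's synchrony index
X_i = (1/(n−1)) Σ_{j≠i} e_ij / f_i.

**Phylogenetic signal** — Blomberg's K.  With C the Brownian-motion trait
covariance implied by the phylogeny and â the phylogenetic GLS mean,

    K = [ (x−â1)ᵀ(x−â1) / (x−â1)ᵀC⁻¹(x−â1) ] / [ (tr C − n/(1ᵀC⁻¹1)) / (n−1) ]

K = 1 under Brownian motion, K < 1 indicates convergence/lability, K > 1
conservatism.  Significance comes from a tip-shuffling permutation test on
the phylogenetic mean squared error.

**Trait-evolution models** — Brownian motion (BM), single-optimum
Ornstein–Uhlenbeck (OU, strength α), and early burst (EB, rate decay
r ≤ 0), fitted by maximum likelihood with μ and σ² profiled analytically,
compared by AIC (statsmodels-style: `TraitEvolutionModel(...).fit("OU")`
returns a results object with `.aic` and `.summary()`).

**Functional structure** — traits are z-scored, rotated by a pooled PCA
(3 components retained by default), and each community summarised by FRic
(convex-hull volume), FDis (mean distance to centroid) and RaoQ (Rao's
quadratic entropy), standardised against richness-preserving draws from
the pooled occurrence list: SES = (obs − null mean)/null SD.

**Phylogenetic structure** — MPD and MNTD on cophenetic distances with
tip-label randomisation SES (negative = clustering; MNTD is sensitive near
the tips, MPD tree-wide).

**Richness rarefaction** — communities are subsampled to decreasing
richness levels, K and its permutation p recomputed per subsample, tracing
how the power to detect signal decays with species number; two communities
can also be merged (shared species take mean traits) to offset low
richness.

## Worked example

Generate a synthetic elevation-gradient campaign (an 86-species pool; two
subalpine sites assembled at random whose flowering follows a conserved
Brownian trait; two high-alpine sites filtered on a labile OU trait),
extract traits, and test signal and structure per site:

```python
import numpy as np
from phenosignal import (two_belt_scenario, ScenarioConfig, build_trait_table,
                         phylogenetic_signal, phylo_ses)
from phenosignal.signal import pruned_vcv
from phenosignal.treeio import DistanceMatrix

sc = two_belt_scenario(ScenarioConfig(seed=1))
traits = build_trait_table(sc.censuses, sc.calendars, sc.temperatures)
V = sc.tree.vcv_matrix()
rng = np.random.default_rng(1)
for site, members in sc.communities.items():
    sp = [s for s in members if (site, s) in traits.index]
    vm = DistanceMatrix(sp, pruned_vcv(V.submatrix(sp).values), kind="covariance")
    sig = phylogenetic_signal(vm, traits.loc[site].loc[sp, "FF"], "FF",
                              n_perm=999, rng=rng)
    ses = phylo_ses(members, sc.tree, "mntd", n_reps=999, rng=rng)
    print(f"{site:14s} {len(sp):3d} {sig.k:7.3f} {sig.p_perm:7.3f} "
          f"{ses.ses:9.3f} {ses.p:7.3f}")
```

Output:

```
site             n   K(FF)       p  MNTD_SES       p
subalpine_I     36   1.319   0.001    -1.039   0.166
subalpine_II    33   1.076   0.001    -0.041   0.470
alpine_III      20   0.042   0.722    -1.962   0.022
alpine_IV       23   0.125   0.355    -1.387   0.087
```

Read: first flowering carries strong phylogenetic signal at both
random-assembly subalpine sites (K near 1, permutation p ≈ 0.001), while
at the trait-filtered high-alpine sites K collapses toward 0 and is not
significant — flowering there tracks a labile trait.  Both high-alpine
sites show negative MNTD SES (significantly so at site III): co-occurring
species are closer relatives than random draws from the pool, i.e.
terminal phylogenetic clustering alongside trait convergence.

The same workflow runs from the shell against CSV/newick/YAML inputs:

```sh
phenosignal simulate fixture/ --seed 1      # write a synthetic campaign
phenosignal run fixture/config.yaml         # traits, PCA, SES, K, AIC, rarefaction
```

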