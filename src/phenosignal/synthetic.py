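"""Synthetic data with known ground truth for every pipeline stage.

Generates the same objects the field campaign produces — an ultrametric
community phylogeny, per-species flowering traits with tunable
phylogenetic signal, hourly temperature series with a seasonal trend and
diurnal cycle, five-day-interval flowering censuses, and site
communities assembled under contrasting rules:

* ``random`` — uniform draw from the species pool (neutral assembly);
* ``clade_filter`` — draws biased toward one clade (environmental
  filtering on a conserved trait: phylogenetic clustering);
* ``trait_filter`` — species whose focal trait falls inside a window
  (filtering on a labile trait: trait convergence without basal
  clustering).

The flagship :func:`two_belt_scenario` emulates an elevation-gradient
study: two species-rich "subalpine" communities assembled at random
whose flowering times follow a conserved (Brownian) trait, and two
smaller "high alpine" communities filtered on a labile
(Ornstein-Uhlenbeck) trait whose flowering times follow that labile
trait — so phylogenetic signal in phenology is present in the lower belt
and erased, with functional convergence and terminal clustering, in the
upper one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .phenology import CensusSeries, SiteCalendar, TemperatureSeries
from .treeio import Phylogeny

__all__ = [
    "simulate_tree",
    "simulate_trait",
    "simulate_season",
    "simulate_census",
    "assemble_community",
    "SeasonConfig",
    "ScenarioConfig",
    "TwoBeltScenario",
    "two_belt_scenario",
]


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    rng: np.random.Generator | int | None = None,
    height: float | None = None,
) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree.

    Forward construction: with k extant lineages the next split arrives
    after Exp(k * birth_rate) and hits a uniformly chosen lineage; after
    the (n-1)th split one further Exp(n * birth_rate) interval is
    appended so pendant edges of the last split are not degenerate.
    ``height`` optionally rescales all branch lengths so the root-to-tip
    depth is exactly that value.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    gen = _rng(rng)
    # each record is one lineage: birth time and index of the parent record
    birth_times = [0.0, 0.0]  # the root's two children, born at the root
    parents = [-1, -1]
    extant = [0, 1]
    t = 0.0
    while len(extant) < n_tips:
        k = len(extant)
        t += float(gen.exponential(1.0 / (birth_rate * k)))
        split = extant[int(gen.integers(k))]
        for _ in range(2):
            birth_times.append(t)
            parents.append(split)
            extant.append(len(birth_times) - 1)
        extant.remove(split)
    present = t + float(gen.exponential(1.0 / (birth_rate * n_tips)))
    scale = 1.0 if height is None else height / present
    end_time = [present] * len(birth_times)
    for child, parent in enumerate(parents):
        if parent >= 0:
            end_time[parent] = birth_times[child]
    # assemble the dendropy tree; parents are always born no later than
    # their children, so birth-time order is a valid insertion order
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    nodes: dict[int, dendropy.Node] = {}
    for i in sorted(range(len(birth_times)), key=birth_times.__getitem__):
        node = dendropy.Node()
        nodes[i] = node
        parent_node = root if parents[i] == -1 else nodes[parents[i]]
        parent_node.add_child(node)
    extant_set = set(extant)
    tip_counter = 0
    for i, node in nodes.items():
        node.edge.length = (end_time[i] - birth_times[i]) * scale
        if i in extant_set:
            tip_counter += 1
            node.taxon = taxa.new_taxon(label=f"sp{tip_counter:03d}")
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------

def simulate_trait(
    tree: Phylogeny,
    model: str = "BM",
    sigma2: float = 1.0,
    mu: float = 0.0,
    alpha: float | None = None,
    rng: np.random.Generator | int | None = None,
    n_traits: int = 1,
) -> pd.Series | pd.DataFrame:
    """Draw tip values from N(mu 1, sigma^2 C(theta)).

    model="BM" uses the tree covariance; model="OU" (requires an
    ultrametric tree and ``alpha`` > 0) uses the single-optimum
    root-at-optimum covariance.  With sigma2 = 0 the trait is the
    constant mu.  Returns a Series (one trait) or a DataFrame with
    ``n_traits`` independent columns.
    """
    gen = _rng(rng)
    vcv = tree.vcv_matrix()
    S = vcv.values
    labels = vcv.labels
    n = len(labels)
    if model.upper() == "BM":
        V = S
    elif model.upper() == "OU":
        if alpha is None or alpha <= 0:
            raise ValueError("OU simulation requires alpha > 0")
        ultra, T = tree.is_ultrametric()
        if not ultra:
            raise ValueError("OU simulation requires an ultrametric tree")
        V = (1.0 / (2 * alpha)) * np.exp(-2 * alpha * (T - S)) * (-np.expm1(-2 * alpha * S))
    else:
        raise ValueError("model must be BM or OU")
    if sigma2 == 0:
        X = np.full((n, n_traits), mu)
    else:
        L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(n))
        X = mu + L @ gen.standard_normal((n, n_traits))
    if n_traits == 1:
        return pd.Series(X[:, 0], index=labels, name="trait")
    return pd.DataFrame(X, index=labels, columns=[f"trait{i+1}" for i in range(n_traits)])


# ---------------------------------------------------------------------------
# season / temperature simulation
# ---------------------------------------------------------------------------

@dataclass
class SeasonConfig:
    """Parameters of one site's synthetic thermal season.

    The daily-mean trend is a sine ramp from winter to summer; snowmelt
    is the first day the trend crosses ``melt_threshold_c``.  Defaults
    emulate a mid-latitude alpine season observed from early spring.
    """

    site_id: str = "site"
    start: date = date(2018, 9, 1)
    n_days: int = 240
    winter_mean_c: float = -4.0
    summer_mean_c: float = 14.0
    ramp_days: int = 120  # days from start over which the trend rises
    diurnal_amplitude_c: float = 6.0
    noise_sd_c: float = 1.0
    melt_threshold_c: float = 2.0

    def trend(self, day_index: np.ndarray) -> np.ndarray:
        frac = np.clip(day_index / self.ramp_days, 0.0, 1.0)
        return self.winter_mean_c + (self.summer_mean_c - self.winter_mean_c) * (
            0.5 - 0.5 * np.cos(np.pi * frac)
        )


def simulate_season(
    config: SeasonConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[TemperatureSeries, SiteCalendar]:
    """Hourly temperatures plus the site calendar they imply.

    temp(d, h) = trend(d) + A sin(2 pi (h - 9)/24) + N(0, noise_sd): the
    diurnal minimum falls at 03:00 and the maximum at 15:00.  Snowmelt is
    the first day whose trend reaches the melt threshold; the season ends
    on the last simulated day.
    """
    gen = _rng(rng)
    days = np.arange(config.n_days)
    trend = config.trend(days)
    hours = np.arange(24)
    diurnal = config.diurnal_amplitude_c * np.sin(2 * np.pi * (hours - 9) / 24.0)
    temp = trend[:, None] + diurnal[None, :]
    if config.noise_sd_c > 0:
        temp = temp + gen.normal(0.0, config.noise_sd_c, size=temp.shape)
    timestamps = [
        datetime.combine(config.start + timedelta(days=int(d)), datetime.min.time())
        + timedelta(hours=int(h))
        for d in days
        for h in hours
    ]
    series = TemperatureSeries(
        config.site_id,
        pd.DataFrame({"timestamp": timestamps, "temp_c": temp.ravel()}),
    )
    melt_idx = np.argmax(trend >= config.melt_threshold_c)
    if trend[melt_idx] < config.melt_threshold_c:
        raise ValueError("trend never reaches the melt threshold")
    calendar = SiteCalendar(
        config.site_id,
        config.start + timedelta(days=int(melt_idx)),
        config.start + timedelta(days=int(config.n_days - 1)),
    )
    return series, calendar


# ---------------------------------------------------------------------------
# census simulation
# ---------------------------------------------------------------------------

def simulate_census(
    flowering_windows: pd.DataFrame,
    calendar: SiteCalendar,
    interval_days: int = 5,
    n_plants: int = 10,
    flowers_per_plant: float = 8.0,
    rng: np.random.Generator | int | None = None,
) -> list[CensusSeries]:
    """Five-day-interval flowering censuses from ground-truth windows.

    ``flowering_windows`` is indexed by species with columns ``onset``,
    ``peak`` and ``end`` (days from snowmelt).  Flowering intensity is a
    triangular curve rising from onset to 1 at the peak and falling to 0
    at the end; on each census the number of plants in flower is
    Binomial(n_plants, intensity) — the marked cohort is finite — and
    open flowers are Poisson(n_plants * flowers_per_plant * intensity).
    A window that misses every census date yields a species with no
    flowering records (aliasing by the census grid).
    """
    gen = _rng(rng)
    census_offsets = np.arange(
        0, (calendar.season_end - calendar.snowmelt_date).days + 1, interval_days
    )
    census_dates = [calendar.snowmelt_date + timedelta(days=int(o)) for o in census_offsets]
    out = []
    for species, row in flowering_windows.iterrows():
        onset, peak, end = float(row["onset"]), float(row["peak"]), float(row["end"])
        if not onset <= peak <= end:
            raise ValueError(f"{species}: onset <= peak <= end violated")
        up = np.where(
            census_offsets <= peak,
            (census_offsets - onset) / max(peak - onset, 1e-9),
            (end - census_offsets) / max(end - peak, 1e-9),
        )
        intensity = np.clip(up, 0.0, 1.0)
        intensity[(census_offsets < onset) | (census_offsets > end)] = 0.0
        plants = gen.binomial(n_plants, intensity)
        flowers = gen.poisson(n_plants * flowers_per_plant * intensity)
        flowers = np.where(plants == 0, 0, np.maximum(flowers, plants))
        records = pd.DataFrame(
            {"date": census_dates, "n_plants": plants, "n_flowers": flowers}
        )
        out.append(CensusSeries(calendar.site_id, str(species), records))
    return out


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def assemble_community(
    tree: Phylogeny,
    size: int,
    scheme: str = "random",
    rng: np.random.Generator | int | None = None,
    strength: float = 1.0,
    trait: pd.Series | None = None,
    window: tuple[float, float] | None = None,
    top_up: bool = True,
) -> list[str]:
    """Draw a species set from the tree's pool under an assembly rule.

    random
        uniform draw without replacement.
    clade_filter
        draws weighted toward the larger root clade: members get weight
        1 + strength, outsiders weight 1; strength 0 reduces to random,
        large strength confines the community to the clade.
    trait_filter
        keep species whose ``trait`` value lies inside ``window``; if
        fewer than ``size`` qualify the community is topped up at random
        (or an error raised when ``top_up`` is false).
    """
    gen = _rng(rng)
    pool = tree.tip_labels
    if size > len(pool):
        raise ValueError(f"community size {size} exceeds pool of {len(pool)}")
    if scheme == "random":
        return list(gen.choice(pool, size=size, replace=False))
    if scheme == "clade_filter":
        if strength < 0:
            raise ValueError("strength must be >= 0")
        clade = _largest_root_clade(tree)
        weights = np.array([1.0 + strength if s in clade else 1.0 for s in pool])
        weights /= weights.sum()
        return list(gen.choice(pool, size=size, replace=False, p=weights))
    if scheme == "trait_filter":
        if trait is None or window is None:
            raise ValueError("trait_filter needs a trait and a window")
        lo, hi = window
        inside = [s for s in pool if lo <= trait[s] <= hi]
        if len(inside) >= size:
            return list(gen.choice(inside, size=size, replace=False))
        if not top_up:
            raise ValueError(
                f"window selects only {len(inside)} species (< {size}) "
                "and top-up is disabled"
            )
        outside = [s for s in pool if s not in set(inside)]
        extra = gen.choice(outside, size=size - len(inside), replace=False)
        return inside + list(extra)
    raise ValueError(f"unknown assembly scheme {scheme!r}")


def _largest_root_clade(tree: Phylogeny) -> set[str]:
    root_children = tree._tree.seed_node.child_nodes()
    clades = [
        {leaf.taxon.label for leaf in child.leaf_iter()} for child in root_children
    ]
    return max(clades, key=len)


# ---------------------------------------------------------------------------
# the two-belt elevation scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Study conditions of the synthetic elevation-gradient scenario.

    Defaults mirror the structure of a four-site campaign: an 86-species
    pool, two species-rich subalpine sites (36 and 33 species, random
    assembly, snowmelt in early spring) and two smaller high alpine
    sites (20 and 23 species, trait-filtered, snowmelt two months
    later).  Flowering in the subalpine belt follows a conserved
    Brownian trait; in the high alpine belt it follows a labile OU trait
    (alpha * T = 0.6: correlations between the deepest splits decay to
    near zero while sister species stay strongly correlated) on which
    the communities are also filtered — convergence
    with terminal, but not basal, clustering.  The filter window keeps
    the central 35% of the pool (about 30 eligible species), so the two
    filtered communities overlap heavily, as real high-alpine
    communities drawn from the same cold-adapted flora do.
    """

    pool_size: int = 86
    birth_rate: float = 1.0
    tree_height: float = 1.0
    subalpine_sizes: tuple[int, int] = (36, 33)
    alpine_sizes: tuple[int, int] = (20, 23)
    ou_alpha_times_height: float = 0.6
    trait_sigma2: float = 1.0
    filter_quantile: float = 0.175  # half-width of the labile-trait window
    census_interval_days: int = 5
    # flowering-time maps (days from snowmelt): mean + spread * z-score
    subalpine_onset_mean: float = 45.0
    subalpine_onset_spread: float = 18.0
    alpine_onset_mean: float = 22.0
    alpine_onset_spread: float = 8.0
    flowering_duration_days: float = 30.0
    duration_sd_days: float = 7.0
    onset_noise_sd_days: float = 2.0
    seed: int = 0


@dataclass
class TwoBeltScenario:
    """Everything a pipeline run consumes, with its ground truth."""

    tree: Phylogeny
    conserved_trait: pd.Series
    labile_trait: pd.Series
    communities: dict[str, list[str]]
    calendars: dict[str, SiteCalendar]
    temperatures: dict[str, TemperatureSeries]
    censuses: list[CensusSeries]
    flowering_windows: dict[str, pd.DataFrame]
    config: ScenarioConfig

    @property
    def site_ids(self) -> list[str]:
        return list(self.communities)

    def community_frame(self) -> pd.DataFrame:
        # only species occurring somewhere: the null-model pool is the tree
        present = sorted(
            {s for members in self.communities.values() for s in members},
            key=self.tree.tip_labels.index,
        )
        data = {
            site: [1 if s in set(members) else 0 for s in present]
            for site, members in self.communities.items()
        }
        return pd.DataFrame(data, index=present).T

    def write(self, outdir) -> None:
        """Emit the fixture files the pipeline's file interface reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tree.write(outdir / "tree.nwk")
        self.community_frame().to_csv(outdir / "communities.csv")
        rows = []
        for cs in self.censuses:
            for _, rec in cs.records.iterrows():
                rows.append(
                    {
                        "site": cs.site_id,
                        "species": cs.species_id,
                        "date": rec["date"].isoformat(),
                        "n_plants": int(rec["n_plants"]),
                        "n_flowers": int(rec["n_flowers"]),
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "census.csv", index=False)
        for site, series in self.temperatures.items():
            df = series.samples.copy()
            df["timestamp"] = df["timestamp"].map(lambda t: t.isoformat())
            df.to_csv(outdir / f"temperature_{site}.csv", index=False)
        cal = {
            site: {
                "snowmelt": c.snowmelt_date.isoformat(),
                "season_end": c.season_end.isoformat(),
            }
            for site, c in self.calendars.items()
        }
        with open(outdir / "calendar.yaml", "w") as fh:
            yaml.safe_dump(cal, fh)


def _standardize(x: pd.Series) -> pd.Series:
    return (x - x.mean()) / x.std(ddof=1)


def two_belt_scenario(config: ScenarioConfig | None = None, seed: int | None = None) -> TwoBeltScenario:
    """Generate a full synthetic elevation-gradient campaign."""
    cfg = config or ScenarioConfig()
    if seed is not None:
        cfg = ScenarioConfig(**{**cfg.__dict__, "seed": seed})
    gen = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.pool_size, cfg.birth_rate, gen, height=cfg.tree_height)
    alpha = cfg.ou_alpha_times_height / cfg.tree_height
    conserved = simulate_trait(tree, "BM", cfg.trait_sigma2, rng=gen).rename("conserved")
    labile = simulate_trait(tree, "OU", cfg.trait_sigma2, alpha=alpha, rng=gen).rename("labile")

    lo, hi = labile.quantile(0.5 - cfg.filter_quantile), labile.quantile(0.5 + cfg.filter_quantile)
    communities = {
        "subalpine_I": assemble_community(tree, cfg.subalpine_sizes[0], "random", gen),
        "subalpine_II": assemble_community(tree, cfg.subalpine_sizes[1], "random", gen),
        "alpine_III": assemble_community(
            tree, cfg.alpine_sizes[0], "trait_filter", gen, trait=labile, window=(lo, hi)
        ),
        "alpine_IV": assemble_community(
            tree, cfg.alpine_sizes[1], "trait_filter", gen, trait=labile, window=(lo, hi)
        ),
    }

    season_cfgs = {
        "subalpine_I": SeasonConfig("subalpine_I", date(2018, 9, 1), 260,
                                    -2.0, 16.0, 100, 6.0, 1.0, 2.0),
        "subalpine_II": SeasonConfig("subalpine_II", date(2018, 9, 1), 260,
                                     -2.5, 15.5, 105, 6.0, 1.0, 2.0),
        "alpine_III": SeasonConfig("alpine_III", date(2018, 9, 1), 260,
                                   -6.0, 11.0, 160, 6.0, 1.0, 2.0),
        "alpine_IV": SeasonConfig("alpine_IV", date(2018, 9, 1), 260,
                                  -6.5, 10.5, 165, 6.0, 1.0, 2.0),
    }
    temperatures, calendars = {}, {}
    for site, scfg in season_cfgs.items():
        series, cal = simulate_season(scfg, gen)
        temperatures[site] = series
        calendars[site] = cal

    z_cons, z_lab = _standardize(conserved), _standardize(labile)
    censuses: list[CensusSeries] = []
    windows: dict[str, pd.DataFrame] = {}
    for site, members in communities.items():
        alpine = site.startswith("alpine")
        z = z_lab if alpine else z_cons
        mean = cfg.alpine_onset_mean if alpine else cfg.subalpine_onset_mean
        spread = cfg.alpine_onset_spread if alpine else cfg.subalpine_onset_spread
        onset = (
            mean
            + spread * z.loc[members]
            + gen.normal(0.0, cfg.onset_noise_sd_days, size=len(members))
        ).clip(lower=1.0)
        duration = np.clip(
            gen.normal(cfg.flowering_duration_days, cfg.duration_sd_days,
                       size=len(members)),
            10.0,
            None,
        )
        season_len = (calendars[site].season_end - calendars[site].snowmelt_date).days
        onset = onset.clip(upper=season_len - duration - 1)
        wf = pd.DataFrame(
            {
                "onset": onset,
                "peak": onset + duration / 2,
                "end": onset + duration,
            }
        )
        windows[site] = wf
        censuses.extend(
            simulate_census(wf, calendars[site], cfg.census_interval_days, rng=gen)
        )
    return TwoBeltScenario(
        tree=tree,
        conserved_trait=conserved,
        labile_trait=labile,
        communities=communities,
        calendars=calendars,
        temperatures=temperatures,
        censuses=censuses,
        flowering_windows=windows,
        config=cfg,
    )
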