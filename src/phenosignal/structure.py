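"""Phylogenetic community structure: MPD, MNTD, and their effect sizes.

Two complementary distance summaries over the species co-occurring at a
site, both computed on the cophenetic (path-length) distance matrix:

* **MPD** — mean pairwise distance over all unordered species pairs;
  sensitive to tree-wide (basal) clustering or evenness;
* **MNTD** — mean, over species, of the distance to the nearest other
  community member; sensitive to structure near the tips.

Standardised effect sizes compare each against richness-preserving
uniform draws of tip labels from the tree's species pool (the
"taxa.labels" null of the R community-phylogenetics toolchain), with the
add-one rank p on the low side: negative SES and small p indicate
phylogenetic clustering, the signature of environmental filtering on
conserved traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nulls import SESResult, rank_p, _summarise
from .treeio import DistanceMatrix, Phylogeny

__all__ = ["CommunityMatrix", "mpd", "mntd", "phylo_ses"]


@dataclass
class CommunityMatrix:
    """Binary site x species presence table."""

    presence: pd.DataFrame  # sites as rows, species as columns, 0/1

    def __post_init__(self) -> None:
        P = self.presence.astype(int)
        if not P.isin([0, 1]).all().all():
            raise ValueError("presence matrix must be binary")
        absent = P.columns[P.sum(axis=0) == 0].tolist()
        if absent:
            raise ValueError(f"species present in no site: {absent}")
        self.presence = P

    @classmethod
    def from_csv(cls, path) -> "CommunityMatrix":
        return cls(pd.read_csv(path, index_col=0))

    @property
    def sites(self) -> list[str]:
        return list(self.presence.index)

    def species_at(self, site: str) -> list[str]:
        row = self.presence.loc[site]
        return list(row.index[row > 0])


def _community_block(community_species, dist: DistanceMatrix) -> np.ndarray:
    species = list(community_species)
    if len(species) < 2:
        raise ValueError("community metrics need at least 2 species")
    return dist.submatrix(species).values


def mpd(community_species, dist: DistanceMatrix) -> float:
    """Mean pairwise phylogenetic distance (unweighted: presence data)."""
    d = _community_block(community_species, dist)
    n = len(d)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def mntd(community_species, dist: DistanceMatrix) -> float:
    """Mean nearest-taxon distance: average over members of the distance
    to the closest other member."""
    d = _community_block(community_species, dist).copy()
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def phylo_ses(
    community_species,
    tree: Phylogeny,
    metric: str = "mpd",
    n_reps: int = 999,
    rng: np.random.Generator | int | None = None,
    pool: list[str] | None = None,
    dist: DistanceMatrix | None = None,
) -> SESResult:
    """Standardised effect size of MPD or MNTD against a tip-label null.

    The null keeps richness fixed and draws species uniformly without
    replacement from ``pool`` (default: every tip of the tree).  Rank p
    is one-sided low (clustering).  A community equal to the whole pool
    has a degenerate null and is reported with SES = NaN.
    """
    fn = {"mpd": mpd, "mntd": mntd}.get(metric.lower())
    if fn is None:
        raise ValueError("metric must be 'mpd' or 'mntd'")
    species = list(community_species)
    if pool is None:
        pool = tree.tip_labels
    if len(species) > len(pool):
        raise ValueError("community richness exceeds pool size")
    if dist is None:
        dist = tree.cophenetic_matrix()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    # index-based draws against a prebuilt pool block keep the null cheap
    pool_block = dist.submatrix(pool).values
    size = len(species)
    observed = fn(species, dist)
    nulls = np.empty(n_reps)
    n_pool = len(pool)
    iu = np.triu_indices(size, k=1)
    for r in range(n_reps):
        idx = gen.choice(n_pool, size=size, replace=False)
        block = pool_block[np.ix_(idx, idx)]
        if metric.lower() == "mpd":
            nulls[r] = block[iu].mean()
        else:
            b = block.copy()
            np.fill_diagonal(b, np.inf)
            nulls[r] = b.min(axis=1).mean()
    return _summarise(observed, nulls, seed, p_kind="rank", side="low")
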