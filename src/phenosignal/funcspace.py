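"""Functional trait space (PCA) and functional-structure indices.

The eleven flowering traits are strongly collinear (thermal sums track
calendar dates), so functional structure is measured in a reduced
orthogonal space: traits are z-scored and rotated by a principal
component analysis fitted ONCE on the pooled occurrence matrix (all
sites' rows together).  Pooled fitting is what makes the cross-site null
model coherent — null communities drawn from the pooled species list
must live in the same coordinate system as the observed ones.  Species
occurring at several sites keep one row per (site, species) occurrence
with their locally measured trait values.

Three indices summarise a community's occupancy of that space:

* **FRic** — functional richness, the volume of the convex hull spanned
  by the community (area in 2-D, length in 1-D);
* **FDis** — functional dispersion, the mean Euclidean distance of
  community members to their centroid (unweighted: presence data);
* **RaoQ** — Rao's quadratic entropy, sum_ij d_ij p_i p_j over the full
  ordered double sum (uniform p by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA

__all__ = ["TraitSpace", "FunctionalIndices", "build_trait_space", "fric", "fdis", "raoq", "functional_indices"]


@dataclass
class TraitSpace:
    """PC scores of pooled (site, species) occurrences."""

    occurrence_ids: pd.MultiIndex
    coordinates: np.ndarray  # rows x retained PCs
    explained_variance_fraction: np.ndarray

    def rows(self, ids) -> np.ndarray:
        """Coordinate block for a list of (site, species) keys."""
        lookup = {key: i for i, key in enumerate(self.occurrence_ids)}
        missing = [k for k in ids if k not in lookup]
        if missing:
            raise KeyError(f"occurrences not in trait space: {missing}")
        return self.coordinates[[lookup[k] for k in ids]]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.occurrence_ids, columns=cols)


@dataclass
class FunctionalIndices:
    fric: float
    fdis: float
    raoq: float


def build_trait_space(
    traits: pd.DataFrame,
    n_components: int | str = 3,
    variance_threshold: float | None = None,
) -> TraitSpace:
    """Z-score the pooled trait table and rotate it by PCA.

    ``n_components`` caps retention at min(n_components, rank); pass
    ``"auto"`` with a ``variance_threshold`` to instead keep the smallest
    k whose cumulative explained variance reaches the threshold.
    Zero-variance traits are dropped with a warning (they carry no
    functional information and break z-scoring); rows with missing values
    are dropped with a warning.
    """
    X = traits.copy()
    n_missing = int(X.isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(f"dropping {n_missing} occurrence rows with missing traits")
        X = X.dropna()
    if len(X) < 2:
        raise ValueError("need at least 2 complete occurrence rows for a trait space")
    sd = X.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance traits: {dead}")
        X = X.drop(columns=dead)
        sd = sd.drop(dead)
    Z = (X - X.mean()) / sd
    rank = min(Z.shape)
    if n_components == "auto":
        if variance_threshold is None:
            raise ValueError("n_components='auto' requires variance_threshold")
        k = rank
    else:
        k = min(int(n_components), rank)
    pca = PCA(n_components=rank, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    frac = pca.explained_variance_ratio_
    if n_components == "auto":
        k = int(np.searchsorted(np.cumsum(frac), variance_threshold) + 1)
        k = min(k, rank)
    return TraitSpace(
        occurrence_ids=pd.MultiIndex.from_tuples(X.index, names=X.index.names)
        if not isinstance(X.index, pd.MultiIndex)
        else X.index,
        coordinates=scores[:, :k],
        explained_variance_fraction=frac[:k],
    )


def fric(points: np.ndarray) -> float:
    """Convex-hull volume of a community in trait space.

    If the community has too few members to span the full space
    (S <= k), the hull is recomputed in the leading S-1 coordinates —
    the dimensionality fallback used by the standard functional-diversity
    toolchain — before declaring the set degenerate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array")
    S, k = pts.shape
    if S <= k:
        if S < 2:
            raise ValueError("FRic needs at least 2 points")
        warnings.warn(
            f"community of {S} members in {k}-D space: hull computed in the "
            f"first {S - 1} axes"
        )
        pts = pts[:, : S - 1]
        k = S - 1
    if k == 1:
        return float(pts.max() - pts.min())
    try:
        return float(ConvexHull(pts).volume)
    except QhullError as exc:
        raise ValueError(f"degenerate point set (coplanar/collinear): {exc}") from exc


def fdis(points: np.ndarray) -> float:
    """Mean Euclidean distance of points to their (unweighted) centroid."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("FDis needs at least 2 points")
    centroid = pts.mean(axis=0)
    return float(np.linalg.norm(pts - centroid, axis=1).mean())


def raoq(points: np.ndarray, abundances: np.ndarray | None = None) -> float:
    """Rao's quadratic entropy: sum_ij d_ij p_i p_j (ordered double sum)."""
    pts = np.asarray(points, dtype=float)
    S = len(pts)
    if S == 0:
        raise ValueError("RaoQ needs at least 1 point")
    if abundances is None:
        p = np.full(S, 1.0 / S)
    else:
        p = np.asarray(abundances, dtype=float)
        if (p < 0).any():
            raise ValueError("abundances must be nonnegative")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("abundances must sum to 1")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return float(p @ d @ p)


def functional_indices(points: np.ndarray) -> FunctionalIndices:
    """All three indices for one community's coordinate block."""
    return FunctionalIndices(fric=fric(points), fdis=fdis(points), raoq=raoq(points))
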