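"""Randomisation nulls, standardised effect sizes, and empirical p-values.

Both the functional-structure and the phylogenetic-structure analyses
compare an observed community statistic against richness-preserving
random draws from a pooled species (or occurrence) list.  This module
owns the two p-value conventions used downstream:

* the **two-tailed proportion** p used for functional indices — the
  fraction of null values deviating from the null mean by at least as
  much as the observation (no add-one correction);
* the **rank** p used for phylogenetic structure — the add-one-corrected
  quantile (1 + #{null <= obs}) / (n_null + 1) for the clustering
  (side="low") tail, mirrored for side="high"; this is the convention of
  the R community-phylogenetics toolchain.

SES is always (observed - null mean) / null SD.  A degenerate null
distribution (SD = 0) makes SES undefined: it is reported as NaN with
p = 1 and a warning rather than raising, so that whole-table pipelines
survive a single degenerate community.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["SESResult", "pool_draw_null", "rank_p", "two_tailed_p"]


@dataclass
class SESResult:
    """Observed statistic vs a randomisation null."""

    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when null_sd == 0
    p: float
    n_null: int
    seed: int | None = None
    p_kind: str = "two_tailed"

    def to_dict(self) -> dict:
        return {
            "Obs": self.observed,
            "SES": self.ses,
            "p": self.p,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_null": self.n_null,
        }


def two_tailed_p(observed: float, null_values: np.ndarray) -> float:
    """Proportion of null values at least as far from the null mean as
    the observation (two-tailed, uncorrected)."""
    nulls = np.asarray(null_values, dtype=float)
    dev = abs(observed - nulls.mean())
    return float(np.mean(np.abs(nulls - nulls.mean()) >= dev))


def rank_p(observed: float, null_values: np.ndarray, side: str = "low") -> float:
    """Add-one-corrected rank p-value of the observation in the null set.

    side="low" tests for unusually small values (e.g. clustering);
    side="high" for unusually large ones.
    """
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size < 1:
        raise ValueError("need at least one null value")
    if side == "low":
        count = int(np.sum(nulls <= observed))
    elif side == "high":
        count = int(np.sum(nulls >= observed))
    else:
        raise ValueError("side must be 'low' or 'high'")
    return (1 + count) / (nulls.size + 1)


def _summarise(
    observed: float,
    nulls: np.ndarray,
    seed: int | None,
    p_kind: str,
    side: str = "low",
) -> SESResult:
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if nulls.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn("degenerate null distribution (sd = 0): SES undefined")
        ses = float("nan")
        p = 1.0
    else:
        ses = (observed - mean) / sd
        p = (
            two_tailed_p(observed, nulls)
            if p_kind == "two_tailed"
            else rank_p(observed, nulls, side=side)
        )
    return SESResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        ses=ses,
        p=p,
        n_null=int(nulls.size),
        seed=seed,
        p_kind=p_kind,
    )


def pool_draw_null(
    statistic: Callable[[Sequence], float],
    observed_members: Sequence,
    pool: Sequence,
    n_reps: int,
    rng: np.random.Generator | int | None = None,
    p_kind: str = "two_tailed",
    side: str = "low",
) -> SESResult:
    """Richness-preserving pool-draw null for an arbitrary statistic.

    Draws ``n_reps`` uniform subsets of size ``len(observed_members)``
    without replacement from ``pool``, evaluates ``statistic`` on each,
    and standardises the observed value against that distribution.
    """
    members = list(observed_members)
    pool = list(pool)
    size = len(members)
    if size > len(pool):
        raise ValueError(f"community size {size} exceeds pool size {len(pool)}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    observed = float(statistic(members))
    nulls = np.empty(n_reps)
    pool_arr = np.array(pool, dtype=object)
    for r in range(n_reps):
        draw = gen.choice(pool_arr, size=size, replace=False)
        nulls[r] = statistic(list(draw))
    return _summarise(observed, nulls, seed, p_kind, side)
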