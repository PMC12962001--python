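"""Phylogenetic signal and trait-evolution model fitting.

**Blomberg's K** measures how strongly trait similarity tracks phylogeny
relative to the Brownian-motion (BM) expectation.  With C the BM trait
covariance implied by the tree (shared root-to-MRCA path lengths),
phylogenetic GLS mean a = (1'C^-1 x)/(1'C^-1 1), and residuals r = x - a1:

    observed ratio   MSE0 / MSE = (r'r) / (r' C^-1 r)
    expected ratio   [tr(C) - n / (1'C^-1 1)] / (n - 1)
    K = observed / expected

K = 1 under BM; K < 1 means relatives resemble each other less than BM
predicts (lability/convergence); K > 1 means more (conservatism).  The
permutation test shuffles trait values across tips and ranks the observed
phylogenetic mean squared error (low MSE = signal) among the permuted
ones, with the add-one correction.

**Trait-evolution models.**  Three Gaussian models are fitted by maximum
likelihood, all of the form x ~ N(mu 1, sigma^2 V(theta)):

* BM:  V = C (2 free parameters: mu, sigma^2);
* OU:  single-optimum Ornstein-Uhlenbeck with the root at the optimum,
  V_ij = (1/(2 alpha)) e^{-2 alpha (T - s_ij)} (1 - e^{-2 alpha s_ij}),
  s_ij the shared root-to-MRCA time, T the tree height (3 parameters);
* EB:  early burst, rates decaying as e^{r t}; each shared-history epoch
  contributes its time-integral, so V_ij = (e^{r s_ij} - 1)/r (3
  parameters, r <= 0).

mu and sigma^2 are profiled analytically (GLS mean; ML variance with
denominator n); alpha is searched in log space, r on [-10/T, 0].  OU and
EB require an ultrametric tree.  Models are compared by AIC
(-2 lnL + 2k); ties break toward the simpler model (BM).

The module also implements the richness-rarefaction assessment — how the
detectability of phylogenetic signal decays as community richness is
subsampled down — and the merging of two communities' trait tables
(shared species get mean trait values) used to counteract low richness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar

from .treeio import DistanceMatrix, Phylogeny

__all__ = [
    "SignalResult",
    "TraitEvolutionModel",
    "TraitEvolutionFit",
    "RarefactionCurve",
    "blomberg_k",
    "signal_permutation_p",
    "phylogenetic_signal",
    "fit_model",
    "select_model",
    "rarefy_signal",
    "merge_communities",
]

_N_PARAMS = {"BM": 2, "OU": 3, "EB": 3}
_MODEL_ORDER = {"BM": 0, "OU": 1, "EB": 2}  # tie-break: fewer params first


# ---------------------------------------------------------------------------
# covariance plumbing
# ---------------------------------------------------------------------------

def _align(tree_or_vcv, trait) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Common entry: returns (C, x, labels) aligned to each other."""
    if isinstance(tree_or_vcv, Phylogeny):
        vcv = tree_or_vcv.vcv_matrix()
    elif isinstance(tree_or_vcv, DistanceMatrix):
        vcv = tree_or_vcv
    else:
        raise TypeError("expected a Phylogeny or a covariance DistanceMatrix")
    trait = pd.Series(trait, dtype=float)
    missing = [s for s in vcv.labels if s not in trait.index]
    if missing:
        raise ValueError(f"trait missing for tips: {missing}")
    labels = list(vcv.labels)
    x = trait.loc[labels].to_numpy()
    return vcv.values.copy(), x, labels


def pruned_vcv(C_sub: np.ndarray) -> np.ndarray:
    """Covariance of the induced subtree from a submatrix of the full one.

    Restricting a tree to a tip subset moves the root to the subset's
    MRCA, whose depth equals the smallest off-diagonal entry of the
    submatrix; that constant is shared by every pair and is subtracted
    throughout.
    """
    C = np.asarray(C_sub, dtype=float)
    n = len(C)
    if n < 2:
        return C.copy()
    off = C[~np.eye(n, dtype=bool)]
    return C - off.min()


def _gls_core(C: np.ndarray, X: np.ndarray):
    """Batched GLS pieces for trait columns X (n x m) under covariance C.

    Returns (ahat, q, q0, logdet, sum_inv) with q the GLS quadratic form
    (x-a1)'C^-1(x-a1), q0 the ordinary sum of squares (x-a1)'(x-a1).
    """
    n = len(C)
    L = np.linalg.cholesky(C)
    u = solve_triangular(L, np.ones(n), lower=True)
    V = solve_triangular(L, X, lower=True)
    sum_inv = float(u @ u)  # 1'C^-1 1
    ahat = (u @ V) / sum_inv
    q = np.einsum("ij,ij->j", V, V) - sum_inv * ahat**2
    R = X - ahat[None, :]
    q0 = np.einsum("ij,ij->j", R, R)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return ahat, q, q0, logdet, sum_inv


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    """Blomberg's K with its permutation p-value."""

    trait_name: str
    k: float
    p_perm: float
    n_species: int
    n_perm: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "trait": self.trait_name,
            "K": self.k,
            "p": self.p_perm,
            "n_species": self.n_species,
            "n_perm": self.n_perm,
        }


def blomberg_k_many(C: np.ndarray, X: np.ndarray) -> np.ndarray:
    """K for each trait column of X under tree covariance C."""
    n = len(C)
    if n < 3:
        raise ValueError("Blomberg's K needs at least 3 species")
    _, q, q0, _, sum_inv = _gls_core(C, X)
    if np.any(q0 == 0):
        raise ValueError("constant trait: phylogenetic signal undefined")
    observed = q0 / q
    expected = (np.trace(C) - n / sum_inv) / (n - 1)
    return observed / expected


def blomberg_k(tree_or_vcv, trait) -> float:
    """Blomberg's K for a single trait on a tree (or its covariance)."""
    C, x, _ = _align(tree_or_vcv, trait)
    return float(blomberg_k_many(C, x[:, None])[0])


def signal_permutation_p(
    tree_or_vcv,
    trait,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation p-value for phylogenetic signal.

    Test statistic is the phylogenetic mean squared error
    (x-a1)'C^-1(x-a1)/(n-1): low values mean the tree explains the trait
    well.  p = (1 + #{MSE_perm <= MSE_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    C, x, _ = _align(tree_or_vcv, trait)
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return _permutation_p_core(C, x, n_perm, gen)


def _permutation_p_core(
    C: np.ndarray, x: np.ndarray, n_perm: int, gen: np.random.Generator
) -> float:
    n = len(C)
    perms = np.empty((n, n_perm))
    for r in range(n_perm):
        perms[:, r] = gen.permutation(x)
    X = np.column_stack([x, perms])
    _, q, _, _, _ = _gls_core(C, X)
    mse_obs, mse_perm = q[0], q[1:]
    return float((1 + np.sum(mse_perm <= mse_obs)) / (n_perm + 1))


def phylogenetic_signal(
    tree_or_vcv,
    trait,
    trait_name: str = "trait",
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> SignalResult:
    """K and its permutation p in one shot (shared covariance work)."""
    C, x, labels = _align(tree_or_vcv, trait)
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = float(blomberg_k_many(C, x[:, None])[0])
    p = _permutation_p_core(C, x, n_perm, gen)
    return SignalResult(trait_name, k, p, len(labels), n_perm, seed)


# ---------------------------------------------------------------------------
# trait-evolution models (statsmodels-style Model / Results pair)
# ---------------------------------------------------------------------------

class TraitEvolutionModel:
    """Gaussian trait-evolution model on a phylogeny.

    Parameters
    ----------
    trait : mapping or Series, species -> value
    tree : Phylogeny
        OU and EB fits require it to be ultrametric (within tolerance).

    Examples
    --------
    >>> fit = TraitEvolutionModel(trait, tree).fit("OU")
    >>> fit.aic
    >>> print(fit.summary())
    """

    def __init__(self, trait, tree: Phylogeny):
        self.tree = tree
        C, x, labels = _align(tree, trait)
        self.labels = labels
        self.C = C
        self.x = x
        self.n = len(x)
        if self.n < 2:
            raise ValueError("model fitting needs at least 2 species")
        ultra, T = tree.is_ultrametric()
        self.is_ultrametric = ultra
        self.height = T

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, trait: str, tree: Phylogeny, species: str | None = None
    ) -> "TraitEvolutionModel":
        """Build from a tidy table; ``species`` defaults to the index."""
        s = data.set_index(species)[trait] if species else data[trait]
        return cls(s, tree)

    # -- model covariances -------------------------------------------

    def _shape_matrix(self, model: str, theta: float | None) -> np.ndarray:
        S, T = self.C, self.height
        if model == "BM":
            return S
        if model == "OU":
            a = theta
            return (1.0 / (2 * a)) * np.exp(-2 * a * (T - S)) * (-np.expm1(-2 * a * S))
        if model == "EB":
            r = theta
            if r == 0.0:
                return S
            return np.expm1(r * S) / r
        raise ValueError(f"unknown model {model!r}")

    def _profiled_loglik(self, V: np.ndarray) -> tuple[float, float, float]:
        """Profile mu and sigma^2 out of N(mu 1, sigma^2 V); returns
        (lnL, mu_hat, sigma2_hat)."""
        ahat, q, _, logdet, _ = _gls_core(V, self.x[:, None])
        sigma2 = float(q[0]) / self.n
        if sigma2 <= 0:
            return -np.inf, float(ahat[0]), 0.0
        lnL = -0.5 * (self.n * math.log(2 * math.pi * sigma2) + self.n + logdet)
        return lnL, float(ahat[0]), sigma2

    # -- fitting ------------------------------------------------------

    def fit(self, model: str = "BM") -> "TraitEvolutionFit":
        model = model.upper()
        if model not in _N_PARAMS:
            raise ValueError("model must be one of BM, OU, EB")
        if model in ("OU", "EB") and not self.is_ultrametric:
            raise ValueError(f"{model} requires an ultrametric tree")
        if model == "BM":
            lnL, mu, s2 = self._profiled_loglik(self.C)
            return self._result(model, {"sigma2": s2, "mu": mu}, lnL, True)
        T = self.height
        if model == "OU":
            lo, hi = math.log(1e-8), math.log(50.0 / T)

            def neg(loga: float) -> float:
                return -self._profiled_loglik(self._shape_matrix("OU", math.exp(loga)))[0]

            res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10})
            alpha = math.exp(res.x)
            lnL, mu, s2 = self._profiled_loglik(self._shape_matrix("OU", alpha))
            return self._result(
                model, {"sigma2": s2, "mu": mu, "alpha": alpha}, lnL, bool(res.success)
            )
        # EB
        lo, hi = -10.0 / T, 0.0

        def neg(r: float) -> float:
            return -self._profiled_loglik(self._shape_matrix("EB", r))[0]

        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        r = float(res.x)
        lnL, mu, s2 = self._profiled_loglik(self._shape_matrix("EB", r))
        return self._result(model, {"sigma2": s2, "mu": mu, "r": r}, lnL, bool(res.success))

    def fit_all(self) -> list["TraitEvolutionFit"]:
        models = ["BM", "OU", "EB"] if self.is_ultrametric else ["BM"]
        return [self.fit(m) for m in models]

    def _result(self, model, params, lnL, converged) -> "TraitEvolutionFit":
        k = _N_PARAMS[model]
        return TraitEvolutionFit(
            model=model,
            params=params,
            log_likelihood=lnL,
            aic=-2 * lnL + 2 * k,
            n_params=k,
            n_species=self.n,
            converged=converged,
        )


@dataclass
class TraitEvolutionFit:
    """Maximum-likelihood fit of one trait-evolution model."""

    model: str
    params: dict
    log_likelihood: float
    aic: float
    n_params: int
    n_species: int
    converged: bool

    def summary(self) -> str:
        lines = [
            f"Trait evolution model: {self.model}",
            f"  n species      {self.n_species}",
            f"  log-likelihood {self.log_likelihood:.4f}",
            f"  AIC            {self.aic:.4f}",
            f"  converged      {self.converged}",
            "  parameters:",
        ]
        for name, val in self.params.items():
            lines.append(f"    {name:8s} {val:.6g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "lnL": self.log_likelihood,
            "AIC": self.aic,
            "converged": self.converged,
        }
        out.update(self.params)
        return out


def fit_model(tree: Phylogeny, trait, model: str = "BM") -> TraitEvolutionFit:
    """Convenience wrapper: fit one model to one trait."""
    return TraitEvolutionModel(trait, tree).fit(model)


def select_model(fits: list[TraitEvolutionFit]) -> TraitEvolutionFit:
    """Minimum-AIC model; ties break toward fewer parameters, then BM."""
    if len(fits) < 2:
        raise ValueError("model selection needs at least 2 fits")
    return min(fits, key=lambda f: (round(f.aic, 10), f.n_params, _MODEL_ORDER[f.model]))


# ---------------------------------------------------------------------------
# richness rarefaction
# ---------------------------------------------------------------------------

@dataclass
class RarefactionCurve:
    """Distribution of K and its p-value across subsampled richness levels."""

    trait_name: str
    levels: list[int]
    k_values: dict[int, np.ndarray]
    p_values: dict[int, np.ndarray]
    n_subsamples: int
    seed: int | None
    alpha: float = 0.05

    def summary(self) -> pd.DataFrame:
        rows = []
        for lev in self.levels:
            ks = self.k_values[lev]
            ps = self.p_values[lev]
            ok = ~np.isnan(ps)
            rows.append(
                {
                    "level": lev,
                    "median_K": float(np.nanmedian(ks)) if ok.any() else np.nan,
                    "prop_significant": float(np.mean(ps[ok] < self.alpha))
                    if ok.any()
                    else np.nan,
                    "n_subsamples": len(ks),
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lev in self.levels:
            for rep, (k, p) in enumerate(zip(self.k_values[lev], self.p_values[lev])):
                rows.append(
                    {"trait": self.trait_name, "level": lev, "replicate": rep,
                     "K": k, "p": p}
                )
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Diagnostic figure: median K and proportion significant vs level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.summary()
        ax.plot(s["level"], s["prop_significant"], "o-",
                label=f"prop. p < {self.alpha:g}")
        ax.plot(s["level"], s["median_K"], "s--", label="median K")
        ax.set_xlabel("subsampled richness")
        ax.set_title(f"signal detectability: {self.trait_name}")
        ax.invert_xaxis()
        ax.legend()
        return ax


def rarefy_signal(
    tree: Phylogeny,
    trait,
    community: list[str],
    levels: list[int],
    n_subsamples: int = 999,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
    trait_name: str = "trait",
) -> RarefactionCurve:
    """Subsample a community to each richness level and re-test signal.

    At each level, ``n_subsamples`` species subsets are drawn without
    replacement; the tree is restricted to each subset (root moved to the
    subset MRCA) and K with its permutation p recomputed.  The proportion
    of subsets significant at 0.05 traces the power of the signal test as
    richness falls.  A level equal to the full richness short-circuits to
    the observed community (all subsamples identical).
    """
    community = list(community)
    richness = len(community)
    if min(levels) < 3:
        raise ValueError("rarefaction levels must be >= 3 species")
    if max(levels) > richness:
        raise ValueError(
            f"level {max(levels)} exceeds community richness {richness}"
        )
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    trait = pd.Series(trait, dtype=float)
    C_full = tree.vcv_matrix().submatrix(community)
    x_full = trait.loc[community].to_numpy()
    comm_idx = np.arange(richness)
    k_values: dict[int, np.ndarray] = {}
    p_values: dict[int, np.ndarray] = {}
    for lev in levels:
        ks = np.empty(n_subsamples)
        ps = np.empty(n_subsamples)
        if lev == richness:
            C = pruned_vcv(C_full.values)
            k_obs = float(blomberg_k_many(C, x_full[:, None])[0])
            for r in range(n_subsamples):
                ks[r] = k_obs
                ps[r] = _permutation_p_core(C, x_full, n_perm, gen)
        else:
            for r in range(n_subsamples):
                idx = gen.choice(comm_idx, size=lev, replace=False)
                C = pruned_vcv(C_full.values[np.ix_(idx, idx)])
                x = x_full[idx]
                if np.ptp(x) == 0:  # constant subsample: signal undefined
                    ks[r] = np.nan
                    ps[r] = np.nan
                    continue
                ks[r] = float(blomberg_k_many(C, x[:, None])[0])
                ps[r] = _permutation_p_core(C, x, n_perm, gen)
        k_values[lev] = ks
        p_values[lev] = ps
    return RarefactionCurve(
        trait_name=trait_name,
        levels=list(levels),
        k_values=k_values,
        p_values=p_values,
        n_subsamples=n_subsamples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# community merging
# ---------------------------------------------------------------------------

def merge_communities(traits_a: pd.DataFrame, traits_b: pd.DataFrame) -> pd.DataFrame:
    """Merge two per-site trait tables into one artificial community.

    Species unique to either site keep their values; species shared by
    both get the arithmetic mean of each trait.  Inputs are indexed by
    species (one site each) with identical trait columns.
    """
    if list(traits_a.columns) != list(traits_b.columns):
        raise ValueError(
            "trait tables have incompatible columns: "
            f"{list(traits_a.columns)} vs {list(traits_b.columns)}"
        )
    stacked = pd.concat([traits_a, traits_b])
    return stacked.groupby(level=-1).mean().sort_index()
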