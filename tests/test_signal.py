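import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from phenosignal import parse_newick
from phenosignal.signal import (
    TraitEvolutionModel,
    blomberg_k,
    blomberg_k_many,
    fit_model,
    merge_communities,
    phylogenetic_signal,
    pruned_vcv,
    rarefy_signal,
    select_model,
    signal_permutation_p,
)
from phenosignal.synthetic import simulate_trait, simulate_tree


class TestBlombergK:
    def test_star_tree_forces_k_one(self):
        star = parse_newick("(A:1,B:1,C:1,D:1);")
        gen = np.random.default_rng(0)
        for _ in range(10):
            x = dict(zip("ABCD", gen.normal(size=4)))
            assert blomberg_k(star, x) == pytest.approx(1.0)

    def test_three_tip_hand_value(self, three_tip_tree):
        assert blomberg_k(three_tip_tree, {"A": 0, "B": 0, "C": 3}) == pytest.approx(
            17 / 12, abs=1e-12
        )

    def test_matches_independent_r_implementation(self):
        # frozen from phytools::phylosig on the identical tree and trait
        tree = simulate_tree(10, 1.0, rng=42, height=1.0)
        x = simulate_trait(tree, "BM", 1.0, rng=7)
        assert blomberg_k(tree, x) == pytest.approx(1.34190516244, abs=1e-9)

    def test_affine_invariance(self, yule_tree_20):
        x = simulate_trait(yule_tree_20, "BM", 1.0, rng=3)
        k0 = blomberg_k(yule_tree_20, x)
        assert blomberg_k(yule_tree_20, 3.7 * x - 11.0) == pytest.approx(k0, rel=1e-10)

    def test_bm_expectation_near_one(self, yule_tree_20):
        X = simulate_trait(yule_tree_20, "BM", 1.0, rng=5, n_traits=500)
        ks = blomberg_k_many(yule_tree_20.vcv_matrix().values, X.to_numpy())
        se = ks.std(ddof=1) / np.sqrt(len(ks))
        assert abs(ks.mean() - 1.0) < 4 * se + 0.05

    def test_constant_trait_rejected(self, three_tip_tree):
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(three_tip_tree, {"A": 1, "B": 1, "C": 1})


class TestPermutationTest:
    def test_exhaustive_enumeration_matches_rank(self):
        # on 6 tips the permutation distribution can be enumerated exactly:
        # the add-one-corrected rank of observed MSE among sampled
        # permutations converges to its rank among all 6! of them
        tree = simulate_tree(6, 1.0, rng=1, height=1.0)
        C = tree.vcv_matrix().values
        x = simulate_trait(tree, "BM", 1.0, rng=2).to_numpy()
        from phenosignal.signal import _gls_core

        def mse(v):
            _, q, _, _, _ = _gls_core(C, np.asarray(v, float)[:, None])
            return float(q[0])

        mse_obs = mse(x)
        all_mse = np.array([mse(p) for p in itertools.permutations(x)])
        exact = np.mean(all_mse <= mse_obs + 1e-12)
        gen = np.random.default_rng(3)
        sampled = signal_permutation_p(tree, pd.Series(x, index=tree.tip_labels),
                                       n_perm=4999, rng=gen)
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_clade_indicator_trait_is_extreme(self, balanced_tree):
        x = {t: (1.0 if t in "ABCD" else 0.0) for t in balanced_tree.tip_labels}
        # tiny jitter so the trait is not constant within groups under permutation
        gen = np.random.default_rng(0)
        x = {t: v + 1e-3 * gen.normal() for t, v in x.items()}
        # within-clade relabelings are near-ties (4!4!2/8! ~ 1/35 of all
        # permutations), so the attainable p floor is ~0.014, not 1/1000
        p = signal_permutation_p(balanced_tree, x, n_perm=999, rng=1)
        assert p <= 0.02

    def test_white_noise_p_uniform(self, yule_tree_20):
        gen = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            x = pd.Series(gen.normal(size=20), index=yule_tree_20.tip_labels)
            ps.append(signal_permutation_p(yule_tree_20, x, n_perm=99, rng=gen))
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.005

    def test_zero_permutations_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            signal_permutation_p(three_tip_tree, {"A": 0, "B": 1, "C": 2}, n_perm=0)


class TestModelFitting:
    def test_bm_two_tip_closed_form(self):
        fit = fit_model(parse_newick("(A:1,B:1);"), {"A": 0.0, "B": 2.0}, "BM")
        assert fit.params["mu"] == pytest.approx(1.0)
        assert fit.params["sigma2"] == pytest.approx(1.0)

    def test_bm_loglik_matches_dense_mvn(self):
        tree = simulate_tree(12, 1.0, rng=4, height=1.0)
        x = simulate_trait(tree, "BM", 2.0, mu=1.0, rng=5)
        fit = fit_model(tree, x, "BM")
        dense = multivariate_normal(
            mean=np.full(12, fit.params["mu"]),
            cov=fit.params["sigma2"] * tree.vcv_matrix().values,
        ).logpdf(x.to_numpy())
        assert fit.log_likelihood == pytest.approx(dense, abs=1e-8)

    def test_ou_limit_recovers_bm(self):
        tree = simulate_tree(10, 1.0, rng=6, height=1.0)
        x = simulate_trait(tree, "BM", 1.0, rng=7)
        m = TraitEvolutionModel(x, tree)
        bm = m.fit("BM")
        lnL_ou_small = m._profiled_loglik(m._shape_matrix("OU", 1e-8))[0]
        assert lnL_ou_small == pytest.approx(bm.log_likelihood, abs=1e-4)

    def test_eb_at_zero_equals_bm_exactly(self):
        tree = simulate_tree(10, 1.0, rng=6, height=1.0)
        x = simulate_trait(tree, "BM", 1.0, rng=8)
        m = TraitEvolutionModel(x, tree)
        assert m._profiled_loglik(m._shape_matrix("EB", 0.0))[0] == m.fit(
            "BM"
        ).log_likelihood

    def test_nonultrametric_ou_rejected(self):
        tree = parse_newick("((A:1,B:2):1,C:4);")
        with pytest.raises(ValueError, match="ultrametric"):
            fit_model(tree, {"A": 0, "B": 1, "C": 2}, "OU")

    def test_aic_tie_breaks_to_bm(self):
        mk = lambda model, aic, k: type(
            "F", (), {"model": model, "aic": aic, "n_params": k}
        )()
        from phenosignal.signal import _MODEL_ORDER  # noqa: F401

        fits = [mk("OU", 10.0, 3), mk("BM", 10.0, 2)]
        assert select_model(fits).model == "BM"

    def test_strong_ou_recovered_by_aic(self):
        tree = simulate_tree(100, 1.0, rng=1, height=1.0)
        wins = 0
        for s in range(20):
            x = simulate_trait(tree, "OU", 1.0, alpha=3.0, rng=s)
            wins += select_model(TraitEvolutionModel(x, tree).fit_all()).model == "OU"
        assert wins > 10

    def test_bm_never_strongly_beaten_under_nesting(self):
        tree = simulate_tree(60, 1.0, rng=2, height=1.0)
        deltas = []
        for s in range(30):
            x = simulate_trait(tree, "BM", 1.0, rng=100 + s)
            fits = {f.model: f for f in TraitEvolutionModel(x, tree).fit_all()}
            deltas.append(fits["BM"].aic - min(fits["OU"].aic, fits["EB"].aic))
        # nested alternatives gain at most ~2 lnL units on average
        assert np.mean(deltas) < 2.0


class TestRarefaction:
    def test_full_richness_is_degenerate_at_observed(self, yule_tree_20):
        x = simulate_trait(yule_tree_20, "BM", 1.0, rng=10)
        community = yule_tree_20.tip_labels[:12]
        curve = rarefy_signal(
            yule_tree_20, x, community, levels=[12], n_subsamples=20,
            n_perm=99, rng=0,
        )
        C = pruned_vcv(yule_tree_20.vcv_matrix().submatrix(community).values)
        k_obs = float(blomberg_k_many(C, x.loc[community].to_numpy()[:, None])[0])
        assert np.allclose(curve.k_values[12], k_obs)

    def test_level_above_richness_rejected(self, yule_tree_20):
        x = simulate_trait(yule_tree_20, "BM", 1.0, rng=11)
        with pytest.raises(ValueError, match="exceeds"):
            rarefy_signal(yule_tree_20, x, yule_tree_20.tip_labels[:10],
                          levels=[15], n_subsamples=5, n_perm=19, rng=0)

    def test_plot_returns_axes(self, yule_tree_20):
        import matplotlib

        matplotlib.use("Agg")
        x = simulate_trait(yule_tree_20, "BM", 1.0, rng=14)
        curve = rarefy_signal(yule_tree_20, x, yule_tree_20.tip_labels,
                              levels=[20, 10], n_subsamples=5, n_perm=19, rng=0)
        ax = curve.plot()
        assert ax.get_xlabel() == "subsampled richness"

    def test_white_noise_flat_near_alpha(self):
        tree = simulate_tree(40, 1.0, rng=12, height=1.0)
        gen = np.random.default_rng(13)
        x = pd.Series(gen.normal(size=40), index=tree.tip_labels)
        curve = rarefy_signal(tree, x, tree.tip_labels, levels=[40, 20, 10],
                              n_subsamples=60, n_perm=99, rng=gen)
        props = curve.summary()["prop_significant"]
        assert (props < 0.18).all()  # ~5% nominal, binomial noise at 60 reps


class TestMerging:
    def test_union_richness(self):
        cols = ["FF", "FSL"]
        a = pd.DataFrame(1.0, index=[f"s{i}" for i in range(20)], columns=cols)
        b = pd.DataFrame(
            2.0, index=[f"s{i}" for i in range(7, 30)], columns=cols
        )  # 23 species, 13 shared
        merged = merge_communities(a, b)
        assert len(merged) == 30

    def test_shared_species_get_mean(self):
        a = pd.DataFrame({"FF": [10.0]}, index=["x"])
        b = pd.DataFrame({"FF": [20.0]}, index=["x"])
        assert merge_communities(a, b).loc["x", "FF"] == 15.0

    def test_identical_tables_identity(self):
        a = pd.DataFrame({"FF": [1.0, 2.0]}, index=["x", "y"])
        assert merge_communities(a, a.copy()).equals(a)

    def test_incompatible_columns_rejected(self):
        a = pd.DataFrame({"FF": [1.0]}, index=["x"])
        b = pd.DataFrame({"PFP": [1.0]}, index=["y"])
        with pytest.raises(ValueError, match="incompatible"):
            merge_communities(a, b)
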