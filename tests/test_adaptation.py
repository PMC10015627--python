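import math

import numpy as np
import pytest

from phyloregime.adaptation import (
    ModelScore,
    aicc,
    compare_models,
    derived_quantities,
    fit_model,
    model_loglik,
    ou_moments,
)
from phyloregime.experiments import gaussian_oracle_max_dev, random_painting
from phyloregime.painting import OUTCROSSER, SELFER, uniform_painting
from phyloregime.simulate import (
    SimulationSpec,
    random_binary_tree,
    simulate_trait,
)
from phyloregime.traits import TraitTable
from phyloregime.tree import read_newick


class TestAicc:
    def test_values(self):
        assert aicc(0.0, 0, 10) == 0.0
        assert aicc(-10.0, 3, 12) == pytest.approx(29.0)

    def test_large_n_limit(self):
        assert abs(aicc(-5.0, 3, 10**9) - (6 + 10)) < 1e-6

    def test_small_n_undefined(self):
        with pytest.raises(ValueError):
            aicc(0.0, 4, 5)


class TestOuMoments:
    def test_half_life_weights_single_path(self):
        tree = read_newick("(A:1.0,B:1.0);")
        paint = uniform_painting(tree, OUTCROSSER)
        W, cols, V0, labels = ou_moments(tree, paint, math.log(2))
        i = labels.index("A")
        assert W[i, 0] == pytest.approx(0.5)  # y0 weight e^{-alpha T}
        assert W[i, 1] == pytest.approx(0.5)  # theta weight
        assert V0[0, 1] == pytest.approx(0.0)  # divergence at the root

    @pytest.mark.parametrize("seed", range(5))
    def test_weight_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree(7, seed)
        paint = random_painting(tree, rng)
        W, *_ = ou_moments(tree, paint, float(rng.uniform(0.1, 5)))
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)


class TestModelLoglik:
    def test_matches_explicit_gaussian(self):
        assert gaussian_oracle_max_dev(n_trees=60, seed=2) < 1e-8

    def test_ou2_collapses_to_ou1(self, elegans_tree, elegans_painting, study_fixture):
        trait = study_fixture.te_percent
        kw = dict(alpha=2.0, v=1.3)
        l1 = model_loglik(elegans_tree, trait, elegans_painting, "OU1", theta=4.0, **kw)
        l2 = model_loglik(
            elegans_tree, trait, elegans_painting, "OU2",
            theta={OUTCROSSER: 4.0, SELFER: 4.0}, **kw,
        )
        assert l2 == pytest.approx(l1, abs=1e-12)

    def test_bm_limit_of_ou(self, elegans_tree, elegans_painting, study_fixture):
        trait = study_fixture.te_percent
        alpha = 1e-8
        v = 2.0 / (2 * alpha)  # sigma^2 = 2 held fixed
        mu = 5.0
        l_ou = model_loglik(
            elegans_tree, trait, elegans_painting, "OU1", alpha=alpha, v=v, theta=mu
        )
        l_bm = model_loglik(elegans_tree, trait, None, "BM", sigma2=2.0, mu=mu)
        assert abs(l_ou - l_bm) < 1e-4

    def test_ou_covariance_converges_to_bm(self, elegans_tree, elegans_painting):
        from phyloregime.adaptation import _mrca_depths

        alpha = 1e-8
        _, _, V0, labels = ou_moments(elegans_tree, elegans_painting, alpha)
        C = _mrca_depths(elegans_tree, labels)
        sigma2 = 2.0
        np.testing.assert_allclose(sigma2 / (2 * alpha) * V0, sigma2 * C, rtol=1e-5)

    def test_duplicate_tips_named_in_error(self):
        tree = read_newick("((A:1.0,B:0.0):1.0,C:2.0);")
        g = tree
        # B and the grafted twin sit at zero distance
        from phyloregime.tree import graft_tips_as_polytomy

        g = graft_tips_as_polytomy(tree, "B", ["B2"], length=0.0)
        trait = TraitTable("x", {l: 1.0 * i for i, l in enumerate(g.tip_labels())})
        with pytest.raises(ValueError, match="B2"):
            model_loglik(g, trait, None, "BM", sigma2=1.0, mu=0.0)


class TestFitModel:
    def test_bm_sigma2_recovery_50_tips(self):
        # sigma2_hat ~ sigma2 * chi2_{n-1} / n: at n = 50 the +-25% window
        # holds ~79% of the sampling distribution, so assert that rate plus
        # unbiasedness of the mean across replicates
        hits = 0
        n = 100
        estimates = []
        for i in range(n):
            tree = random_binary_tree(50, seed=i, ultrametric=True)
            spec = SimulationSpec(seed=2_000 + i, trait_model="BM", y0=0.0, sigma2=2.0)
            trait = simulate_trait(tree, None, spec)
            fit = fit_model(tree, trait, None, "BM")
            estimates.append(fit.sigma2)
            hits += abs(fit.sigma2 - 2.0) / 2.0 <= 0.25
        assert hits >= 70
        assert np.mean(estimates) == pytest.approx(2.0, rel=0.10)

    def test_ou2_requires_both_regimes(self, elegans_tree, study_fixture):
        paint = uniform_painting(elegans_tree, OUTCROSSER)
        with pytest.raises(ValueError, match="both regimes"):
            fit_model(elegans_tree, study_fixture.te_percent, paint, "OU2")

    def test_needs_six_tips(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        trait = TraitTable("x", {"A": 1.0, "B": 2.0, "C": 3.0})
        with pytest.raises(ValueError, match="6 tips"):
            fit_model(tree, trait, None, "BM")

    def test_nesting_on_fixture(self, elegans_tree, elegans_painting, study_fixture):
        trait = study_fixture.te_percent
        f_bm = fit_model(elegans_tree, trait, elegans_painting, "BM")
        f_ou1 = fit_model(elegans_tree, trait, elegans_painting, "OU1")
        f_ou2 = fit_model(elegans_tree, trait, elegans_painting, "OU2")
        assert f_ou2.loglik >= f_ou1.loglik - 1e-4
        assert f_ou1.loglik >= f_bm.loglik - 1e-4
        assert (f_bm.k, f_ou1.k, f_ou2.k) == (2, 3, 4)


class TestCompareModels:
    def test_mutator_printed_row(self):
        scores = [
            ModelScore("BM", 51.41, 2),
            ModelScore("OU1", 51.00, 3),
            ModelScore("OU2", 49.21, 4),
        ]
        rank = compare_models(scores)
        assert rank.best == "OU2"
        assert rank.margin == pytest.approx(1.79, abs=1e-9)
        assert rank.indistinguishable == ["OU2", "OU1"]

    def test_unclassified_repeats_printed_row(self):
        scores = [
            ModelScore("BM", 72.05, 2),
            ModelScore("OU1", 42.61, 3),
            ModelScore("OU2", 45.13, 4),
        ]
        rank = compare_models(scores)
        assert rank.best == "OU1"
        assert rank.delta["BM"] == pytest.approx(29.44)
        assert "BM" not in rank.indistinguishable
        assert rank.indistinguishable == ["OU1"]

    def test_tie_prefers_simpler_model(self):
        rank = compare_models([ModelScore("OU2", 10.0, 4), ModelScore("BM", 10.0, 2)])
        assert rank.best == "BM"
        assert set(rank.indistinguishable) == {"BM", "OU2"}


class TestDerivedQuantities:
    def test_half_life(self):
        assert derived_quantities(math.log(2), 1.0)["t_half"] == pytest.approx(1.0)

    def test_stationary_variance(self):
        assert derived_quantities(1.0, 2.0)["v"] == pytest.approx(1.0)

    def test_mutator_half_life_as_percent_of_height(self):
        # t1/2 = 0.0011 on a height-1 tree is 0.11% of tree height
        alpha = math.log(2) / 0.0011
        dq = derived_quantities(alpha, 1.0, tree_height=1.0)
        assert dq["t_half_pct_height"] == pytest.approx(0.11, abs=1e-9)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            derived_quantities(0.0, 1.0)
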