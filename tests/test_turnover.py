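import math

import numpy as np
import pandas as pd
import pytest

from phyloregime.experiments import (
    bd_enumeration_max_dev,
    bd_expm_max_dev,
    bd_row_sum_max_dev,
    planted_loss_recovery,
)
from phyloregime.families import GeneFamilyMatrix
from phyloregime.painting import SELFER
from phyloregime.qvalue import qvalues
from phyloregime.simulate import simulate_gene_families
from phyloregime.tree import read_newick
from phyloregime.turnover import (
    _classify_nets,
    bd_transition_matrix,
    bd_transition_prob,
    family_loglik,
    family_significance,
    fisher_enrichment,
    fit_turnover,
    lineage_net_changes,
    reconstruct_changes,
)


class TestTransitionProbabilities:
    def test_zero_time_identity(self):
        assert bd_transition_prob(3, 3, 0.0, 1.0) == 1.0
        assert bd_transition_prob(3, 2, 0.0, 1.0) == 0.0

    def test_single_gene_unit_rate(self):
        assert bd_transition_prob(1, 0, 1.0, 1.0) == pytest.approx(0.5)
        assert bd_transition_prob(1, 1, 1.0, 1.0) == pytest.approx(0.25)

    def test_zero_absorbing(self):
        assert bd_transition_prob(0, 0, 5.0, 1.0) == 1.0
        assert bd_transition_prob(0, 2, 5.0, 1.0) == 0.0

    def test_rows_sum_to_one(self):
        assert bd_row_sum_max_dev(max_s=10, a_max=0.45) < 1e-9

    def test_matrix_matches_closed_form(self):
        M = bd_transition_matrix(15, t=0.7, lam=0.6)
        for s in (1, 3, 7):
            for c in (0, 2, 5, 11):
                assert M[s, c] == pytest.approx(
                    bd_transition_prob(s, c, 0.7, 0.6), abs=1e-12
                )

    def test_matrix_matches_generator_exponential(self):
        assert bd_expm_max_dev(seed=0) < 1e-9


class TestFamilyLoglik:
    def test_identity_transitions_select_root(self):
        tree = read_newick("(A:1.0,B:1.0);")
        ll = family_loglik(tree, {"A": 3, "B": 3}, 0.0, n_max=10)
        assert ll == pytest.approx(-math.log(10), abs=1e-12)

    def test_impossible_under_zero_rate(self):
        tree = read_newick("(A:1.0,B:1.0);")
        assert family_loglik(tree, {"A": 3, "B": 5}, 0.0, n_max=10) == -math.inf

    def test_matches_enumeration(self):
        assert bd_enumeration_max_dev(n_trees=20, seed=1) < 1e-9

    def test_count_exceeding_nmax_rejected(self):
        tree = read_newick("(A:1.0,B:1.0);")
        with pytest.raises(ValueError, match="n_max"):
            family_loglik(tree, {"A": 99, "B": 1}, 0.5, n_max=10)


class TestFitTurnover:
    def test_lambda_zero_simulation_hits_lower_bound(self, elegans_tree):
        fams = simulate_gene_families(elegans_tree, 0.0, n_families=200, seed=5)
        fit = fit_turnover(elegans_tree, fams, n_lambdas=1)
        assert fit.lambdas[0] <= 1e-5

    def test_two_lambda_model_detected(self, elegans_tree, elegans_painting):
        # selfer branches lambda=0.1, outcrosser 0.6: the 2-rate model
        # should beat the 1-rate model by > 2 AICc in most replicates
        lam_map = {
            nid: (0.1 if s == SELFER else 0.6)
            for nid, s in elegans_painting.states.items()
        }
        wins = 0
        n = 60
        for i in range(n):
            fams = simulate_gene_families(
                elegans_tree, lam_map, n_families=400, seed=10_000 + i
            )
            f1 = fit_turnover(elegans_tree, fams, n_lambdas=1)
            f2 = fit_turnover(
                elegans_tree, fams, n_lambdas=2, painting=elegans_painting
            )
            wins += f1.aicc - f2.aicc > 2.0
        assert wins >= 0.8 * n

    def test_error_model_grid(self, elegans_tree):
        fams = simulate_gene_families(elegans_tree, 0.3, n_families=80, eps=0.1, seed=3)
        fit = fit_turnover(elegans_tree, fams, n_lambdas=1, fit_error=True)
        assert 0.0 <= fit.eps <= 0.2
        assert fit.k == 2

    def test_requires_ultrametric_binary(self, elegans_tree):
        t = read_newick("(A:1.0,B:2.0);")
        fams = simulate_gene_families(elegans_tree, 0.3, n_families=10, seed=1)
        with pytest.raises(ValueError, match="ultrametric"):
            fit_turnover(t, fams, n_lambdas=1)


class TestSignificance:
    def test_extreme_family_flagged(self, elegans_tree):
        fams = simulate_gene_families(elegans_tree, 0.43, n_families=300, seed=21)
        planted = fams.counts.copy()
        row = np.zeros(len(planted.columns), dtype=int)
        row[0] = 50
        planted.loc["EXTREME"] = row
        fit = fit_turnover(
            elegans_tree, GeneFamilyMatrix(planted), n_lambdas=1, apply_filter=False
        )
        p, q = family_significance(fit, M=1000, seed=22)
        assert p["EXTREME"] < 0.01

    def test_planted_parallel_losses_recovered(self):
        recovered, planted = planted_loss_recovery(
            seed=0, n_background=600, n_planted=30, M=5000
        )
        assert recovered >= 0.8 * planted


class TestQvalues:
    def test_all_ones(self):
        assert np.all(qvalues(np.ones(50)) == 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_bh_fallback_never_exceeds_one(self):
        p = np.linspace(0.9, 1.0, 30)
        assert qvalues(p).max() <= 1.0


class TestReconstructChanges:
    def test_stable_family(self):
        tree = read_newick("(A:1.0,B:1.0);")
        counts = pd.DataFrame({"A": [5], "B": [5]}, index=["F1"])
        fit = fit_turnover(
            tree, GeneFamilyMatrix(counts), n_lambdas=1, apply_filter=False
        )
        fit.lambdas[0] = 0.01
        nodes, deltas, tie = reconstruct_changes(fit, "F1")
        assert nodes[tree.root] == 5
        assert all(d == 0 for d in deltas.values())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_argmax(self, seed):
        from phyloregime.simulate import random_binary_tree

        tree = random_binary_tree(3, seed, ultrametric=True)
        rng = np.random.default_rng(seed)
        n_max = 10
        counts = {l: int(rng.integers(0, 5)) for l in tree.tip_labels()}
        df = pd.DataFrame({k: [v] for k, v in counts.items()}, index=["F1"])
        fit = fit_turnover(
            tree, GeneFamilyMatrix(df), n_lambdas=1, apply_filter=False
        )
        lam = 0.5
        fit.lambdas[0] = lam
        fit.n_max = n_max
        nodes, _, tie = reconstruct_changes(fit, "F1")
        # brute force over internal assignments (root > 0)
        import itertools

        internals = [n.id for n in tree.nodes if n.children]
        scored = []
        for assign in itertools.product(range(n_max + 1), repeat=len(internals)):
            state = dict(zip(internals, assign))
            if state[tree.root] == 0:
                continue
            for t in tree.tips():
                state[t.id] = counts[t.label]
            score = 0.0
            for n in tree.nodes:
                if n.parent is None:
                    continue
                prob = bd_transition_prob(state[n.parent], state[n.id], n.length, lam)
                score += math.log(prob) if prob > 0 else -math.inf
            scored.append((score, assign))
        best_score = max(s for s, _ in scored)
        best_set = {a for s, a in scored if s >= best_score - 1e-10}
        assert tuple(nodes[i] for i in internals) in best_set


class TestClassification:
    def test_decreasing_in_selfers_rule(self):
        assert _classify_nets([-1, 0, -2], [0, 1, 3]) == "DecreasingInSelfers"

    def test_all_stable(self):
        assert _classify_nets([0, 0], [0, 0, 0]) == "Stable"

    def test_mixed_signs_unclassified(self):
        assert _classify_nets([-1, 1], [0, 0]) == "Unclassified"

    @pytest.mark.parametrize(
        "selfer,outx,expected",
        [
            ([1, 0], [0, -2], "IncreasingInSelfers"),
            ([0, 0], [-1, -3], "DecreasingInOutcrossers"),
            ([0, 0], [2, 1], "IncreasingInOutcrossers"),
            ([-2, -1], [-1, 0], "Unclassified"),
        ],
    )
    def test_other_categories(self, selfer, outx, expected):
        assert _classify_nets(selfer, outx) == expected

    def test_lineage_origins_on_fixture(self, elegans_tree, elegans_painting):
        counts = {n.id: 5 for n in elegans_tree.nodes}
        counts[elegans_tree.tip_id("C_elegans")] = 2
        nets = lineage_net_changes(elegans_tree, elegans_painting, counts)
        # every outcrosser chain reaches the root
        for t in elegans_tree.tips():
            state, net = nets[t.label]
            if t.label == "C_elegans":
                assert state == SELFER and net == -3
            else:
                assert net == 0
        # the C. tropicalis lineage starts where its selfing clade begins
        trop = elegans_tree.mrca(
            elegans_tree.tip_id("C_tropicalis_JU1373"),
            elegans_tree.tip_id("C_tropicalis_NIC58"),
        )
        origin = elegans_tree.nodes[trop].parent
        counts[origin] = 9
        counts[elegans_tree.tip_id("C_tropicalis_JU1373")] = 4
        nets = lineage_net_changes(elegans_tree, elegans_painting, counts)
        assert nets["C_tropicalis_JU1373"] == (SELFER, -5)


class TestFisher:
    def test_diagonal_table(self):
        odds, p = fisher_enrichment([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-9)
        assert odds == math.inf

    def test_flat_table(self):
        _, p = fisher_enrichment([[1, 1], [1, 1]])
        assert p == 1.0

    def test_transpose_invariance(self):
        t = [[7, 2], [3, 9]]
        _, p1 = fisher_enrichment(t)
        _, p2 = fisher_enrichment(np.array(t).T)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_degenerate_margin(self):
        _, p = fisher_enrichment([[0, 0], [3, 4]])
        assert p == 1.0
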