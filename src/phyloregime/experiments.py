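"""Validation experiments: oracle equivalences, parameter recovery,
model-selection calibration and distributional checks.

These are the package's own correctness experiments, shared by the test
suite and the acceptance script. Each function is deterministic given its
seed and returns plain numbers. The oracles are written independently of
the implementation paths they check: explicit multivariate-Gaussian
construction for the trait models, exhaustive enumeration for the Mk and
birth--death pruning recursions, and matrix exponentials for the
birth--death transition matrix.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm
from scipy.stats import kstest, multivariate_normal

from .adaptation import compare_models, fit_model, model_loglik
from .ancestral import reconstruct_ancestral_bm
from .mk import MkFit, fit_mk, marginal_ancestral_states, mk_loglik, mk_transition_matrix
from .painting import OUTCROSSER, SELFER, RegimePainting
from .simulate import (
    SimulationSpec,
    elegans_like_painting,
    elegans_like_tree,
    make_study_fixture,
    random_binary_tree,
    simulate_gene_families,
    simulate_trait,
)
from .traits import TraitTable
from .tree import Phylogeny
from .turnover import (
    bd_transition_matrix,
    bd_transition_prob,
    classify_parallel,
    evaluate_families,
    family_loglik,
    family_significance,
    fit_turnover,
)

# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------


def random_painting(tree: Phylogeny, rng: np.random.Generator) -> RegimePainting:
    states = {n.id: int(rng.integers(2)) for n in tree.nodes if n.parent is not None}
    return RegimePainting(states, int(rng.integers(2)), provenance="simulated")


def _ou_moments_recursive(tree, painting, alpha, v, theta, y0):
    """Tip mean/cov by forward recursion down the tree (oracle path).

    E[child] = E[parent] e^{-at} + theta (1 - e^{-at});
    Cov(i, j) = Cov at the MRCA decayed by e^{-a * (paths to i and j)}.
    """
    labels = tree.tip_labels()
    mean = {tree.root: y0}
    var = {tree.root: 0.0}
    for n in tree.preorder():
        if n.parent is None:
            continue
        t = n.length
        th = theta[painting.states[n.id]]
        decay = math.exp(-alpha * t)
        mean[n.id] = mean[n.parent] * decay + th * (1 - decay)
        var[n.id] = var[n.parent] * decay**2 + v * (1 - decay**2)
    d = tree.depths()
    ids = [tree.tip_id(l) for l in labels]
    n = len(ids)
    C = np.empty((n, n))
    for i in range(n):
        C[i, i] = var[ids[i]]
        for j in range(i + 1, n):
            m = tree.mrca(ids[i], ids[j])
            decay = math.exp(-alpha * (d[ids[i]] - d[m])) * math.exp(
                -alpha * (d[ids[j]] - d[m])
            )
            C[i, j] = C[j, i] = var[m] * decay
    mu = np.array([mean[i] for i in ids])
    return mu, C


def gaussian_oracle_max_dev(n_trees: int = 200, seed: int = 0) -> float:
    """Max |lnL - explicit MVN logpdf| over random trees for BM/OU1/OU2."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trees):
        n_tips = int(rng.integers(3, 7))
        tree = random_binary_tree(n_tips, int(rng.integers(2**31)))
        painting = random_painting(tree, rng)
        labels = tree.tip_labels()
        y = rng.normal(3.0, 2.0, n_tips)
        trait = TraitTable("y", dict(zip(labels, y)))
        d = tree.depths()
        ids = [tree.tip_id(l) for l in labels]
        # BM oracle: mean mu, covariance sigma2 * shared depth
        sigma2, mu = float(rng.uniform(0.5, 3.0)), float(rng.normal(0, 2))
        C = np.array([[d[tree.mrca(i, j)] for j in ids] for i in ids])
        ll = model_loglik(tree, trait, None, "BM", sigma2=sigma2, mu=mu)
        oracle = multivariate_normal.logpdf(y, np.full(n_tips, mu), sigma2 * C)
        worst = max(worst, abs(ll - oracle))
        # OU oracles
        alpha = float(rng.uniform(0.2, 5.0))
        v = float(rng.uniform(0.5, 3.0))
        th = {OUTCROSSER: float(rng.normal(5, 1)), SELFER: float(rng.normal(2, 1))}
        for model, theta_arg in (("OU1", th[OUTCROSSER]), ("OU2", th)):
            tmap = {s: float(theta_arg) for s in (0, 1)} if model == "OU1" else th
            y0 = tmap[painting.root_state]
            mu_vec, Cov = _ou_moments_recursive(tree, painting, alpha, v, tmap, y0)
            ll = model_loglik(
                tree, trait, painting, model, alpha=alpha, v=v, theta=theta_arg
            )
            oracle = multivariate_normal.logpdf(y, mu_vec, Cov)
            worst = max(worst, abs(ll - oracle))
    return worst


def mk_enumeration_max_dev(n_trees: int = 50, seed: int = 0) -> float:
    """Max |pruning - enumeration| over random <=5-tip trees (lnL and marginals)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trees):
        n_tips = int(rng.integers(2, 6))
        tree = random_binary_tree(n_tips, int(rng.integers(2**31)))
        q01, q10 = rng.uniform(0.05, 2.0, 2)
        tip_states = {l: int(rng.integers(2)) for l in tree.tip_labels()}
        internals = [n.id for n in tree.nodes if n.children]
        # enumerate all internal-state assignments
        lik_total = 0.0
        node_post = {i: np.zeros(2) for i in internals}
        for assign in itertools.product((0, 1), repeat=len(internals)):
            state = dict(zip(internals, assign))
            for t in tree.tips():
                state[t.id] = tip_states[t.label]
            lik = 0.5  # flat root prior
            for n in tree.nodes:
                if n.parent is not None:
                    P = mk_transition_matrix(q01, q10, n.length)
                    lik *= P[state[n.parent], state[n.id]]
            lik_total += lik
            for i in internals:
                node_post[i][state[i]] += lik
        ll = mk_loglik(tree, tip_states, float(q01), float(q10))
        worst = max(worst, abs(ll - math.log(lik_total)))
        fit = MkFit("ARD", float(q01), float(q10), ll, 2, 0.0)
        marg = marginal_ancestral_states(fit, tree, tip_states)
        for i in internals:
            worst = max(worst, float(np.abs(marg[i] - node_post[i] / lik_total).max()))
    return worst


def bd_enumeration_max_dev(n_trees: int = 30, seed: int = 0, n_max: int = 12) -> float:
    """Max |pruning - enumeration| for family likelihoods on 3-tip trees."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trees):
        tree = random_binary_tree(3, int(rng.integers(2**31)), ultrametric=True)
        lam = float(rng.uniform(0.1, 1.0))
        counts = {l: int(rng.integers(0, 5)) for l in tree.tip_labels()}
        internals = [n.id for n in tree.nodes if n.children]
        mats = {
            n.id: np.array(
                [
                    [bd_transition_prob(s, c, n.length, lam) for c in range(n_max + 1)]
                    for s in range(n_max + 1)
                ]
            )
            for n in tree.nodes
            if n.parent is not None
        }
        total = 0.0
        for assign in itertools.product(range(n_max + 1), repeat=len(internals)):
            state = dict(zip(internals, assign))
            if state[tree.root] == 0:
                continue
            for t in tree.tips():
                state[t.id] = counts[t.label]
            lik = 1.0 / n_max  # uniform root prior on 1..n_max
            for n in tree.nodes:
                if n.parent is not None:
                    lik *= mats[n.id][state[n.parent], state[n.id]]
            total += lik
        ll = family_loglik(tree, counts, lam, n_max=n_max)
        worst = max(worst, abs(ll - math.log(total)))
    return worst


def bd_expm_max_dev(seed: int = 0, n_max: int = 25) -> float:
    """Closed-form BD transition matrix vs. the matrix exponential of the generator."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(10):
        lam, t = float(rng.uniform(0.1, 1.5)), float(rng.uniform(0.1, 2.0))
        big = 4 * n_max  # generous truncation for the generator
        Q = np.zeros((big + 1, big + 1))
        for n in range(1, big + 1):
            Q[n, n - 1] = lam * n
            if n + 1 <= big:
                Q[n, n + 1] = lam * n
            Q[n, n] = -Q[n].sum()
        P_exp = expm(Q)[: n_max + 1, : n_max + 1]
        P = bd_transition_matrix(n_max, t=t, lam=lam)
        # the generator needs t folded in
        P_exp = expm(Q * t)[: n_max + 1, : n_max + 1]
        worst = max(worst, float(np.abs(P - P_exp).max()))
    return worst


def bd_row_sum_max_dev(max_s: int = 10, a_max: float = 0.45) -> float:
    """Max |1 - sum_c P(c | s)| for s <= max_s with generous truncation."""
    worst = 0.0
    for a in np.linspace(0.05, a_max, 9):
        lam_t = a / (1 - a)  # lambda * t giving this a
        for s in range(1, max_s + 1):
            total = sum(bd_transition_prob(s, c, 1.0, lam_t) for c in range(0, 600))
            worst = max(worst, abs(1 - total))
    return worst


# ----------------------------------------------------------------------
# recovery and calibration
# ----------------------------------------------------------------------


def er_sym_identity(seed: int = 0, n_datasets: int = 20) -> tuple[float, float]:
    """Max |lnL(ER) - lnL(SYM)| and |AICc difference| over binary datasets."""
    rng = np.random.default_rng(seed)
    tree = elegans_like_tree()
    worst_ll, worst_aicc = 0.0, 0.0
    fixture = make_study_fixture(seed)
    datasets = [fixture.tip_states()]
    for _ in range(n_datasets - 1):
        states = {l: int(rng.integers(2)) for l in tree.tip_labels()}
        if len(set(states.values())) == 2:
            datasets.append(states)
    for ts in datasets:
        fe = fit_mk(tree, ts, "ER")
        fs = fit_mk(tree, ts, "SYM")
        worst_ll = max(worst_ll, abs(fe.loglik - fs.loglik))
        worst_aicc = max(worst_aicc, abs(fe.aicc - fs.aicc))
    return worst_ll, worst_aicc


def ou2_recovery(n_reps: int = 100, seed: int = 0) -> int:
    """How many of n_reps OU2 simulations recover both optima within 2 SE."""
    tree = elegans_like_tree()
    painting = elegans_like_painting(tree)
    truth = {OUTCROSSER: 6.19, SELFER: 2.97}
    ss = np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        spec = SimulationSpec(seed=rep_seed, trait_model="OU", y0=truth[OUTCROSSER])
        trait = simulate_trait(tree, painting, spec)
        fit = fit_model(tree, trait, painting, "OU2")
        ok = all(
            abs(fit.theta[s] - truth[s]) <= 2 * fit.theta_se[s] for s in (OUTCROSSER, SELFER)
        )
        hits += ok
    return hits


def bd_lambda_recovery(
    n_reps: int = 100, seed: int = 0, n_families: int = 500, lam: float = 0.43
) -> int:
    """How many of n_reps birth--death simulations recover lambda within 10%."""
    tree = elegans_like_tree()
    ss = np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        fams = simulate_gene_families(tree, lam, n_families=n_families, seed=rep_seed)
        fit = fit_turnover(tree, fams, n_lambdas=1)
        hits += abs(fit.lambdas[0] - lam) / lam <= 0.10
    return hits


def model_selection_calibration(n_reps: int = 100, seed: int = 0) -> tuple[int, int]:
    """(false OU2 wins under BM, OU2 selections under OU2) over n_reps each.

    'False win' = OU2 beats every other model by more than 2 AICc on
    BM-simulated data; 'selection' = OU2 is within 2 AICc of the best on
    data simulated at the fixture effect size.
    """
    tree = elegans_like_tree()
    painting = elegans_like_painting(tree)
    ss = np.random.SeedSequence(seed)
    false_wins = 0
    detections = 0
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        bm_spec = SimulationSpec(seed=rep_seed, trait_model="BM", y0=5.0, sigma2=2.0)
        trait = simulate_trait(tree, None, bm_spec)
        fits = [fit_model(tree, trait, painting, m) for m in ("BM", "OU1", "OU2")]
        rank = compare_models(fits)
        false_wins += rank.best == "OU2" and rank.margin > 2.0
    for child in ss.spawn(2 * n_reps)[n_reps:]:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        ou_spec = SimulationSpec(seed=rep_seed, trait_model="OU", y0=6.19)
        trait = simulate_trait(tree, painting, ou_spec)
        fits = [fit_model(tree, trait, painting, m) for m in ("BM", "OU1", "OU2")]
        rank = compare_models(fits)
        detections += "OU2" in rank.indistinguishable
    return false_wins, detections


def ancestral_ci_coverage(n_reps: int = 200, seed: int = 0) -> tuple[int, int]:
    """(covered, total) internal-node 95% CI coverage under BM simulation."""
    tree = elegans_like_tree()
    ss = np.random.SeedSequence(seed)
    covered = total = 0
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        spec = SimulationSpec(seed=rep_seed, trait_model="BM", y0=150.0, sigma2=2500.0)
        trait = simulate_trait(tree, None, spec)
        est = reconstruct_ancestral_bm(tree, trait)
        for n in tree.nodes:
            if not n.children:
                continue
            truth = trait.node_values[n.id]
            covered += est.ci_low[n.id] <= truth <= est.ci_high[n.id]
            total += 1
    return covered, total


def pvalue_uniformity_ks(seed: int = 0, n_null: int = 1000, M: int = 1000) -> float:
    """KS distance of Monte-Carlo p-values from uniform under the fitted null."""
    from .turnover import sample_model_families

    fixture = make_study_fixture(seed)
    fit = fit_turnover(fixture.tree, fixture.families, n_lambdas=1)
    rng = np.random.default_rng(seed + 1)
    null = sample_model_families(fit, n_null, seed=int(rng.integers(2**31)))
    null_fit = evaluate_families(fit, null)
    p, _ = family_significance(null_fit, M=M, seed=int(rng.integers(2**31)))
    return float(kstest(p.to_numpy(), "uniform").statistic)


def planted_loss_recovery(
    seed: int = 0,
    n_background: int = 1000,
    n_planted: int = 50,
    root_count: int = 10,
    survival: float = 0.2,
    M: int = 5000,
) -> tuple[int, int]:
    """(recovered, planted) for parallel-loss classification.

    Planted families start from ``root_count`` genes (parallel-loss
    families in this system are typically large) and evolve under the
    background rate with additional binomial thinning (per-gene survival
    ``survival``) on every selfing branch; draws are rejection-sampled
    until the *true* trajectory realizes the parallel-loss pattern (every
    selfing lineage net <= 0 with a loss somewhere, every outcrossing
    lineage net >= 0), so all planted families are genuinely
    DecreasingInSelfers. Recovery = classified DecreasingInSelfers at
    q < 0.01 among a null background.
    """
    import pandas as pd

    from .families import GeneFamilyMatrix
    from .turnover import _classify_nets, lineage_net_changes

    tree = elegans_like_tree()
    painting = elegans_like_painting(tree)
    rng = np.random.default_rng(seed)
    background = simulate_gene_families(
        tree, 0.43, n_families=n_background, seed=int(rng.integers(2**31))
    )
    planted_rows = []
    while len(planted_rows) < n_planted:
        batch = simulate_gene_families(
            tree,
            0.43,
            root_prior=lambda r: root_count,
            n_families=200,
            seed=int(rng.integers(2**31)),
            selfer_loss_survival=survival,
            painting=painting,
            record_node_counts=True,
        )
        for fam in batch.families:
            truth = batch.node_counts.loc[fam].to_dict()
            nets = lineage_net_changes(tree, painting, truth)
            selfer = [d for s, d in nets.values() if s == SELFER]
            outx = [d for s, d in nets.values() if s == OUTCROSSER]
            if _classify_nets(selfer, outx) == "DecreasingInSelfers":
                planted_rows.append(batch.counts.loc[fam])
                if len(planted_rows) == n_planted:
                    break
    planted_counts = pd.DataFrame(planted_rows)
    planted_counts.index = [f"P{i:04d}" for i in range(n_planted)]
    merged = GeneFamilyMatrix(pd.concat([background.counts, planted_counts]))
    fit = fit_turnover(tree, merged, n_lambdas=1)
    p, q = family_significance(fit, M=M, seed=int(rng.integers(2**31)))
    significant = list(q.index[q < 0.01])
    categories = classify_parallel(fit, painting, significant)
    recovered = sum(
        1 for f in planted_counts.index if categories.get(f) == "DecreasingInSelfers"
    )
    return recovered, n_planted
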