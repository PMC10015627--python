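"""Two-state Mk models for reproductive mode: fitting, marginal ancestral
states, and branch regime painting.

The character is binary (0 = outcrosser, 1 = selfer) with a continuous-time
Markov rate matrix constrained as ER (one rate), SYM (symmetric rates) or
ARD (all rates different); for a binary character ER and SYM impose the
same constraint and yield identical likelihood surfaces. Transition
probabilities are closed-form,

    P00(t) = pi0 + pi1 * exp(-(q01 + q10) t),

with pi the stationary weights; likelihoods are computed by pruning over
the tree, and per-node marginal posteriors by a combined upward/downward
(re-rooting) pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .adaptation import aicc
from .painting import OUTCROSSER, RegimePainting
from .tree import Phylogeny

__all__ = [
    "MkFit",
    "mk_transition_matrix",
    "mk_loglik",
    "fit_mk",
    "marginal_ancestral_states",
    "paint_regimes",
]

RATE_LO, RATE_HI = 1e-8, 1e3
NEG_INF = float("-inf")


def mk_transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    if q01 < 0 or q10 < 0 or t < 0:
        raise ValueError("rates and time must be non-negative")
    total = q01 + q10
    if total == 0:
        return np.eye(2)
    pi0, pi1 = q10 / total, q01 / total
    e = math.exp(-total * t)
    return np.array(
        [[pi0 + pi1 * e, pi1 * (1 - e)], [pi0 * (1 - e), pi1 + pi0 * e]]
    )


def _tip_partial(state) -> np.ndarray:
    if state is None:
        return np.ones(2)  # missing data: marginalized out
    return np.array([1.0, 0.0]) if state == 0 else np.array([0.0, 1.0])


def _resolve_prior(root_prior, q01: float, q10: float) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "flat":
            return np.array([0.5, 0.5])
        if root_prior == "stationary":
            total = q01 + q10
            if total == 0:
                return np.array([0.5, 0.5])
            return np.array([q10 / total, q01 / total])
        raise ValueError(f"unknown root prior {root_prior!r}")
    p = np.asarray(root_prior, dtype=float)
    return p / p.sum()


def _down_partials(
    tree: Phylogeny, tip_states: dict[str, int | None], q01: float, q10: float
) -> dict[int, np.ndarray]:
    """Partial likelihood of the data below each node, given its state."""
    down: dict[int, np.ndarray] = {}
    for n in tree.postorder():
        if not n.children:
            down[n.id] = _tip_partial(tip_states.get(n.label))
        else:
            part = np.ones(2)
            for c in n.children:
                P = mk_transition_matrix(q01, q10, tree.nodes[c].length)
                part = part * (P @ down[c])
            down[n.id] = part
    return down


def mk_loglik(
    tree: Phylogeny,
    tip_states: dict[str, int | None],
    q01: float,
    q10: float,
    root_prior="flat",
) -> float:
    """Log-likelihood of tip states under the 2-state Mk model (pruning).

    Missing tips contribute a partial likelihood of (1, 1). An impossible
    pattern (e.g. both rates 0 with discordant tips) returns -inf.
    """
    prior = _resolve_prior(root_prior, q01, q10)
    down = _down_partials(tree, tip_states, q01, q10)
    lik = float(prior @ down[tree.root])
    return math.log(lik) if lik > 0 else NEG_INF


@dataclass
class MkFit:
    model: str  # ER | SYM | ARD
    q01: float
    q10: float
    loglik: float
    k: int
    aicc: float
    root_prior: str = "flat"
    marginals: dict[int, np.ndarray] = field(default_factory=dict)
    at_bound: bool = False

    @property
    def rate_matrix(self) -> np.ndarray:
        return np.array([[-self.q01, self.q01], [self.q10, -self.q10]])


def fit_mk(
    tree: Phylogeny,
    tip_states: dict[str, int | None],
    model: str = "ER",
    root_prior: str = "flat",
) -> MkFit:
    """Maximum-likelihood rates under ER/SYM/ARD, with AICc (n = tips).

    Bounded optimization over [1e-8, 1e3] in log-rate space from three
    deterministic start points; for a binary character ER and SYM coincide
    (k = 1), ARD has k = 2.
    """
    if model not in {"ER", "SYM", "ARD"}:
        raise ValueError(f"unknown Mk model {model!r}")
    k = 2 if model == "ARD" else 1
    n = tree.n_tips
    observed = {s for s in tip_states.values() if s is not None}
    if len(observed) < 2:
        warnings.warn("all observed tips share one state; rate estimate at lower bound")

    def unpack(x: np.ndarray) -> tuple[float, float]:
        rates = np.exp(x)
        return (rates[0], rates[0]) if k == 1 else (rates[0], rates[1])

    def nll(x: np.ndarray) -> float:
        ll = mk_loglik(tree, tip_states, *unpack(x), root_prior)
        return 1e10 if ll == NEG_INF else -ll

    height = tree.height()
    bounds = [(math.log(RATE_LO), math.log(RATE_HI))] * k
    best = None
    for q0 in (0.1 / height, 1.0 / height, 10.0 / height):
        x0 = np.full(k, math.log(min(max(q0, RATE_LO), RATE_HI)))
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    q01, q10 = unpack(best.x)
    ll = -best.fun
    at_bound = bool(np.any(np.isclose(best.x, bounds[0][0])) or np.any(np.isclose(best.x, bounds[0][1])))
    fit = MkFit(model, q01, q10, ll, k, aicc(ll, k, n), root_prior, at_bound=at_bound)
    fit.marginals = marginal_ancestral_states(fit, tree, tip_states)
    return fit


def marginal_ancestral_states(
    fit: MkFit, tree: Phylogeny, tip_states: dict[str, int | None]
) -> dict[int, np.ndarray]:
    """Per-node marginal posterior P(state | all tip data).

    Upward pass: partial likelihood of the subtree below each node.
    Downward pass: likelihood of everything outside the subtree, seeded
    with the root prior. Observed tips return a point mass.
    """
    q01, q10 = fit.q01, fit.q10
    prior = _resolve_prior(fit.root_prior, q01, q10)
    down = _down_partials(tree, tip_states, q01, q10)
    up: dict[int, np.ndarray] = {tree.root: prior.copy()}
    for n in tree.preorder():
        for c in n.children:
            sib = np.ones(2)
            for b in n.children:
                if b != c:
                    Pb = mk_transition_matrix(q01, q10, tree.nodes[b].length)
                    sib = sib * (Pb @ down[b])
            Pc = mk_transition_matrix(q01, q10, tree.nodes[c].length)
            up[c] = (up[n.id] * sib) @ Pc
    marg: dict[int, np.ndarray] = {}
    for n in tree.nodes:
        if not n.children and tip_states.get(n.label) is not None:
            marg[n.id] = _tip_partial(tip_states[n.label])
            continue
        w = up[n.id] * down[n.id]
        total = w.sum()
        if total <= 0:
            raise ValueError("zero likelihood: data impossible under these rates")
        marg[n.id] = w / total
    return marg


def paint_regimes(
    marginals: dict[int, np.ndarray],
    tree: Phylogeny,
    tip_states: dict[str, int | None] | None = None,
    tie_rule: str = "parent",
    tie_tol: float = 1e-12,
) -> RegimePainting:
    """Discretize marginals to a branch painting by child-node argmax.

    A branch takes the most probable state of its child node; observed tip
    branches always match the observed state. Exact ties follow the
    parent's state (resolved root-down); a root tie falls to outcrosser.
    All ties are flagged.
    """
    if tie_rule not in {"parent", "outcrosser"}:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    ties: set[int] = set()

    def argmax(node_id: int, parent_state: int | None) -> int:
        p = marginals[node_id]
        if abs(p[0] - p[1]) <= tie_tol:
            ties.add(node_id)
            if tie_rule == "outcrosser" or parent_state is None:
                return OUTCROSSER
            return parent_state
        return int(np.argmax(p))

    node_state: dict[int, int] = {}
    states: dict[int, int] = {}
    for n in tree.preorder():
        parent_state = node_state.get(n.parent) if n.parent is not None else None
        s = argmax(n.id, parent_state)
        if (
            not n.children
            and tip_states is not None
            and tip_states.get(n.label) is not None
        ):
            s = tip_states[n.label]
        node_state[n.id] = s
        if n.parent is not None:
            states[n.id] = s
    return RegimePainting(states, node_state[tree.root], provenance="argmax marginal", ties=ties)
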