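"""Brownian-motion and Ornstein--Uhlenbeck adaptation models on a painted tree.

The trait follows dy = -alpha (y - theta) dt + sigma dW, with the primary
optimum theta depending on the branch regime (Hansen's framework: one
optimum per niche, here selfing vs outcrossing). Three nested hypotheses
are fit and compared by AICc:

* BM  — no pull (alpha = 0): a single ancestral mean, variance sigma^2 t;
* OU1 — one global optimum theta;
* OU2 — separate selfer and outcrosser optima.

Tip expectations accumulate exp(-alpha ...) weights over the
constant-regime segments of each root-to-tip path; tip covariances are
v * exp(-alpha (T_i - d_a)) * exp(-alpha (T_j - d_a)) * (1 - exp(-2 alpha d_a))
with d_a the MRCA depth and v = sigma^2 / (2 alpha) the stationary
variance — valid on non-ultrametric trees. By default the root value is
tied to the root regime's optimum (no extra parameter), so k = 2/3/4;
``y0_rule='estimate'`` frees it. Alpha is profiled by a deterministic
log-grid over the phylogenetic half-life t1/2 = ln 2 / alpha with
golden-section refinement; optima and the stationary variance are profiled
analytically by GLS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .painting import RegimePainting
from .traits import TraitTable
from .tree import Phylogeny, root_to_tip_segments

__all__ = [
    "aicc",
    "ou_moments",
    "model_loglik",
    "fit_model",
    "compare_models",
    "derived_quantities",
    "ModelFit",
    "ModelScore",
    "ModelRanking",
]

AICC_RULE = 2.0  # models within 2 AICc units are indistinguishable
_GRID_POINTS = 50
_THALF_RANGE = (1e-4, 10.0)  # x tree height


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: 2k - 2 lnL + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return 2 * k - 2 * loglik + 2 * k * (k + 1) / (n - k - 1)


def derived_quantities(
    alpha: float, sigma2: float, tree_height: float | None = None
) -> dict[str, float]:
    """Phylogenetic half-life t1/2 = ln2/alpha and stationary variance v = sigma^2/(2 alpha)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    out = {"t_half": math.log(2) / alpha, "v": sigma2 / (2 * alpha)}
    if tree_height is not None:
        out["t_half_pct_height"] = 100.0 * out["t_half"] / tree_height
    return out


# -- moments ------------------------------------------------------------


def _mrca_depths(tree: Phylogeny, labels: list[str]) -> np.ndarray:
    d = tree.depths()
    ids = [tree.tip_id(l) for l in labels]
    n = len(ids)
    M = np.empty((n, n))
    for i in range(n):
        M[i, i] = d[ids[i]]
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = d[tree.mrca(ids[i], ids[j])]
    return M


def ou_moments(
    tree: Phylogeny, painting: RegimePainting, alpha: float
) -> tuple[np.ndarray, list, np.ndarray, list[str]]:
    """OU tip expectation weights and unit covariance.

    Returns ``(W, columns, V0, labels)``: row i of W gives tip i's weights
    over columns ["y0", theta_state...]; rows sum to 1. V0 is the tip
    covariance in units of the stationary variance v.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    labels = tree.tip_labels()
    states = sorted(painting.states_present())
    cols: list = ["y0"] + [("theta", s) for s in states]
    col_index = {c: i for i, c in enumerate(cols)}
    depths = tree.depths()
    W = np.zeros((len(labels), len(cols)))
    for i, lab in enumerate(labels):
        T = depths[tree.tip_id(lab)]
        W[i, 0] = math.exp(-alpha * T)
        for seg in root_to_tip_segments(tree, painting, lab):
            w = math.exp(-alpha * (T - seg.end)) - math.exp(-alpha * (T - seg.start))
            W[i, col_index[("theta", seg.state)]] += w
    M = _mrca_depths(tree, labels)
    T = np.diag(M).copy()
    V0 = np.exp(-alpha * (T[:, None] - M)) * np.exp(-alpha * (T[None, :] - M)) * (
        1.0 - np.exp(-2.0 * alpha * M)
    )
    np.fill_diagonal(V0, 1.0 - np.exp(-2.0 * alpha * T))
    return W, cols, V0, labels


def _check_nonsingular(C: np.ndarray, labels: list[str]) -> None:
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if C[i, i] + C[j, j] - 2 * C[i, j] <= 0:
                raise ValueError(
                    f"singular trait covariance: tips {labels[i]!r} and {labels[j]!r} "
                    "are at zero patristic distance"
                )


def _gauss_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    L = np.linalg.cholesky(cov)
    z = np.linalg.solve(L, y - mean)
    return float(
        -0.5 * len(y) * math.log(2 * math.pi)
        - np.log(np.diag(L)).sum()
        - 0.5 * z @ z
    )


def model_loglik(
    tree: Phylogeny,
    trait: TraitTable,
    painting: Optional[RegimePainting],
    model: str,
    *,
    alpha: float | None = None,
    v: float | None = None,
    theta=None,
    sigma2: float | None = None,
    mu: float | None = None,
    y0: float | None = None,
    y0_rule: str = "root-regime",
) -> float:
    """Exact Gaussian log-density of the tip vector under BM/OU1/OU2.

    BM takes ``sigma2`` and ``mu``; OU1 takes scalar ``theta``; OU2 takes a
    state->theta mapping. Under the default y0 rule the root value equals
    the root regime's optimum; with ``y0_rule='estimate'`` pass ``y0``.
    """
    labels = tree.tip_labels()
    y = np.array(trait.vector(labels))
    if model == "BM":
        if sigma2 is None or mu is None:
            raise ValueError("BM requires sigma2 and mu")
        C = _mrca_depths(tree, labels)
        _check_nonsingular(C, labels)
        return _gauss_loglik(y, np.full(len(y), mu), sigma2 * C)
    if model not in {"OU1", "OU2"}:
        raise ValueError(f"unknown model {model!r}")
    if alpha is None or alpha <= 0 or v is None:
        raise ValueError("OU requires alpha > 0 and v")
    if painting is None:
        raise ValueError("OU requires a regime painting")
    if model == "OU1":
        theta_map = {s: float(theta) for s in painting.states_present()}
    else:
        theta_map = dict(theta)
    W, cols, V0, labels = ou_moments(tree, painting, alpha)
    _check_nonsingular(V0, labels)
    if y0_rule == "root-regime":
        y0_val = theta_map[painting.root_state]
    elif y0_rule == "estimate":
        if y0 is None:
            raise ValueError("y0_rule='estimate' requires y0")
        y0_val = float(y0)
    else:
        raise ValueError(f"unknown y0 rule {y0_rule!r}")
    params = np.array([y0_val] + [theta_map[c[1]] for c in cols[1:]])
    return _gauss_loglik(y, W @ params, v * V0)


# -- fitting ------------------------------------------------------------


@dataclass
class ModelFit:
    model: str
    loglik: float
    k: int
    n: int
    aicc: float
    alpha: float | None = None
    sigma2: float | None = None
    v: float | None = None
    t_half: float | None = None
    t_half_pct_height: float | None = None
    theta: dict | None = None  # state -> optimum (OU2) / {"global": ...} (OU1)
    theta_se: dict | None = None
    mu: float | None = None  # BM ancestral mean
    r2: float = 0.0
    y0_rule: str = "root-regime"
    at_boundary: bool = False


def _gls(y, X, V):
    """GLS through a cholesky whitening; returns (beta, rss, tss, XtVinvX_inv)."""
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    r = yw - Xw @ beta
    rss = float(r @ r)
    ones_w = np.linalg.solve(L, np.ones(len(y)))
    ybar = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float((yw - ybar * ones_w) @ (yw - ybar * ones_w))
    return beta, rss, tss, np.linalg.inv(XtX), L

def _ou_design(tree, painting, alpha, y0_rule):
    W, cols, V0, labels = ou_moments(tree, painting, alpha)
    states = [c[1] for c in cols[1:]]
    if y0_rule == "root-regime":
        X = W[:, 1:].copy()
        X[:, states.index(painting.root_state)] += W[:, 0]
        return X, states, V0, labels, False
    return W, states, V0, labels, True


def _ou_profile(tree, y, painting, alpha, y0_rule, collapse_ou1):
    X, states, V0, labels, has_y0 = _ou_design(tree, painting, alpha, y0_rule)
    if collapse_ou1:
        if has_y0:
            X = np.hstack([X[:, :1], X[:, 1:].sum(axis=1, keepdims=True)])
            states = ["global"]
        else:
            X = X.sum(axis=1, keepdims=True)
            states = ["global"]
    _check_nonsingular(V0, labels)
    n = len(y)
    beta, rss, tss, XtXinv, L = _gls(y, X, V0)
    v_hat = rss / n
    loglik = (
        -0.5 * n * math.log(2 * math.pi * v_hat)
        - np.log(np.diag(L)).sum()
        - 0.5 * n
    )
    return loglik, beta, v_hat, rss, tss, XtXinv, states, has_y0


def fit_model(
    tree: Phylogeny,
    trait: TraitTable,
    painting: Optional[RegimePainting],
    model: str,
    y0_rule: str = "root-regime",
) -> ModelFit:
    """Maximum-likelihood fit of BM, OU1 or OU2 with AICc (n = tips).

    Alpha is profiled over a 50-point log grid of half-lives spanning
    [1e-4, 10] tree heights with golden-section refinement; theta (and y0
    if freed) by GLS and v by the profiled residual variance. Standard
    errors of the optima come from the inverse GLS information scaled by
    v-hat; r^2 is 1 - RSS/TSS in the GLS metric. A fit whose half-life
    lands on the grid boundary is flagged.
    """
    labels = tree.tip_labels()
    n = len(labels)
    if n < 6:
        raise ValueError("model fitting requires at least 6 tips")
    trait.validate(tree)
    if set(labels) - set(trait.values):
        raise ValueError("every tip needs a trait value")
    y = np.array(trait.vector(labels))
    height = tree.height()

    if model == "BM":
        C = _mrca_depths(tree, labels)
        _check_nonsingular(C, labels)
        Cinv_1 = np.linalg.solve(C, np.ones(n))
        denom = float(np.ones(n) @ Cinv_1)
        mu = float(y @ Cinv_1) / denom
        r = y - mu
        q = float(r @ np.linalg.solve(C, r))
        sigma2 = q / n  # ML within the AICc comparison
        sign, logdet = np.linalg.slogdet(C)
        loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
        k = 2
        return ModelFit("BM", loglik, k, n, aicc(loglik, k, n), sigma2=sigma2, mu=mu, r2=0.0)

    if model not in {"OU1", "OU2"}:
        raise ValueError(f"unknown model {model!r}")
    if painting is None:
        raise ValueError("OU fitting requires a regime painting")
    if model == "OU2" and len(painting.states_present()) < 2:
        raise ValueError("OU2 requires both regimes present in the painting")
    collapse = model == "OU1"

    def profile(log_thalf: float) -> float:
        alpha = math.log(2) / math.exp(log_thalf)
        return _ou_profile(tree, y, painting, alpha, y0_rule, collapse)[0]

    lo = math.log(_THALF_RANGE[0] * height)
    hi = math.log(_THALF_RANGE[1] * height)
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = [profile(g) for g in grid]
    best = int(np.argmax(vals))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, _GRID_POINTS - 1)]
    gr = (math.sqrt(5) - 1) / 2
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = profile(c), profile(d)
    for _ in range(60):
        if b - a < 1e-10:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = profile(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = profile(d)
    log_thalf = (a + b) / 2
    at_boundary = best in (0, _GRID_POINTS - 1)
    if at_boundary:
        warnings.warn(f"{model} half-life at grid boundary; fit flagged")
    alpha = math.log(2) / math.exp(log_thalf)
    loglik, beta, v_hat, rss, tss, XtXinv, states, has_y0 = _ou_profile(
        tree, y, painting, alpha, y0_rule, collapse
    )
    # reported v and optima SEs use the unbiased GLS residual variance
    # (rss / residual df); the ML profile v_hat stays inside the likelihood
    p_reg = XtXinv.shape[0]
    v_gls = rss / max(n - p_reg, 1)
    se = np.sqrt(np.maximum(np.diag(XtXinv) * v_gls, 0.0))
    offset = 1 if has_y0 else 0
    theta = {s: float(beta[offset + i]) for i, s in enumerate(states)}
    theta_se = {s: float(se[offset + i]) for i, s in enumerate(states)}
    k = (2 if collapse else 3) + 1 + offset  # alpha, v, optima(, y0)
    dq = derived_quantities(alpha, 2 * alpha * v_gls, height)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return ModelFit(
        model,
        loglik,
        k,
        n,
        aicc(loglik, k, n),
        alpha=alpha,
        sigma2=2 * alpha * v_gls,
        v=v_gls,
        t_half=dq["t_half"],
        t_half_pct_height=dq["t_half_pct_height"],
        theta=theta,
        theta_se=theta_se,
        r2=r2,
        y0_rule=y0_rule,
        at_boundary=at_boundary,
    )


# -- model comparison ---------------------------------------------------


@dataclass
class ModelScore:
    """A bare (model, AICc) record, e.g. a printed table row."""

    model: str
    aicc: float
    k: int = 0


_DEFAULT_K = {"BM": 2, "OU1": 3, "OU2": 4}


@dataclass
class ModelRanking:
    order: list  # fits/scores sorted by AICc (ties: simpler model first)
    delta: dict[str, float]  # model -> AICc - best AICc
    indistinguishable: list[str]  # within AICC_RULE of the best

    @property
    def best(self) -> str:
        return self.order[0].model

    @property
    def margin(self) -> float:
        """AICc margin of the best model over the runner-up."""
        if len(self.order) < 2:
            return math.inf
        return self.order[1].aicc - self.order[0].aicc


def compare_models(fits: Sequence) -> ModelRanking:
    """Rank fits by AICc; ties sort the simpler model (fewest k) first.

    The 'indistinguishable' set holds every model within 2 AICc units of
    the best — the conventional threshold for a meaningful difference.
    """
    def key(f):
        return (f.aicc, getattr(f, "k", 0) or _DEFAULT_K.get(f.model, 0))

    order = sorted(fits, key=key)
    best = order[0].aicc
    delta = {f.model: f.aicc - best for f in order}
    indist = [f.model for f in order if f.aicc - best <= AICC_RULE]
    return ModelRanking(order, delta, indist)
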