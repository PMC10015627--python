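"""Brownian-motion ancestral reconstruction of continuous traits with REML.

The trait (e.g. genome size in Mb) evolves by Brownian motion on the tree:
tip covariances equal sigma^2 times the shared root-to-MRCA depth. The
diffusion rate sigma^2 is estimated by restricted maximum likelihood
(free of the bias from estimating the root mean), for which the BM model
has a closed form: the GLS residual quadratic form divided by (n - 1),
equivalently the mean squared standardized independent contrast. Node
states are the GLS conditional expectations given the tips, with a flat
prior on the root value; 95% intervals use the normal 1.96 multiplier and
condition on the REML rate estimate.

Trees need not be ultrametric (branch lengths may be substitutions/site).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .traits import TraitTable
from .tree import Phylogeny

__all__ = ["AncestralEstimate", "bm_covariance", "bm_sigma2_reml", "reconstruct_ancestral_bm"]

_CI_MULT = 1.96
_ZERO_FLOOR = 1e-12


def bm_covariance(tree: Phylogeny, labels: list[str]) -> np.ndarray:
    """Unit-rate BM tip covariance: shared depth of each tip pair.

    Tips at zero patristic distance (grafted strains on length-0 branches)
    would make this singular; their diagonal is floored up by 1e-12 and a
    warning raised.
    """
    d = tree.depths()
    ids = [tree.tip_id(l) for l in labels]
    n = len(ids)
    C = np.empty((n, n))
    for i in range(n):
        C[i, i] = d[ids[i]]
        for j in range(i + 1, n):
            C[i, j] = C[j, i] = d[tree.mrca(ids[i], ids[j])]
    floored = False
    for i in range(n):
        for j in range(i + 1, n):
            if C[i, i] + C[j, j] - 2 * C[i, j] <= 0:
                C[i, i] += _ZERO_FLOOR
                C[j, j] += _ZERO_FLOOR
                floored = True
    if floored:
        warnings.warn("tips at zero patristic distance; 1e-12 variance floor applied")
    return C


def bm_sigma2_reml(tree: Phylogeny, trait: TraitTable) -> tuple[float, float]:
    """REML estimate of the BM rate and the restricted log-likelihood at it."""
    trait.validate(tree)
    labels = [l for l in tree.tip_labels() if l in trait.values]
    n = len(labels)
    if n < 3:
        if n < 2:
            raise ValueError("need at least 2 tips with data")
        warnings.warn("fewer than 3 tips with data; REML uses a single contrast")
    y = np.array(trait.vector(labels))
    C = bm_covariance(tree, labels)
    Cinv_y = np.linalg.solve(C, y)
    Cinv_1 = np.linalg.solve(C, np.ones(n))
    denom = float(np.ones(n) @ Cinv_1)
    mu = float(np.ones(n) @ Cinv_y) / denom
    r = y - mu
    q = float(r @ np.linalg.solve(C, r))
    sigma2 = q / (n - 1)
    scale = float(np.mean(y * y)) + 1.0
    if sigma2 <= 1e-14 * scale:  # numerically constant trait
        warnings.warn("trait is constant; sigma^2 = 0")
        return 0.0, math.inf
    sign, logdetC = np.linalg.slogdet(C)
    loglik = -0.5 * (
        (n - 1) * math.log(2 * math.pi * sigma2) + logdetC + math.log(denom) + q / sigma2
    )
    return sigma2, loglik


@dataclass
class AncestralEstimate:
    """Per-node mean, variance and 95% CI, plus the REML rate behind them."""

    means: dict[int, float]
    variances: dict[int, float]
    ci_low: dict[int, float]
    ci_high: dict[int, float]
    sigma2: float
    loglik_restricted: float


def reconstruct_ancestral_bm(tree: Phylogeny, trait: TraitTable) -> AncestralEstimate:
    """GLS ancestral states under BM with sigma^2 from REML.

    Node mean: mu_hat + C_aY C_YY^{-1} (y - mu_hat 1); node variance adds
    the root-mean uncertainty term h^2 / (1' C^{-1} 1) with
    h = 1 - C_aY C^{-1} 1 (universal-kriging form), so the 2-tip root
    variance is sigma^2 / sum(1/t_i). Tips have variance 0.
    """
    trait.validate(tree)
    labels = [l for l in tree.tip_labels() if l in trait.values]
    missing = set(tree.tip_labels()) - set(labels)
    if missing:
        raise ValueError(f"tips without trait data: {sorted(missing)}")
    y = np.array(trait.vector(labels))
    n = len(labels)
    C = bm_covariance(tree, labels)
    sigma2, loglik = bm_sigma2_reml(tree, trait)
    Cinv_1 = np.linalg.solve(C, np.ones(n))
    denom = float(np.ones(n) @ Cinv_1)
    mu = float(y @ Cinv_1) / denom
    resid = y - mu

    depths = tree.depths()
    tip_ids = [tree.tip_id(l) for l in labels]
    means, variances, lo, hi = {}, {}, {}, {}
    for node in tree.nodes:
        if not node.children:
            val = trait.values[node.label]
            means[node.id], variances[node.id] = val, 0.0
            lo[node.id] = hi[node.id] = val
            continue
        cross = np.array([depths[tree.mrca(node.id, t)] for t in tip_ids])
        w = np.linalg.solve(C, cross)
        mean = mu + float(w @ resid)
        h = 1.0 - float(w @ np.ones(n))
        var_unit = depths[node.id] - float(w @ cross) + h * h / denom
        var = sigma2 * max(var_unit, 0.0)
        means[node.id], variances[node.id] = mean, var
        half = _CI_MULT * math.sqrt(var)
        lo[node.id], hi[node.id] = mean - half, mean + half
    return AncestralEstimate(means, variances, lo, hi, sigma2, loglik)
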