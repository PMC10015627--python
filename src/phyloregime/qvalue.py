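"""Storey q-values with a Benjamini-Hochberg fallback.

pi0 (the null proportion) is estimated on the usual lambda grid
0.05..0.95 and smoothed with a cubic fit evaluated at the largest lambda;
if the estimate is unstable (outside (0, 1]) the procedure falls back to
BH, i.e. pi0 = 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["estimate_pi0", "qvalues"]

_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    p = np.asarray(p, dtype=float)
    m = len(p)
    raw = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
    if np.allclose(raw, raw[0]):
        pi0 = float(raw[0])
    else:
        coef = np.polyfit(lambdas, raw, 3)
        pi0 = float(np.polyval(coef, lambdas[-1]))
    if not (0 < pi0 <= 1):
        return 1.0  # BH fallback
    return pi0


def qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Monotone FDR-adjusted q-values; q_i = min over j>=i of pi0*m*p_j/j."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p)
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
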