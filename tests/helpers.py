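"""Independent oracles used by the test suite.

These deliberately re-derive quantities from first principles (normal
equations, explicit RSS ratios, grid-search likelihood maximisation, regex
parsing) so they share no code path with the package implementation.
"""

from __future__ import annotations

import math
import re

import numpy as np
from scipy import stats


def ols_oracle(X: np.ndarray, y: np.ndarray):
    """OLS by explicit normal equations: coef, se, t, two-sided p, rss."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, rss, df


def partial_f_oracle(rss_reduced: float, rss_full: float, q: int, df_full: int):
    """Nested-model F test from explicit RSS ratio."""
    f = ((rss_reduced - rss_full) / q) / (rss_full / df_full)
    return f, float(stats.f.sf(f, q, df_full))


def hwe_grid_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """HWE G statistic via grid-search maximisation of the HWE likelihood.

    2 * (saturated multinomial log-likelihood - max over allele frequency of
    the HWE-constrained log-likelihood), maximised on a coarse grid refined
    around its argmax.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    n = counts.sum()

    def hwe_loglik(p):
        probs = np.stack([p * p, 2 * p * (1 - p), (1 - p) ** 2])
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = counts[:, None] * np.log(probs)
        ll[np.broadcast_to(counts[:, None] == 0, ll.shape)] = 0.0
        return ll.sum(axis=0)

    grid = np.linspace(1e-9, 1 - 1e-9, 20_001)
    ll = hwe_loglik(grid)
    best = grid[np.argmax(ll)]
    lo = max(best - 1e-4, 1e-12)
    hi = min(best + 1e-4, 1 - 1e-12)
    fine = np.linspace(lo, hi, 20_001)
    max_hwe = hwe_loglik(fine).max()

    saturated = sum(c * math.log(c / n) for c in counts if c > 0)
    return max(2.0 * (saturated - max_hwe), 0.0)


_DOT_EDGE = re.compile(r'^\s*"([^"]+)"\s*->\s*"([^"]+)"\s*\[(.*)\];\s*$')


def parse_dot(text: str):
    """Recover (directed, undirected) edge sets from exported DOT."""
    directed, undirected = set(), set()
    for line in text.splitlines():
        m = _DOT_EDGE.match(line)
        if not m:
            continue
        src, dst, attrs = m.groups()
        if "dir=none" in attrs:
            undirected.add(tuple(sorted((src, dst))))
        else:
            directed.add((src, dst))
    return directed, undirected
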