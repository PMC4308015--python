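"""Independent oracles used by the test suite.

Each function here recomputes a quantity the package produces through a
deliberately different route — exhaustive enumeration over hidden states,
explicit normal equations, brute-force cumulative mass — so agreement is a
genuine cross-check rather than the same code run twice.
"""
from __future__ import annotations

import itertools

import numpy as np

F2_PRIOR = np.array([0.25, 0.5, 0.25])


def haldane(d_cm: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def transition(r: float) -> np.ndarray:
    one = 1.0 - r
    return np.array([
        [one**2, 2 * r * one, r**2],
        [r * one, one**2 + r**2, r * one],
        [r**2, 2 * r * one, one**2]])


def enumerate_genoprob(grid_positions, observed, error_prob=0.0,
                       cm_per_mb=1.0):
    """Exhaustive-marginalization genotype probabilities.

    ``grid_positions``: ordered loci (markers and pseudomarkers alike);
    ``observed``: dict {grid index: genotype code 0/1/2}.  Enumerates all
    3^L hidden configurations, weighting each by the F2 prior, the Haldane
    transition products and the emission model, and returns the (L, 3)
    marginal distribution.  Only usable for small L.
    """
    pos = np.asarray(grid_positions, dtype=float)
    L = len(pos)
    rs = [haldane((pos[i + 1] - pos[i]) * cm_per_mb) for i in range(L - 1)]
    ts = [transition(r) for r in rs]

    def emit(i, state):
        if i not in observed:
            return 1.0
        if observed[i] == state:
            return 1.0 - error_prob
        return error_prob / 2.0

    marg = np.zeros((L, 3))
    for config in itertools.product(range(3), repeat=L):
        w = F2_PRIOR[config[0]] * emit(0, config[0])
        for i in range(1, L):
            w *= ts[i - 1][config[i - 1], config[i]] * emit(i, config[i])
        for i, s in enumerate(config):
            marg[i, s] += w
    return marg / marg.sum(axis=1, keepdims=True)


def ols_rss(x: np.ndarray, y: np.ndarray):
    """RSS and coefficients via explicit normal equations."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), beta


def hk_lod_oracle(y, xa, xd, covariates=None):
    """Two explicit regressions; LOD = (n/2) log10(RSS0/RSS1)."""
    n = len(y)
    base = [np.ones(n)]
    if covariates is not None:
        base.extend(np.atleast_2d(np.asarray(covariates, float).T))
    rss0, _ = ols_rss(np.column_stack(base), y)
    rss1, beta = ols_rss(np.column_stack(base + [xa, xd]), y)
    lod = 0.5 * n * np.log10(rss0 / rss1)
    return max(lod, 0.0), float(beta[-2]), float(beta[-1])


def bayes_interval_oracle(positions, lod, prob=0.95):
    """Brute-force cumulative-mass credible set (no marker expansion)."""
    w = 10.0 ** (np.asarray(lod, float) - np.max(lod))
    w = w / w.sum()
    items = sorted(range(len(w)), key=lambda i: (-w[i], positions[i]))
    acc, mass = [], 0.0
    for i in items:
        acc.append(i)
        mass += w[i]
        if mass >= prob - 1e-12:
            break
    sel = np.asarray(positions)[acc]
    return float(sel.min()), float(sel.max()), len(acc)


def chi2_121(counts):
    """Hand 1:2:1 chi-square."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    expected = n * np.array([0.25, 0.5, 0.25])
    return float(np.sum((counts - expected) ** 2 / expected))
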