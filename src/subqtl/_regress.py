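"""Vectorized least-squares kernels for the scan code.

Everything here is plain linear algebra organised for speed: the scans add
the same two Haley-Knott regressors (an additive score and a dominance
score) to a fixed base model at hundreds of grid positions, so the base
model is reduced to an orthonormal basis once and each position costs a
couple of rank-2 updates.  The position-wise problems are solved through
the Frisch-Waugh projection, which also yields the additive/dominance
coefficients of the full model directly.
"""
from __future__ import annotations

import numpy as np

_RTOL = 1e-10

#: a column whose projected sum of squares falls below this fraction of the
#: scale expected of a segregating score column (norm ~ n) is considered
#: non-segregating at that position
INFO_RTOL = 1e-4


def orthonormal_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of ``x`` (rank-safe, via SVD)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return u[:, :0]
    return u[:, s > s[0] * _RTOL]


def residualize(q: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Project ``x`` onto the orthogonal complement of span(q)."""
    return x - q @ (q.T @ x)


def pair_scan(q: np.ndarray, y: np.ndarray, xa: np.ndarray, xd: np.ndarray):
    """Add columns (xa_p, xd_p) to the base model span(q), per position.

    ``xa``/``xd`` are (n, P).  Returns ``(rss0, rss1, a, d)`` where ``rss0``
    is the base-model residual sum of squares, ``rss1[p]`` the RSS of the
    augmented model at position p, and ``a``/``d`` the fitted coefficients
    of the added columns.  Degenerate positions (monomorphic, or additive
    and dominance scores collinear) fall back to the best single informative
    column, or to the base model when neither column adds information.
    """
    y = np.asarray(y, dtype=float)
    r = y - q @ (q.T @ y)
    rss0 = float(r @ r)
    ra = residualize(q, xa)
    rd = residualize(q, xd)
    aa = np.einsum("np,np->p", ra, ra)
    dd = np.einsum("np,np->p", rd, rd)
    ad = np.einsum("np,np->p", ra, rd)
    ay = ra.T @ r
    dy = rd.T @ r

    # informativeness is judged against the scale of a genuinely
    # segregating score column (sum of squares of order n), never against
    # the projected values themselves: this guards fixed-background
    # congenic markers, where the genotyping-error model leaks vanishing
    # variation from neighbours into otherwise constant columns
    n = xa.shape[0]
    na = np.maximum(np.einsum("np,np->p", xa, xa), 0.01 * n)
    nd = np.maximum(np.einsum("np,np->p", xd, xd), 0.01 * n)
    info_a = aa > INFO_RTOL * na
    info_d = dd > INFO_RTOL * nd
    det = aa * dd - ad * ad
    ok = info_a & info_d & (det > 1e-10 * aa * dd)
    a = np.zeros_like(aa)
    d = np.zeros_like(aa)
    red = np.zeros_like(aa)
    with np.errstate(divide="ignore", invalid="ignore"):
        a[ok] = (dd[ok] * ay[ok] - ad[ok] * dy[ok]) / det[ok]
        d[ok] = (aa[ok] * dy[ok] - ad[ok] * ay[ok]) / det[ok]
    red[ok] = a[ok] * ay[ok] + d[ok] * dy[ok]

    bad = ~ok
    if bad.any():
        use_a = bad & info_a
        a[use_a] = ay[use_a] / aa[use_a]
        red[use_a] = ay[use_a] ** 2 / aa[use_a]
        use_d = bad & ~use_a & info_d
        d[use_d] = dy[use_d] / dd[use_d]
        red[use_d] = dy[use_d] ** 2 / dd[use_d]

    red = np.clip(red, 0.0, rss0)
    return rss0, rss0 - red, a, d


def block_scan(q: np.ndarray, y: np.ndarray, added: np.ndarray):
    """Generic k-column variant of :func:`pair_scan`.

    ``added`` is (P, n, k).  Solved through a batched eigendecomposition of
    the projected Gram matrices (a pseudoinverse, so rank-deficient blocks
    are handled).  Returns ``(rss0, rss1, coef)`` with ``coef`` (P, k).
    """
    y = np.asarray(y, dtype=float)
    r = y - q @ (q.T @ y)
    rss0 = float(r @ r)
    qta = np.einsum("nq,pnk->pqk", q, added, optimize=True)
    ares = added - np.einsum("nq,pqk->pnk", q, qta, optimize=True)
    gram = np.einsum("pnk,pnl->pkl", ares, ares, optimize=True)
    b = np.einsum("pnk,n->pk", ares, r, optimize=True)
    w, v = np.linalg.eigh(gram)
    wmax = np.maximum(w[..., -1:], 0.0)
    inv = np.where(w > wmax * 1e-12, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    vtb = np.einsum("pkl,pk->pl", v, b)
    coef = np.einsum("pkl,pl->pk", v, inv * vtb)
    red = np.clip(np.einsum("pk,pk->p", b, coef), 0.0, rss0)
    return rss0, rss0 - red, coef


def lod_from_rss(n: int, rss0, rss1) -> np.ndarray:
    """LOD = (n/2) log10(RSS0/RSS1), clamped at zero.

    A degenerate null (RSS0 = 0, e.g. a constant phenotype) is defined to
    give LOD 0 everywhere.
    """
    rss0 = np.asarray(rss0, dtype=float)
    rss1 = np.asarray(rss1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(rss0 / np.maximum(rss1, 1e-300))
    lod = np.where(rss0 <= 0.0, 0.0, lod)
    return np.maximum(lod, 0.0)


def perm_max_lod(q: np.ndarray, ymat: np.ndarray, xa: np.ndarray,
                 xd: np.ndarray, n: int) -> np.ndarray:
    """Maximum LOD over positions for each column of ``ymat``.

    The workhorse of permutation thresholds: ``ymat`` is (n, n_perm) of
    shuffled phenotypes sharing the regressors, so the position-wise 2x2
    normal equations are solved in closed form for all permutations at once.
    """
    ry = ymat - q @ (q.T @ ymat)
    ra = residualize(q, xa)
    rd = residualize(q, xd)
    aa = np.einsum("np,np->p", ra, ra)[:, None]
    dd = np.einsum("np,np->p", rd, rd)[:, None]
    ad = np.einsum("np,np->p", ra, rd)[:, None]
    na = np.maximum(np.einsum("np,np->p", xa, xa), 0.01 * n)[:, None]
    nd = np.maximum(np.einsum("np,np->p", xd, xd), 0.01 * n)[:, None]
    ay = ra.T @ ry  # (P, m)
    dy = rd.T @ ry
    info_a = aa > INFO_RTOL * na
    info_d = dd > INFO_RTOL * nd
    det = aa * dd - ad * ad
    ok = info_a & info_d & (det > 1e-10 * aa * dd)
    with np.errstate(divide="ignore", invalid="ignore"):
        red2 = (dd * ay**2 - 2.0 * ad * ay * dy + aa * dy**2) / det
        red_a = np.where(info_a, ay**2 / np.maximum(aa, 1e-300), 0.0)
        red_d = np.where(info_d, dy**2 / np.maximum(dd, 1e-300), 0.0)
    red = np.where(ok, red2, np.maximum(red_a, red_d))
    rss0 = np.einsum("nm,nm->m", ry, ry)
    red = np.clip(red, 0.0, rss0[None, :])
    rss1 = np.maximum(rss0[None, :] - red, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(rss0[None, :] / rss1)
    lod = np.where(rss0[None, :] <= 0.0, 0.0, lod)
    return np.maximum(lod, 0.0).max(axis=0)
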