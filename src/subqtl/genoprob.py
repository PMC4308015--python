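"""Conditional genotype probabilities for an F2 intercross.

The genotype sequence of an F2 individual along a chromosome is modelled as
a three-state Markov chain (B, H, C) with stationary distribution
(1/4, 1/2, 1/4) and transition probabilities driven by the Haldane
recombination fraction between adjacent loci.  A forward-backward pass over
the marker lattice gives, at every marker and pseudomarker, the probability
of each genotype conditional on all observed markers of that individual —
the quantities Haley-Knott regression needs.  A forward-filtering /
backward-sampling pass draws whole consistent genotype vectors, which is how
missing genotypes are imputed for composite interval mapping.

Positions are in Mb and converted to cM by a configurable factor
(default 1 cM/Mb), since the study maps over the physical scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cross import (GENO_B, GENO_C, GENO_H, GENO_MISSING, CrossData,
                    CrossValidationError, haldane_r)

#: Stationary F2 genotype frequencies (B, H, C).
F2_PRIOR = np.array([0.25, 0.5, 0.25])


def f2_transition_matrix(r) -> np.ndarray:
    """3x3 genotype transition matrix between two loci at recombination
    fraction ``r``.

    Rows/columns are ordered (B, H, C).  Accepts a scalar or an array of
    fractions; an array input returns a stacked (..., 3, 3) array.  Each row
    sums to 1 and the matrix family is consistent under composition of
    adjacent intervals (the genotype process is Markov).
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    one = 1.0 - r
    t = np.empty(r.shape + (3, 3))
    t[..., 0, 0] = one**2
    t[..., 0, 1] = 2 * r * one
    t[..., 0, 2] = r**2
    t[..., 1, 0] = r * one
    t[..., 1, 1] = one**2 + r**2
    t[..., 1, 2] = r * one
    t[..., 2, 0] = r**2
    t[..., 2, 1] = 2 * r * one
    t[..., 2, 2] = one**2
    return t


@dataclass(eq=False)
class GenoProbGrid:
    """Genotype probabilities on a position grid.

    ``probs`` has shape (n_individuals, n_positions, 3) with the state order
    (B, H, C); every 3-vector is a probability distribution.
    ``marker_index[j]`` is the grid index of map marker ``j``.
    """

    positions: np.ndarray
    probs: np.ndarray
    marker_index: np.ndarray

    @property
    def is_pseudomarker(self) -> np.ndarray:
        mask = np.ones(len(self.positions), dtype=bool)
        mask[self.marker_index] = False
        return mask

    def to_frame(self, ids):
        """Wide per-individual table (debugging aid, not a pipeline format)."""
        import pandas as pd
        n, p, _ = self.probs.shape
        recs = {"id": np.repeat(ids, p),
                "pos_mb": np.tile(self.positions, n),
                "p_B": self.probs[:, :, 0].ravel(),
                "p_H": self.probs[:, :, 1].ravel(),
                "p_C": self.probs[:, :, 2].ravel()}
        return pd.DataFrame(recs)


def build_grid(gmap, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Marker + pseudomarker positions.

    Pseudomarkers are laid every ``step`` Mb anchored at the first marker;
    marker positions are always kept (a pseudomarker landing on a marker is
    merged with it).  ``step = 0`` means markers only.  Grid positions are
    resolved at 1e-6 Mb.
    """
    pos = gmap.positions
    keys = np.round(pos * 1e6).astype(np.int64)
    if step and step > 0:
        k = int(np.floor((pos[-1] - pos[0]) / step + 1e-9))
        grid = pos[0] + step * np.arange(k + 1)
        keys = np.concatenate([keys, np.round(grid * 1e6).astype(np.int64)])
    ukeys = np.unique(keys)
    positions = ukeys / 1e6
    marker_index = np.searchsorted(ukeys, np.round(pos * 1e6).astype(np.int64))
    positions[marker_index] = pos  # keep exact marker coordinates
    return positions, marker_index


def _emission(genotypes_col: np.ndarray, error_prob: float) -> np.ndarray:
    """(n, 3) emission weights for one marker column."""
    n = len(genotypes_col)
    e = np.ones((n, 3))
    for code in (GENO_B, GENO_H, GENO_C):
        rows = genotypes_col == code
        if rows.any():
            e[rows] = error_prob / 2.0
            e[rows, code] = 1.0 - error_prob
    return e


def calc_genoprob(cross: CrossData, step: float = 0.1,
                  error_prob: float = 1e-4,
                  cm_per_mb: float = 1.0) -> GenoProbGrid:
    """Forward-backward conditional genotype probabilities.

    ``error_prob`` is the per-marker genotyping error rate: each observed
    code is emitted from the true genotype with probability
    ``1 - error_prob`` and from either wrong genotype with probability
    ``error_prob / 2``.  A nonzero default guards against observed
    double-recombinant configurations collapsing the likelihood.

    An individual with no observed markers gets the stationary F2
    distribution (1/4, 1/2, 1/4) everywhere.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    positions, marker_index = build_grid(cross.gmap, step)
    n = cross.n
    p = len(positions)
    trans = f2_transition_matrix(
        haldane_r(np.diff(positions) * cm_per_mb))  # (p-1, 3, 3)

    emis: list[np.ndarray | None] = [None] * p
    for j, g in enumerate(marker_index):
        col = cross.genotypes[:, j]
        if np.any(col != GENO_MISSING):
            e = _emission(col, error_prob)
            emis[g] = e if emis[g] is None else emis[g] * e

    alpha = np.empty((n, p, 3))
    a = np.broadcast_to(F2_PRIOR, (n, 3)).copy()
    if emis[0] is not None:
        a = a * emis[0]
        a /= a.sum(axis=1, keepdims=True)
    alpha[:, 0] = a
    for t in range(1, p):
        a = a @ trans[t - 1]
        if emis[t] is not None:
            a = a * emis[t]
            a /= a.sum(axis=1, keepdims=True)
        alpha[:, t] = a

    gamma = alpha  # reuse storage; alpha[:, t] already consumed going back
    b = np.ones((n, 3))
    for t in range(p - 2, -1, -1):
        w = b if emis[t + 1] is None else b * emis[t + 1]
        b = w @ trans[t].T
        b /= b.sum(axis=1, keepdims=True)
        gamma[:, t] = gamma[:, t] * b
    gamma /= gamma.sum(axis=2, keepdims=True)
    return GenoProbGrid(positions, gamma, marker_index)


def impute_missing(cross: CrossData, seed: int | None = None,
                   error_prob: float = 0.0, cm_per_mb: float = 1.0,
                   rng: np.random.Generator | None = None) -> CrossData:
    """Draw one consistent completion of all missing genotypes.

    Uses forward filtering / backward sampling over the markers, so each
    imputed vector is a draw from the joint conditional distribution given
    the individual's observed markers (not independent per-marker draws:
    CIM uses whole imputed markers as covariates, so within-individual
    consistency matters).  Observed codes are never altered.  Deterministic
    given ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    geno = cross.genotypes
    if not np.any(geno == GENO_MISSING):
        return cross.replace_genotypes(geno.copy())
    n, m = geno.shape
    pos = cross.gmap.positions
    if m < 2:
        raise CrossValidationError("imputation needs at least 2 markers")
    trans = f2_transition_matrix(haldane_r(np.diff(pos) * cm_per_mb))

    # emissions for all markers at once
    emis = np.full((n, m, 3), error_prob / 2.0 if error_prob > 0 else 0.0)
    miss = geno == GENO_MISSING
    emis[miss] = 1.0
    flat = np.flatnonzero(~miss)
    emis.reshape(-1, 3)[flat, geno.reshape(-1)[flat]] = \
        1.0 - error_prob if error_prob > 0 else 1.0

    alpha = np.empty((n, m, 3))
    a = np.broadcast_to(F2_PRIOR, (n, 3)) * emis[:, 0]
    a = a / a.sum(axis=1, keepdims=True)
    alpha[:, 0] = a
    for t in range(1, m):
        a = (a @ trans[t - 1]) * emis[:, t]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, t] = a

    def draw(w: np.ndarray) -> np.ndarray:
        w0 = w[:, 0]
        w01 = w0 + w[:, 1]
        total = w01 + w[:, 2]
        u = rng.random(n) * total
        return ((u > w0).view(np.int8) + (u > w01).view(np.int8))

    sampled = np.empty((n, m), dtype=np.int8)
    state = draw(alpha[:, m - 1])
    sampled[:, m - 1] = state
    for t in range(m - 2, -1, -1):
        w = alpha[:, t] * trans[t][:, state].T  # (n, 3)
        state = draw(w)
        sampled[:, t] = state

    out = geno.copy()
    out[miss] = sampled[miss]
    return cross.replace_genotypes(out)
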