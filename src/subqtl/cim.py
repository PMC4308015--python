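"""Composite interval mapping and its replicated, median-LOD summary.

Composite interval mapping (CIM) augments the Haley-Knott scan with a small
set of marker covariates chosen by forward selection, which absorb the
effects of linked QTL elsewhere on the chromosome; covariates falling
within a window centred on the test position are dropped from that
position's model so the covariate does not soak up the very signal being
tested.

Because missing genotypes are re-imputed — and covariates re-selected — on
every run, repeated CIM runs wander.  The replicated-CIM procedure turns
that instability into a signal: run CIM many times, summarize the replicate
LOD profiles by their pointwise *median* (the replicate distributions are
skewed, so the mean is not used), repeat over a factorial of window/step
sizes, and report the modal location of the median-profile peaks.  Only
positions that carry signal in most imputations survive the median, which
is what makes the summary a fine-mapping tool.  No significance threshold
is attached to the replicated summary; it is a peak-prioritization
heuristic for a QTL that is already established.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _regress
from .cross import GENO_H, GENO_MISSING, CrossData
from .genoprob import build_grid, f2_transition_matrix, impute_missing
from .cross import haldane_r
from .scan import ScanResult, adjust_phenotype

logger = logging.getLogger(__name__)

#: The window/step factorial explored around the baseline parameters:
#: windows of 1, 0.5 and 0.25 Mb crossed with steps of 0, 1 and 0.5 Mb.
FACTORIAL_GRID = tuple((w, s) for w in (1.0, 0.5, 0.25) for s in (0.0, 1.0, 0.5))


@dataclass(frozen=True)
class CimParams:
    """Composite-interval-mapping parameters.

    ``window`` is the full width (Mb) of the exclusion window centred on the
    test position: a covariate marker within window/2 of the tested location
    is dropped there.  ``step`` is the pseudomarker spacing (0 = markers
    only).  Defaults are the baseline used throughout: 3 covariates, 2 Mb
    window, 0.2 Mb step, 400 replicates.
    """

    n_covar: int = 3
    window: float = 2.0
    step: float = 0.2
    n_rep: int = 400

    def __post_init__(self):
        if self.n_covar < 0 or self.window < 0 or self.step < 0:
            raise ValueError("n_covar, window and step must be >= 0")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")


@dataclass(eq=False)
class RepCimResult:
    """Replicated-CIM output: one median profile per parameter combination."""

    trait: str
    combos: list
    median_scans: list
    replicate_peaks: list
    n_runs: int

    def __post_init__(self):
        if self.n_runs != sum(c.n_rep for c in self.combos):
            raise ValueError("run count does not match the parameter grid")


def _marker_scores(genotypes: np.ndarray):
    g = genotypes.astype(float)
    g[genotypes == GENO_MISSING] = np.nan
    xa = g - 1.0
    xd = (genotypes == GENO_H).astype(float)
    return xa, xd


def select_covariate_markers(cross: CrossData, trait: str, n_covar: int,
                             seed: int | None = None,
                             y: np.ndarray | None = None) -> list[str]:
    """Forward selection of ``n_covar`` marker covariates.

    Each candidate marker contributes an additive and a dominance column;
    the marker with the largest residual-sum-of-squares reduction over the
    current model is added, ``n_covar`` times.  Ties break to the leftmost
    position.  Missing genotypes are imputed first (with ``seed``), which is
    why repeated runs can pick different covariates.
    """
    if n_covar > cross.gmap.n_markers:
        raise ValueError("n_covar exceeds the number of markers")
    if n_covar == 0:
        return []
    if y is None:
        y = adjust_phenotype(cross, trait)
    if np.any(cross.genotypes == GENO_MISSING):
        cross = impute_missing(cross, seed=seed)
    xa, xd = _marker_scores(cross.genotypes)
    n = cross.n
    selected: list[int] = []
    base = np.ones((n, 1))
    for _ in range(n_covar):
        q = _regress.orthonormal_basis(base)
        rss0, rss1, _, _ = _regress.pair_scan(q, y, xa, xd)
        reduction = rss0 - rss1
        reduction[selected] = -np.inf
        j = int(np.argmax(reduction))
        selected.append(j)
        base = np.column_stack([base, xa[:, j], xd[:, j]])
    return [cross.gmap.names[j] for j in selected]


_TABLE_CACHE: dict = {}


def _pseudo_tables(gmap, step: float, cm_per_mb: float):
    """Cached per-pseudomarker conditional tables for complete data.

    For every pseudomarker t inside interval (j, j+1) the 9 possible
    flanking genotype pairs each induce a conditional distribution over the
    3 genotypes at t; those (9, 3) tables depend only on the map geometry,
    so they are computed once per (map, step) and reused across replicates.
    """
    key = (gmap.positions.tobytes(), float(step), float(cm_per_mb))
    if key in _TABLE_CACHE:
        return _TABLE_CACHE[key]
    positions, marker_index = build_grid(gmap, step)
    inner_t, inner_j, tables = [], [], []
    for j in range(gmap.n_markers - 1):
        lo, hi = marker_index[j], marker_index[j + 1]
        pl, pr = positions[lo], positions[hi]
        for t in range(lo + 1, hi):
            tl = f2_transition_matrix(haldane_r((positions[t] - pl) * cm_per_mb))
            tr = f2_transition_matrix(haldane_r((pr - positions[t]) * cm_per_mb))
            w = tl[:, None, :] * tr.T[None, :, :]  # (gL, gR, state)
            w = w / w.sum(axis=2, keepdims=True)
            inner_t.append(t)
            inner_j.append(j)
            tables.append(w.reshape(9, 3))
    out = (positions, marker_index,
           np.asarray(inner_t, dtype=int), np.asarray(inner_j, dtype=int),
           np.asarray(tables) if tables else np.zeros((0, 9, 3)))
    if len(_TABLE_CACHE) > 16:
        _TABLE_CACHE.clear()
    _TABLE_CACHE[key] = out
    return out


def _complete_scores(cross: CrossData, step: float, cm_per_mb: float):
    """Haley-Knott scores on a grid for a cross with no missing genotypes.

    With complete marker data the genotype at a pseudomarker depends only on
    the flanking markers (the F2 genotype chain is Markov), so the
    conditional distribution is looked up per interval over the 9 flanking
    genotype pairs — no forward-backward pass needed.
    """
    positions, marker_index, inner_t, inner_j, tables = _pseudo_tables(
        cross.gmap, step, cm_per_mb)
    g = cross.genotypes
    n = cross.n
    xa = np.empty((n, len(positions)))
    xd = np.empty((n, len(positions)))
    xa[:, marker_index] = g
    xa[:, marker_index] -= 1.0
    xd[:, marker_index] = g == GENO_H
    if len(inner_t):
        flat = (g[:, inner_j].astype(np.int16) * 3
                + g[:, inner_j + 1])  # (n, n_inner)
        cols = np.arange(len(inner_t), dtype=np.intp)[None, :]
        xa_tab = tables[:, :, 2] - tables[:, :, 0]  # (n_inner, 9)
        xa[:, inner_t] = xa_tab[cols, flat]
        xd[:, inner_t] = tables[:, :, 1][cols, flat]
    return positions, xa, xd


def cim_scan(cross: CrossData, trait: str, params: CimParams | None = None,
             seed: int = 0, cm_per_mb: float = 1.0,
             y: np.ndarray | None = None) -> ScanResult:
    """One composite-interval-mapping run.

    Missing genotypes are imputed (deterministically from ``seed``),
    covariate markers are forward-selected on the imputed data, and the
    Haley-Knott scan runs on the imputed cross with each position's model
    holding the selected covariates except those inside the exclusion
    window.  ``n_covar = 0`` degenerates to plain interval mapping on the
    imputed data.
    """
    params = params or CimParams()
    if y is None:
        y = adjust_phenotype(cross, trait)
    imp = impute_missing(cross, seed=seed, cm_per_mb=cm_per_mb)
    covariates = select_covariate_markers(imp, trait, params.n_covar, y=y)
    cov_idx = np.array([imp.gmap.index(nm) for nm in covariates], dtype=int)
    positions, xa, xd = _complete_scores(imp, params.step, cm_per_mb)
    n = imp.n
    p = len(positions)

    lod = np.empty(p)
    a_hat = np.empty(p)
    d_hat = np.empty(p)
    if len(cov_idx):
        cov_pos = imp.gmap.positions[cov_idx]
        cov_xa, cov_xd = _marker_scores(imp.genotypes[:, cov_idx])
        active = np.abs(positions[:, None] - cov_pos[None, :]) > params.window / 2.0
        masks, inverse = np.unique(active, axis=0, return_inverse=True)
    else:
        masks = np.zeros((1, 0), dtype=bool)
        inverse = np.zeros(p, dtype=int)
        cov_xa = cov_xd = np.empty((n, 0))

    for k, mask in enumerate(masks):
        idx = np.flatnonzero(inverse == k)
        cols = [np.ones(n)]
        for c in np.flatnonzero(mask):
            cols.extend([cov_xa[:, c], cov_xd[:, c]])
        q = _regress.orthonormal_basis(np.column_stack(cols))
        rss0, rss1, a, d = _regress.pair_scan(q, y, xa[:, idx], xd[:, idx])
        lod[idx] = _regress.lod_from_rss(n, rss0, rss1)
        a_hat[idx] = a
        d_hat[idx] = d

    meta = {"trait": trait, "method": "CIM", "params": params, "seed": seed,
            "covariates": covariates,
            "marker_positions": imp.gmap.positions.copy()}
    return ScanResult(positions, lod, a_hat, d_hat, meta)


def replicated_cim(cross: CrossData, trait: str,
                   base: CimParams | None = None,
                   grid=FACTORIAL_GRID, seed: int = 0,
                   cm_per_mb: float = 1.0,
                   y: np.ndarray | None = None) -> RepCimResult:
    """Replicated CIM over the baseline plus a window-by-step factorial.

    Each parameter combination is run ``n_rep`` times with distinct
    replicate seeds (``seed`` plus a global run index), and summarized by
    the pointwise median LOD; the per-replicate peak positions are kept for
    the consensus step.  With the default 3x3 grid and 400 replicates this
    issues 4,000 CIM runs.
    """
    base = base or CimParams()
    combos = [base] + [replace(base, window=w, step=s) for w, s in (grid or [])]
    if y is None:
        y = adjust_phenotype(cross, trait)

    median_scans, replicate_peaks = [], []
    run = 0
    for combo in combos:
        lods = None
        peaks = np.empty(combo.n_rep)
        result = None
        for rep in range(combo.n_rep):
            result = cim_scan(cross, trait, combo, seed=seed + run,
                              cm_per_mb=cm_per_mb, y=y)
            run += 1
            if lods is None:
                lods = np.empty((combo.n_rep, len(result.positions)))
            lods[rep] = result.lod
            peaks[rep] = result.peak_position
        med = np.median(lods, axis=0)
        meta = {"trait": trait, "method": "repCIM", "params": combo,
                "n_rep": combo.n_rep,
                "marker_positions": result.meta["marker_positions"]}
        median_scans.append(ScanResult(result.positions, med,
                                       np.full_like(med, np.nan),
                                       np.full_like(med, np.nan), meta))
        replicate_peaks.append(peaks)
        logger.info("repCIM combo window=%.2f step=%.2f: median peak %.2f Mb",
                    combo.window, combo.step, median_scans[-1].peak_position)
    return RepCimResult(trait, combos, median_scans, replicate_peaks, run)


def consensus_peak(result: RepCimResult, bin_width: float = 0.5):
    """Modal location of the median-profile peaks across combinations.

    The per-combination argmax positions are histogrammed in bins of
    ``bin_width`` Mb (anchored at 0); the consensus peak is the centre of
    the modal bin (ties to the leftmost bin) and the support interval is the
    min..max of the argmaxes.
    """
    if not result.median_scans:
        raise ValueError("no summarized combinations")
    argmaxes = np.array([s.peak_position for s in result.median_scans])
    bins = np.floor(argmaxes / bin_width + 1e-9).astype(np.int64)
    uniq, counts = np.unique(bins, return_counts=True)
    modal = uniq[np.argmax(counts)]  # ties -> smallest bin index (leftmost)
    peak = float((modal + 0.5) * bin_width)
    return peak, (float(argmaxes.min()), float(argmaxes.max()))
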