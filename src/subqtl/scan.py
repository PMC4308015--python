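"""Phenotype adjustment, Haley-Knott interval mapping, permutation
thresholds and Bayes credible intervals.

The mapping model follows the classic two-step recipe: fat phenotypes are
first adjusted for strain, sex and sacrifice weight by ordinary least
squares, then the residuals are regressed, position by position, on the
expected additive score x_a = P(C) - P(B) and dominance score x_d = P(H)
from the genotype-probability grid.  The LOD at a position is
(n/2) log10(RSS0/RSS1) comparing the model with and without the two
genotype scores (covariates, when present, are kept in both).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _regress
from .cross import CrossData, CrossValidationError
from .genoprob import GenoProbGrid, calc_genoprob

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("strain", "sex", "sac_wt")


@dataclass(eq=False)
class ScanResult:
    """LOD and effect estimates along a position grid.

    ``a_hat``/``d_hat`` are the fitted additive and dominance coefficients
    (grams) at each position.  ``meta`` records the trait, the method
    (IM/CIM/repCIM) and the parameters that produced the profile, plus the
    genotyped marker positions used to expand credible intervals.
    """

    positions: np.ndarray
    lod: np.ndarray
    a_hat: np.ndarray
    d_hat: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.lod = np.asarray(self.lod, dtype=float)

    @property
    def peak_position(self) -> float:
        return float(self.positions[int(np.argmax(self.lod))])

    @property
    def max_lod(self) -> float:
        return float(np.max(self.lod))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position_mb": self.positions, "lod": self.lod,
            "a_hat": self.a_hat, "d_hat": self.d_hat,
            "method": self.meta.get("method", ""),
            "trait": self.meta.get("trait", "")})


def adjust_phenotype(cross: CrossData, trait: str,
                     covariates=DEFAULT_COVARIATES) -> np.ndarray:
    """Least-squares residuals of a trait on the environmental covariates.

    The design holds an intercept, categorical strain and sex (dummy
    coded), and linear sacrifice weight; single-level categorical terms are
    dropped with a warning (e.g. a one-strain cross).  Residuals are
    mean-zero and orthogonal to every design column.
    """
    if trait not in cross.phenotypes.columns:
        raise CrossValidationError(f"unknown trait {trait!r}")
    y = cross.phenotypes[trait].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise CrossValidationError(f"trait {trait!r} has missing values")
    cols = [np.ones(cross.n)]
    for cov in covariates:
        if cov == "strain" or cov == "sex":
            values = cross.strain if cov == "strain" else cross.sex
            levels = sorted(set(values.astype(str)))
            if len(levels) < 2:
                logger.warning("covariate %r has a single level; dropped", cov)
                continue
            for lev in levels[1:]:
                cols.append((values == lev).astype(float))
        elif cov == "sac_wt":
            sac = cross.sac_wt
            if not np.all(np.isfinite(sac)):
                raise CrossValidationError("sac_wt has missing values")
            cols.append(sac - sac.mean())
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    design = np.column_stack(cols)
    if cross.n <= design.shape[1]:
        raise CrossValidationError("more model columns than individuals")
    q = _regress.orthonormal_basis(design)
    return y - q @ (q.T @ y)


def hk_lod(y: np.ndarray, probs: np.ndarray, covariates: np.ndarray | None = None):
    """Haley-Knott test at a single position.

    ``probs`` is the (n, 3) genotype-probability block; the regressors are
    x_a = P(C) - P(B) and x_d = P(H).  Returns ``(lod, a_hat, d_hat)``.
    ``covariates`` (n, k) are kept in both the null and the full model.
    """
    y = np.asarray(y, dtype=float)
    probs = np.asarray(probs, dtype=float)
    n = len(y)
    base = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    q = _regress.orthonormal_basis(base)
    xa = (probs[:, 2] - probs[:, 0])[:, None]
    xd = probs[:, 1][:, None]
    rss0, rss1, a, d = _regress.pair_scan(q, y, xa, xd)
    lod = _regress.lod_from_rss(n, rss0, rss1)
    return float(lod[0]), float(a[0]), float(d[0])


def _scores(grid: GenoProbGrid):
    xa = grid.probs[:, :, 2] - grid.probs[:, :, 0]
    xd = grid.probs[:, :, 1]
    return xa, xd


def scan_im(cross: CrossData, trait: str, step: float = 0.1,
            error_prob: float = 1e-4, cm_per_mb: float = 1.0,
            y: np.ndarray | None = None,
            grid: GenoProbGrid | None = None,
            covariates=DEFAULT_COVARIATES) -> ScanResult:
    """Interval mapping of (adjusted) ``trait`` along the chromosome.

    ``y`` and ``grid`` may be passed to reuse a previous adjustment or
    genotype-probability computation (the permutation code does).
    """
    if y is None:
        y = adjust_phenotype(cross, trait, covariates)
    if grid is None:
        grid = calc_genoprob(cross, step=step, error_prob=error_prob,
                             cm_per_mb=cm_per_mb)
    xa, xd = _scores(grid)
    n = cross.n
    q = np.full((n, 1), 1.0 / np.sqrt(n))
    rss0, rss1, a, d = _regress.pair_scan(q, y, xa, xd)
    lod = _regress.lod_from_rss(n, rss0, rss1)
    meta = {"trait": trait, "method": "IM", "step": step,
            "error_prob": error_prob,
            "marker_positions": cross.gmap.positions.copy()}
    return ScanResult(grid.positions, lod, a, d, meta)


def permutation_threshold(cross: CrossData, trait: str, n_perm: int = 1000,
                          alphas=(0.05, 0.01), seed: int = 0,
                          step: float = 0.1, error_prob: float = 1e-4,
                          cm_per_mb: float = 1.0,
                          y: np.ndarray | None = None,
                          grid: GenoProbGrid | None = None,
                          covariates=DEFAULT_COVARIATES,
                          stratify: np.ndarray | None = None,
                          return_null: bool = False):
    """Genome-wide LOD thresholds from phenotype permutations.

    The pre-adjusted residuals are shuffled against the genotypes (the
    covariates were removed once, before the scan, matching the
    adjust-then-scan order of the pipeline); each permutation is rescanned
    and its maximum LOD recorded.  ``threshold(alpha)`` is the (1 - alpha)
    empirical quantile of those maxima.  Deterministic given ``seed``.

    ``stratify`` restricts shuffling to within groups of the given labels
    (e.g. ``cross.strain``), preserving any residual between-group
    structure under the null; the default is unstratified shuffling.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if y is None:
        y = adjust_phenotype(cross, trait, covariates)
    if grid is None:
        grid = calc_genoprob(cross, step=step, error_prob=error_prob,
                             cm_per_mb=cm_per_mb)
    xa, xd = _scores(grid)
    n = cross.n
    q = np.full((n, 1), 1.0 / np.sqrt(n))
    rng = np.random.default_rng(seed)
    if stratify is not None:
        stratify = np.asarray(stratify)
        if len(stratify) != n:
            raise ValueError("stratify labels must match the cross size")
        groups = [np.flatnonzero(stratify == g) for g in np.unique(stratify)]

    def shuffled() -> np.ndarray:
        if stratify is None:
            return y[rng.permutation(n)]
        out = np.empty_like(y)
        for idx in groups:
            out[idx] = y[idx[rng.permutation(len(idx))]]
        return out

    max_lods = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(4e7 // max(len(grid.positions), 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        ymat = np.empty((n, m))
        for j in range(m):
            ymat[:, j] = shuffled()
        max_lods[done:done + m] = _regress.perm_max_lod(q, ymat, xa, xd, n)
        done += m
    thresholds = {float(a): float(np.quantile(max_lods, 1.0 - a))
                  for a in alphas}
    if return_null:
        return thresholds, max_lods
    return thresholds


def bayes_credible_interval(scan: ScanResult, prob: float = 0.95,
                            marker_positions: np.ndarray | None = None):
    """Bayes credible interval for the QTL location.

    Positions are weighted by 10^LOD and normalized to a probability mass;
    positions are accumulated in decreasing-weight order (ties broken by
    leftmost position) until the mass reaches ``prob``, and the interval is
    the (min, max) of the accumulated set, expanded outward to the nearest
    genotyped markers.  An all-zero profile returns the whole scanned
    region.
    """
    if len(scan.positions) == 0:
        raise ValueError("empty scan")
    if marker_positions is None:
        marker_positions = scan.meta.get("marker_positions")
    lod = scan.lod
    positions = scan.positions
    if np.max(lod) <= 0.0:
        return float(positions[0]), float(positions[-1])
    w = np.power(10.0, lod - np.max(lod))
    w = w / w.sum()
    order = np.lexsort((positions, -w))
    cum = np.cumsum(w[order])
    k = int(np.argmax(cum >= prob - 1e-12)) + 1
    sel = order[:k]
    lo = float(positions[sel].min())
    hi = float(positions[sel].max())
    if marker_positions is not None and len(marker_positions):
        mp = np.asarray(marker_positions, dtype=float)
        left = mp[mp <= lo + 1e-9]
        right = mp[mp >= hi - 1e-9]
        if left.size:
            lo = float(left.max())
        if right.size:
            hi = float(right.min())
    return lo, hi


def scan_sex_interaction(cross: CrossData, trait: str, step: float = 0.1,
                         error_prob: float = 1e-4, cm_per_mb: float = 1.0,
                         y: np.ndarray | None = None,
                         grid: GenoProbGrid | None = None) -> ScanResult:
    """Per-position LOD gain of a QTL-by-sex interaction.

    Compares, at each position, the model with sex-specific genotype scores
    (x_a*sex, x_d*sex added) against the sex-plus-genotype model; the
    difference is nonnegative by nesting.  Both models keep an additive sex
    term.  Requires both sexes.
    """
    sexf = (cross.sex == "F").astype(float)
    if len(set(cross.sex.astype(str))) < 2:
        raise CrossValidationError("sex-interaction scan needs both sexes")
    if y is None:
        y = adjust_phenotype(cross, trait)
    if grid is None:
        grid = calc_genoprob(cross, step=step, error_prob=error_prob,
                             cm_per_mb=cm_per_mb)
    xa, xd = _scores(grid)
    n = cross.n
    base = np.column_stack([np.ones(n), sexf])
    q = _regress.orthonormal_basis(base)
    _, rss_red, _, _ = _regress.pair_scan(q, y, xa, xd)

    p = len(grid.positions)
    dlod = np.empty(p)
    chunk = max(1, int(2e7 // max(n, 1)))
    for start in range(0, p, chunk):
        stop = min(start + chunk, p)
        block = np.stack([
            xa[:, start:stop], xd[:, start:stop],
            xa[:, start:stop] * sexf[:, None],
            xd[:, start:stop] * sexf[:, None]], axis=2)  # (n, b, 4)
        block = np.moveaxis(block, 1, 0)  # (b, n, 4)
        _, rss_full, _ = _regress.block_scan(q, y, block)
        with np.errstate(divide="ignore", invalid="ignore"):
            dlod[start:stop] = 0.5 * n * np.log10(
                np.maximum(rss_red[start:stop], 1e-300)
                / np.maximum(rss_full, 1e-300))
    dlod = np.maximum(dlod, 0.0)
    nan = np.full(p, np.nan)
    meta = {"trait": trait, "method": "IM-sexint", "step": step,
            "marker_positions": cross.gmap.positions.copy()}
    return ScanResult(grid.positions, dlod, nan, nan, meta)
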