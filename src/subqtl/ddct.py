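"""Comparative-Ct (2^-ddCt) relative expression and its genotype model.

Quantitative PCR threshold cycles (Ct) are normalized within each sample
against the median Ct of two housekeeping genes, referenced to a designated
reference sample set, and expressed as relative quantities RQ = 2^-ddCt.
Because RQ variances differ among genotypes, inference runs on the natural
log scale: ln(RQ) is fitted to sex + genotype and the pairwise genotype
contrasts are adjusted for multiplicity with a max-|t| Monte-Carlo
adjustment (the joint null distribution of the contrast t statistics is
sampled, 100,000 draws by default).

The reference set is an explicit, required argument: studies vary between a
pooled-control mean and a single calibrator sample, and the two conventions
give different ddCt baselines.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

REQUIRED_COLUMNS = ("sample", "sex", "genotype", "gene", "ct")
DEFAULT_HOUSEKEEPERS = ("Gus", "Sdha")


class DdctError(ValueError):
    """Malformed Ct table or impossible request."""


def _pivot(table: pd.DataFrame, genes) -> pd.DataFrame:
    """sample x gene Ct matrix; errors if a sample misses a gene."""
    wide = table.pivot_table(index="sample", columns="gene", values="ct",
                             aggfunc="first")
    for g in genes:
        if g not in wide.columns:
            raise DdctError(f"gene {g!r} absent from the Ct table")
        missing = wide.index[wide[g].isna()]
        if len(missing):
            raise DdctError(
                f"samples {list(missing)[:5]} have no Ct for {g!r}")
    return wide


def compute_ddct(table: pd.DataFrame, target: str,
                 housekeepers=DEFAULT_HOUSEKEEPERS,
                 reference_samples=None) -> pd.DataFrame:
    """Per-sample relative expression of ``target``.

    dCt_s = Ct_target,s - median(Ct_hk1,s, Ct_hk2,s)  (the median of two
    values is their mean); ddCt_s subtracts the mean dCt over the reference
    samples; RQ_s = 2^-ddCt_s.  Returns one row per sample with the sample
    annotations plus dct/ddct/rq columns.
    """
    cols = set(table.columns)
    if not set(REQUIRED_COLUMNS) <= cols:
        raise DdctError(f"Ct table needs columns {REQUIRED_COLUMNS}")
    ct = table["ct"].to_numpy(float)
    if np.any(~np.isfinite(ct)) or np.any(ct <= 0):
        raise DdctError("Ct values must be finite and positive")
    if len(housekeepers) != 2:
        raise DdctError("exactly two housekeeping genes are required")
    if not reference_samples:
        raise DdctError("a non-empty reference sample set is required")

    wide = _pivot(table, (target, *housekeepers))
    hk = wide[list(housekeepers)].to_numpy(float)
    dct = wide[target].to_numpy(float) - np.median(hk, axis=1)
    dct = pd.Series(dct, index=wide.index, name="dct")

    ref = [s for s in reference_samples]
    unknown = set(ref) - set(wide.index)
    if unknown:
        raise DdctError(f"unknown reference samples {sorted(unknown)}")
    ddct = dct - dct.loc[ref].mean()

    anno = (table[table["gene"] == target]
            .drop_duplicates("sample").set_index("sample"))
    out = pd.DataFrame({
        "sample": dct.index,
        "sex": anno["sex"].reindex(dct.index).to_numpy(),
        "genotype": anno["genotype"].reindex(dct.index).to_numpy(),
        "dct": dct.to_numpy(),
        "ddct": ddct.to_numpy(),
        "rq": np.power(2.0, -ddct.to_numpy())})
    for extra in ("strain", "tissue"):
        if extra in anno.columns:
            out[extra] = anno[extra].reindex(dct.index).to_numpy()
    return out.reset_index(drop=True)


def fit_expression_model(rq, sex, genotype, n_draws: int = 100_000,
                         seed: int = 0) -> pd.DataFrame:
    """ln(RQ) ~ sex + genotype, with adjusted pairwise genotype contrasts.

    Returns one row per genotype pair with the log-scale estimate, SE, t,
    unadjusted p and the max-|t| Monte-Carlo adjusted p (never below the
    unadjusted p).  Requires at least two genotype classes.
    """
    rq = np.asarray(rq, dtype=float)
    if np.any(rq <= 0):
        raise DdctError("RQ values must be positive")
    sex = np.asarray(sex, dtype=object)
    genotype = np.asarray(genotype, dtype=object)
    levels = sorted(set(genotype.astype(str)),
                    key=lambda g: {"B": 0, "H": 1, "C": 2}.get(g, 9))
    if len(levels) < 2:
        raise DdctError("need at least two genotype classes")

    y = np.log(rq)
    x = pd.DataFrame({"const": np.ones(len(y))})
    for lev in sorted(set(sex.astype(str)))[1:]:
        x[f"sex_{lev}"] = (sex == lev).astype(float)
    for lev in levels[1:]:
        x[f"g_{lev}"] = (genotype == lev).astype(float)
    fit = sm.OLS(y, x).fit()

    k = len(fit.params)
    names = list(x.columns)

    def level_vec(lev):
        v = np.zeros(k)
        if lev != levels[0]:
            v[names.index(f"g_{lev}")] = 1.0
        return v

    lmat = []
    labels = []
    for g1, g2 in combinations(levels, 2):
        lmat.append(level_vec(g2) - level_vec(g1))
        labels.append(f"{g2}-{g1}")
    lmat = np.array(lmat)
    cov = lmat @ fit.cov_params().to_numpy() @ lmat.T
    est = lmat @ fit.params.to_numpy()
    se = np.sqrt(np.diag(cov))
    t = est / se
    df = int(fit.df_resid)
    p_unadj = 2.0 * stats.t.sf(np.abs(t), df)

    # joint null of the t vector: multivariate t with the contrast correlation
    corr = cov / np.outer(se, se)
    w, v = np.linalg.eigh(corr)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, len(est))) @ root.T
    scale = np.sqrt(rng.chisquare(df, n_draws) / df)
    max_abs_t = np.max(np.abs(z / scale[:, None]), axis=1)
    p_adj = np.array([np.mean(max_abs_t >= abs(ti)) for ti in t])
    p_adj = np.maximum(p_adj, p_unadj)

    return pd.DataFrame({"contrast": labels, "estimate": est, "se": se,
                         "t": t, "df": df, "p": p_unadj, "p_adj": p_adj})
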