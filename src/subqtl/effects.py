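"""Per-strain additive/dominance effect models and the cumulative
decomposition across overlapping donor regions.

Each congenic strain's F2 population supports a simple single-locus model:
classify every individual by its consensus genotype over the strain's donor
region (the whole introgressed segment segregates as one block apart from
rare recombinants), then regress each fat trait on sex, sacrifice weight,
an additive score x_a (B = -1, H = 0, C = +1) and a dominance indicator
x_d (1 for H).  When the sex-by-additive interaction is significant the
model keeps sex-specific genotype effects and both per-sex estimates are
reported.  LS means are model predictions at the covariate mean for each
sex-by-genotype cell.

Because the subcongenic donor regions tile the founder's, the founder's
additive effect should decompose as the sum of the subcongenic effects plus
a remainder; a nonzero remainder flags an undetected (possibly
transgressive) QTL.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cross import (GENO_B, GENO_C, GENO_H, CODE_CHARS, CrossData,
                    CrossValidationError)

logger = logging.getLogger(__name__)

SEXES = ("F", "M")
GENO_ORDER = ("B", "H", "C")


class MissingGenotypeClassError(CrossValidationError):
    """A strain lacks one of the three genotype classes."""


@dataclass(eq=False)
class StrainEffectEstimate:
    """Fitted single-locus model for one strain and trait.

    ``sex_specific`` is None when the sex-by-additive interaction was not
    significant; otherwise a dict with per-sex a and d estimates and SEs.
    ``ls_means`` is indexed by (sex, genotype) with columns mean/se/n.
    """

    strain: str
    trait: str
    a: float
    a_se: float
    p_a: float
    d: float
    d_se: float
    p_d: float
    ls_means: pd.DataFrame
    sex_specific: dict | None = None
    p_interaction: float = float("nan")
    n_used: int = 0
    n_excluded: int = 0
    n_recombinant: int = 0


class AdditiveDecomposition(NamedTuple):
    sum_subcongenic: float
    residual: float


def consensus_donor_genotype(cross: CrossData, strain: str):
    """Majority genotype over the donor-region markers, per individual.

    Returns ``(codes, n_recombinant)`` where ``codes`` holds B/H/C integers
    or -9 for excluded individuals (no informative marker, or a tie between
    codes).  Individuals showing more than one distinct code are recombinant
    within the donor region; they keep their majority code but are counted.
    """
    if cross.strain_defs is None or strain not in cross.strain_defs:
        raise CrossValidationError(f"no strain definition for {strain!r}")
    sdef = cross.strain_defs[strain]
    rows = cross.strain == strain
    pos = cross.gmap.positions
    donor = (pos >= sdef.donor_start - 1e-9) & (pos <= sdef.donor_end + 1e-9)
    g = cross.genotypes[rows][:, donor]
    counts = np.stack([(g == c).sum(axis=1) for c in (GENO_B, GENO_H, GENO_C)])
    total = counts.sum(axis=0)
    order = np.argsort(-counts, axis=0, kind="stable")
    best = order[0]
    best_n = np.take_along_axis(counts, best[None], axis=0)[0]
    second_n = np.take_along_axis(counts, order[1][None], axis=0)[0]
    codes = np.where((total > 0) & (best_n > second_n), best, -9).astype(int)
    n_recomb = int(np.sum((counts > 0).sum(axis=0) > 1))
    if n_recomb:
        logger.info("strain %s: %d individuals recombinant within the donor "
                    "region", strain, n_recomb)
    return codes, n_recomb


def _cells(sex: np.ndarray, codes: np.ndarray) -> dict:
    return {(s, gc): int(np.sum((sex == s) & (codes == gi)))
            for s in SEXES for gi, gc in enumerate(GENO_ORDER)}


def fit_strain_model(cross: CrossData, trait: str, strain: str | None = None,
                     interaction_alpha: float = 0.05) -> StrainEffectEstimate:
    """Single-locus effect model for one strain.

    ``cross`` may be the merged dataset (give ``strain``) or already
    restricted to one strain.  Requires both sexes and all three genotype
    classes at the strain's donor-region consensus genotype.
    """
    if strain is None:
        strains = set(cross.strain.astype(str))
        if len(strains) != 1:
            raise CrossValidationError("give strain= on a multi-strain cross")
        strain = strains.pop()
        sub = cross.subset(strain=strain)
    else:
        sub = cross.subset(strain=strain)
    codes, n_recomb = consensus_donor_genotype(sub, strain)
    keep = codes >= 0
    n_excluded = int(np.sum(~keep))
    codes = codes[keep]
    sex = sub.sex[keep].astype(str)
    sac = sub.sac_wt[keep]
    y = sub.phenotypes[trait].to_numpy(float)[keep]

    present = {CODE_CHARS[c] for c in np.unique(codes)}
    if present != set(GENO_ORDER):
        raise MissingGenotypeClassError(
            f"strain {strain}: genotype classes present are {sorted(present)}")
    if len(set(sex)) < 2:
        raise CrossValidationError(f"strain {strain}: single-sex data")

    sexf = (sex == "F").astype(float)
    xa = codes - 1.0
    xd = (codes == 1).astype(float)
    x = pd.DataFrame({"const": 1.0, "sexF": sexf, "sac_wt": sac - sac.mean(),
                      "xa": xa, "xd": xd})
    fit0 = sm.OLS(y, x).fit()
    fit_int = sm.OLS(y, x.assign(xa_sexF=xa * sexf)).fit()
    p_int = float(fit_int.pvalues["xa_sexF"])

    sex_specific = None
    if p_int <= interaction_alpha:
        xfull = x.assign(xa_sexF=xa * sexf, xd_sexF=xd * sexf)
        fit = sm.OLS(y, xfull).fit()
        co, v = fit.params, fit.cov_params()
        a_m, d_m = float(co["xa"]), float(co["xd"])
        a_f = a_m + float(co["xa_sexF"])
        d_f = d_m + float(co["xd_sexF"])
        sex_specific = {
            "a_F": a_f, "a_M": a_m, "d_F": d_f, "d_M": d_m,
            "a_F_se": float(np.sqrt(v.loc["xa", "xa"]
                                    + v.loc["xa_sexF", "xa_sexF"]
                                    + 2 * v.loc["xa", "xa_sexF"])),
            "a_M_se": float(fit.bse["xa"]),
            "d_F_se": float(np.sqrt(v.loc["xd", "xd"]
                                    + v.loc["xd_sexF", "xd_sexF"]
                                    + 2 * v.loc["xd", "xd_sexF"])),
            "d_M_se": float(fit.bse["xd"]),
        }
        # pooled effect = unweighted sex average = xa + xa_sexF/2
        k = len(fit.params)
        la = np.zeros(k)
        la[xfull.columns.get_loc("xa")] = 1.0
        la[xfull.columns.get_loc("xa_sexF")] = 0.5
        ld = np.zeros(k)
        ld[xfull.columns.get_loc("xd")] = 1.0
        ld[xfull.columns.get_loc("xd_sexF")] = 0.5
        ta = fit.t_test(la)
        td = fit.t_test(ld)
        a, a_se, p_a = float(ta.effect[0]), float(ta.sd[0, 0]), float(ta.pvalue)
        d, d_se, p_d = float(td.effect[0]), float(td.sd[0, 0]), float(td.pvalue)
    else:
        fit = fit0
        a, a_se, p_a = (float(fit.params["xa"]), float(fit.bse["xa"]),
                        float(fit.pvalues["xa"]))
        d, d_se, p_d = (float(fit.params["xd"]), float(fit.bse["xd"]),
                        float(fit.pvalues["xd"]))

    cells = _cells(sex, codes)
    rows = []
    cov = fit.cov_params().to_numpy()
    for s in SEXES:
        for gi, gc in enumerate(GENO_ORDER):
            xrow = {"const": 1.0, "sexF": 1.0 if s == "F" else 0.0,
                    "sac_wt": 0.0, "xa": gi - 1.0,
                    "xd": 1.0 if gc == "H" else 0.0}
            if sex_specific is not None:
                xrow["xa_sexF"] = xrow["xa"] * xrow["sexF"]
                xrow["xd_sexF"] = xrow["xd"] * xrow["sexF"]
            vec = np.array([xrow[c] for c in fit.params.index])
            rows.append({"sex": s, "genotype": gc,
                         "mean": float(vec @ fit.params.to_numpy()),
                         "se": float(np.sqrt(vec @ cov @ vec)),
                         "n": cells[(s, gc)]})
    ls_means = pd.DataFrame(rows).set_index(["sex", "genotype"])

    return StrainEffectEstimate(
        strain=strain, trait=trait, a=a, a_se=a_se, p_a=p_a,
        d=d, d_se=d_se, p_d=p_d, ls_means=ls_means,
        sex_specific=sex_specific, p_interaction=p_int,
        n_used=len(codes), n_excluded=n_excluded, n_recombinant=n_recomb)


def additive_from_lsmeans(ls_means) -> dict:
    """Additive/dominance contrasts from a table of sex-by-genotype means.

    Per sex, a = (C - B)/2 and d = H - (B + C)/2; the pooled values are the
    unweighted average over the two sexes.  Accepts the ``ls_means`` frame
    of :class:`StrainEffectEstimate` or a mapping ``{(sex, code): mean}``.
    """
    if isinstance(ls_means, pd.DataFrame):
        table = {idx: float(row["mean"]) for idx, row in ls_means.iterrows()}
    else:
        table = {k: float(v) for k, v in ls_means.items()}
    out = {}
    for s in SEXES:
        try:
            b, h, c = (table[(s, g)] for g in GENO_ORDER)
        except KeyError as exc:
            raise ValueError(f"missing LS-mean cell {exc}") from exc
        out[s] = ((c - b) / 2.0, h - (b + c) / 2.0)
    out["pooled"] = (float(np.mean([out[s][0] for s in SEXES])),
                     float(np.mean([out[s][1] for s in SEXES])))
    return out


def decompose_additive(founder_a: float,
                       subcongenic_as: Sequence[float]) -> AdditiveDecomposition:
    """Cumulative decomposition of the founder congenic's additive effect.

    ``sum_subcongenic`` is the sum of the subcongenic additive effects and
    ``residual = founder_a - sum`` is the remainder attributable to
    undetected (e.g. transgressive) QTL.  Exact arithmetic:
    sum + residual = founder_a, order-invariant.
    """
    s = float(np.sum(np.asarray(subcongenic_as, dtype=float)))
    if not np.isfinite(s) or not np.isfinite(founder_a):
        raise ValueError("effects must be finite")
    return AdditiveDecomposition(s, float(founder_a) - s)
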