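"""Synthetic congenic-cross generator.

Emulates the study design: six F2 populations — a founder congenic whose
donor segment spans most of distal chromosome 2, plus five overlapping
subcongenics — segregating two linked additive QTL about 20 Mb apart, with
a sex effect, a body-weight covariate, Gaussian residual noise and missing
genotypes.  Within a strain's donor interval each individual receives two
gamete haplotypes simulated as Markov chains with Haldane recombination
between adjacent loci; outside the interval everyone is homozygous
background.  Each fat pad receives a fixed share of the genetic and
environmental signal and total fat is their sum, so TF = GFP+MFP+RFP+FFP
holds by construction.

Default donor intervals reproduce the overlap topology of the strain panel
(only the founder and the distal-most subcongenic have printed bounds; the
rest are plausible inventions and freely overridable).  Default QTL effects
(-0.040 g at 156.9 Mb, -0.090 g at 174.3 Mb, residual SD 0.30 g) are
calibrated to the magnitude of the reported strain effects; they are stated
choices, not measured values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross import (GENO_B, GENO_H, GENO_MISSING, CongenicStrainDef,
                    CrossData, CrossValidationError, GeneticMap,
                    assemble_merged_cross, haldane_r)

#: Share of the phenotypic signal carried by each fat pad (sums to 1);
#: roughly proportional to the observed pad weights.
DEFAULT_PAD_SHARES = {"GFP": 0.36, "FFP": 0.34, "MFP": 0.22, "RFP": 0.08}


@dataclass(frozen=True)
class QtlSpec:
    """One simulated QTL: position (Mb), additive and dominance effects (g).

    ``a_F``/``a_M`` override the additive effect per sex when set (the
    convention is a = (C - B)/2, so a negative ``a`` means donor alleles
    reduce the trait).
    """

    pos: float
    a: float
    d: float = 0.0
    a_F: float | None = None
    a_M: float | None = None

    def additive(self, is_female: np.ndarray) -> np.ndarray:
        a_f = self.a if self.a_F is None else self.a_F
        a_m = self.a if self.a_M is None else self.a_M
        return np.where(is_female, a_f, a_m)


@dataclass(eq=False)
class SimConfig:
    """Full description of a simulated multi-strain study."""

    gmap: GeneticMap
    strains: list  # [(CongenicStrainDef, n), ...]
    qtl: list = field(default_factory=list)
    sex_effect: float = 0.30     # grams added to females
    sac_mean: float = 45.0       # sacrifice weight, grams
    sac_sd: float = 5.0
    sac_slope: float = 0.02      # grams of fat per gram of body weight
    baseline: float = 0.15       # total-fat intercept, grams
    residual_sd: float = 0.30    # total-fat residual SD, grams
    pad_shares: dict = field(default_factory=lambda: dict(DEFAULT_PAD_SHARES))
    missing_rate: float = 0.05
    cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise CrossValidationError("residual_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise CrossValidationError("missing_rate must be in [0, 1)")
        if abs(sum(self.pad_shares.values()) - 1.0) > 1e-9:
            raise CrossValidationError("pad shares must sum to 1")
        lo, hi = self.gmap.span
        for q in self.qtl:
            if not lo - 1e-9 <= q.pos <= hi + 1e-9:
                raise CrossValidationError(f"QTL at {q.pos} outside the map")
        for sdef, n in self.strains:
            sdef.validate_against(self.gmap)
            if n < 1:
                raise CrossValidationError(f"{sdef.name}: n must be >= 1")


def default_map() -> GeneticMap:
    """Marker panel: 1 marker / 2 Mb below 145 Mb (microsatellite era),
    1 / 0.75 Mb from 145 Mb to the telomere (SNP fine-mapping panel)."""
    low = 74.9 + 2.0 * np.arange(35)            # 74.9 .. 142.9
    high = 145.0 + 0.75 * np.arange(49)         # 145.0 .. 181.0
    pos = np.concatenate([low, high])
    names = [f"D2sim{i + 1:03d}" for i in range(len(low))]
    names += [f"rs_sim{i + 1:03d}" for i in range(len(high))]
    kinds = ["microsatellite"] * len(low) + ["SNP"] * len(high)
    return GeneticMap("2", names, pos, kinds)


def default_strains() -> list:
    """The founder congenic and five overlapping subcongenics with the
    study's per-strain sample sizes (total 1,990)."""
    return [
        (CongenicStrainDef("HG2D", 74.9, 181.0, 1.0), 278),
        (CongenicStrainDef("HG2D-1", 75.0, 120.0, 1.0), 384),
        (CongenicStrainDef("HG2D-2", 115.0, 145.0, 1.0), 208),
        (CongenicStrainDef("HG2D-3", 145.0, 163.0, 1.0), 382),
        (CongenicStrainDef("HG2D-4", 152.0, 176.0, 1.0), 353),
        (CongenicStrainDef("HG2D-5", 168.5, 178.5, 1.0), 385),
    ]


def default_config(seed: int = 0) -> SimConfig:
    """The flagship two-QTL configuration: a proximal QTL at 156.9 Mb and a
    distal, stronger QTL at 174.3 Mb, both reducing fat."""
    return SimConfig(
        gmap=default_map(),
        strains=default_strains(),
        qtl=[QtlSpec(156.9, -0.040), QtlSpec(174.3, -0.090)],
        seed=seed)


def simulate_strain_f2(strain_def: CongenicStrainDef, n: int,
                       gmap: GeneticMap, qtl, *, seed: int = 0,
                       rng: np.random.Generator | None = None,
                       sex_effect: float = 0.30, sac_mean: float = 45.0,
                       sac_sd: float = 5.0, sac_slope: float = 0.02,
                       baseline: float = 0.15, residual_sd: float = 0.30,
                       pad_shares=None, missing_rate: float = 0.05,
                       cm_per_mb: float = 1.0) -> CrossData:
    """Simulate one congenic strain's F2 population.

    The returned dataset covers the markers of the strain's genotyping
    panel (the donor region expanded by the boundary uncertainty); markers
    inside a recombinant-end zone are coded missing for everyone, and
    additional genotypes are dropped at ``missing_rate``.  QTL outside the
    donor region contribute nothing (their genotype is fixed background).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pad_shares = dict(pad_shares or DEFAULT_PAD_SHARES)
    pos = gmap.positions
    s, e = strain_def.donor_start, strain_def.donor_end
    lo, hi = strain_def.expanded()
    panel = np.flatnonzero((pos >= lo - 1e-9) & (pos <= hi + 1e-9))
    if len(panel) < 2:
        raise CrossValidationError(
            f"{strain_def.name}: fewer than 2 markers in the panel")

    seg_markers = panel[(pos[panel] >= s - 1e-9) & (pos[panel] <= e + 1e-9)]
    inside_qtl = [q for q in qtl if s - 1e-9 <= q.pos <= e + 1e-9]
    loci = {round(float(pos[j]), 9): None for j in seg_markers}
    for q in inside_qtl:
        loci.setdefault(round(float(q.pos), 9), None)
    loci_pos = np.array(sorted(loci))
    locus_of = {p: i for i, p in enumerate(loci_pos)}

    # two independent gamete chains per individual, Haldane recombination
    r = haldane_r(np.diff(loci_pos) * cm_per_mb)
    nloc = len(loci_pos)
    alleles = np.empty((n, 2, nloc), dtype=np.int8)
    alleles[:, :, 0] = rng.integers(0, 2, size=(n, 2))
    if nloc > 1:
        flips = (rng.random((n, 2, nloc - 1)) < r).astype(np.int8)
        alleles[:, :, 1:] = flips
        np.bitwise_xor.accumulate(alleles, axis=2, out=alleles)
    geno_loci = alleles.sum(axis=1)  # 0/1/2 per locus

    codes = np.full((n, len(panel)), GENO_B, dtype=np.int8)
    for k, j in enumerate(seg_markers):
        col = np.flatnonzero(panel == j)[0]
        codes[:, col] = geno_loci[:, locus_of[round(float(pos[j]), 9)]]
    uncertain = strain_def.uncertainty_mask(pos[panel])
    codes[:, uncertain] = GENO_MISSING
    if missing_rate > 0:
        drop = rng.random(codes.shape) < missing_rate
        codes[drop & (codes != GENO_MISSING)] = GENO_MISSING

    is_female = rng.random(n) < 0.5
    sex = np.where(is_female, "F", "M").astype(object)
    sac = rng.normal(sac_mean, sac_sd, n)
    signal = baseline + sex_effect * is_female + sac_slope * sac
    for q in inside_qtl:
        g = geno_loci[:, locus_of[round(float(q.pos), 9)]]
        signal = signal + q.additive(is_female) * (g - 1.0) + q.d * (g == 1)

    pads = {}
    for pad, share in pad_shares.items():
        noise = rng.normal(0.0, residual_sd * np.sqrt(share), n)
        pads[pad] = share * signal + noise
    phen = pd.DataFrame({p: pads[p] for p in ("GFP", "MFP", "RFP", "FFP")})
    phen["TF"] = phen.sum(axis=1)

    ids = np.array([f"{strain_def.name}-{i + 1:04d}" for i in range(n)],
                   dtype=object)
    return CrossData(
        gmap.submap(panel), ids, np.full(n, strain_def.name, dtype=object),
        sex, sac, codes, phen, {strain_def.name: strain_def})


def simulate_study(config: SimConfig) -> CrossData:
    """Simulate all strains of a configuration and merge them.

    Per-strain random streams are spawned from the study seed, so the
    merged dataset is deterministic given the configuration.
    """
    children = np.random.SeedSequence(config.seed).spawn(len(config.strains))
    datasets = []
    for child, (sdef, n) in zip(children, config.strains):
        datasets.append(simulate_strain_f2(
            sdef, n, config.gmap, config.qtl,
            rng=np.random.default_rng(child),
            sex_effect=config.sex_effect, sac_mean=config.sac_mean,
            sac_sd=config.sac_sd, sac_slope=config.sac_slope,
            baseline=config.baseline, residual_sd=config.residual_sd,
            pad_shares=config.pad_shares, missing_rate=config.missing_rate,
            cm_per_mb=config.cm_per_mb))
    return assemble_merged_cross(datasets, union_map=config.gmap)
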