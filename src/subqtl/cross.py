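"""Core data model for congenic F2 intercrosses.

A congenic strain carries a donor segment from one inbred strain (here
CAST/EiJ, genotype code ``C``) introgressed into an otherwise uniform
recipient background (C57BL/6J-hg, code ``B``).  An F2 intercross from such
a strain segregates only *inside* the donor interval; outside it every
individual is homozygous for the background allele.  Overlapping
subcongenic strains therefore tile a chromosome with intervals in which
different subsets of individuals are informative, and merging their F2
populations yields one large mapping panel.

This module holds the marker map, the strain donor-region geometry, the
genotype/phenotype container, the map function, and the merge and
segregation-check operations.  Genotypes are stored as small integers:
``0 = B`` (background homozygote), ``1 = H`` (heterozygote), ``2 = C``
(donor homozygote), ``-1 = missing``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENO_B = 0
GENO_H = 1
GENO_C = 2
GENO_MISSING = -1

CODE_CHARS = {GENO_B: "B", GENO_H: "H", GENO_C: "C", GENO_MISSING: "-"}
CHAR_CODES = {v: k for k, v in CODE_CHARS.items()}

#: The four dissected fat depots; total fat is their sum.
FAT_PADS = ("GFP", "MFP", "RFP", "FFP")
TOTAL_FAT = "TF"


class CrossValidationError(ValueError):
    """Base class for malformed map/cross inputs."""


class UnsortedMapError(CrossValidationError):
    """Marker positions are not strictly increasing."""


class DuplicateMarkerError(CrossValidationError):
    """Two markers share a name (or a name maps to conflicting positions)."""


class UnknownGenotypeCodeError(CrossValidationError):
    """A genotype entry is not one of B, H, C or missing."""


class ConflictingGenotypeError(CrossValidationError):
    """An observed donor allele lies outside the strain's donor region."""


class DuplicateIndividualError(CrossValidationError):
    """Two individuals share an id in a merge."""


def haldane_r(d):
    """Convert a map distance ``d`` (cM) to a recombination fraction.

    Haldane's map function, r = (1 - exp(-2 d / 100)) / 2, which assumes no
    crossover interference.  Accepts scalars or arrays; rejects negative
    distances.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * arr / 100.0))
    if arr.ndim == 0:
        return float(r)
    return r


@dataclass(eq=False)
class GeneticMap:
    """Ordered markers on a single chromosome, positions in Mb.

    The study maps over the physical (Mb) scale; conversion to genetic
    distance happens downstream via a configurable cM/Mb factor.
    """

    chromosome: str
    names: Sequence[str]
    positions: np.ndarray
    kinds: Sequence[str] | None = None  # "microsatellite" | "SNP"

    def __post_init__(self):
        self.names = tuple(str(n) for n in self.names)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != len(self.positions):
            raise CrossValidationError("marker names and positions differ in length")
        if len(self.names) < 2:
            raise CrossValidationError("a map needs at least 2 markers")
        if len(set(self.names)) != len(self.names):
            raise DuplicateMarkerError("duplicate marker names in map")
        if not np.all(np.diff(self.positions) > 0):
            raise UnsortedMapError("marker positions must be strictly increasing")
        if self.kinds is not None:
            self.kinds = tuple(self.kinds)
            if len(self.kinds) != len(self.names):
                raise CrossValidationError("kinds length mismatch")

    @property
    def n_markers(self) -> int:
        return len(self.names)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.positions[0]), float(self.positions[-1])

    def index(self, name: str) -> int:
        return self.names.index(name)

    def submap(self, indices) -> "GeneticMap":
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        kinds = None if self.kinds is None else [self.kinds[i] for i in idx]
        return GeneticMap(self.chromosome, [self.names[i] for i in idx],
                          self.positions[idx], kinds)

    def to_frame(self) -> pd.DataFrame:
        kinds = self.kinds if self.kinds is not None else ["SNP"] * self.n_markers
        return pd.DataFrame({"marker": self.names, "chr": self.chromosome,
                             "pos_mb": self.positions, "kind": kinds})


@dataclass(eq=False)
class CongenicStrainDef:
    """Donor interval of one congenic strain.

    ``boundary_uncertainty`` is the width (Mb, per end) of the recombinant-end
    zone whose genotype is unknown: the strain founder recombined somewhere in
    that window, so markers there cannot be assumed either donor or background.
    """

    name: str
    donor_start: float
    donor_end: float
    boundary_uncertainty: float = 1.0

    def __post_init__(self):
        if not self.donor_start < self.donor_end:
            raise CrossValidationError(
                f"{self.name}: donor_start must be < donor_end")
        if self.boundary_uncertainty < 0:
            raise CrossValidationError(
                f"{self.name}: boundary_uncertainty must be >= 0")

    def validate_against(self, gmap: GeneticMap) -> None:
        lo, hi = gmap.span
        if self.donor_start < lo - 1e-9 or self.donor_end > hi + 1e-9:
            raise CrossValidationError(
                f"{self.name}: donor region outside the map range")

    def expanded(self) -> tuple[float, float]:
        """Donor interval grown by the boundary uncertainty on each side."""
        return (self.donor_start - self.boundary_uncertainty,
                self.donor_end + self.boundary_uncertainty)

    def uncertainty_mask(self, positions: np.ndarray) -> np.ndarray:
        """True for positions inside a recombinant-end zone of this strain."""
        u = self.boundary_uncertainty
        p = np.asarray(positions)
        near_start = np.abs(p - self.donor_start) < u
        near_end = np.abs(p - self.donor_end) < u
        return near_start | near_end


TF_TOL = 1e-9  # total fat must equal the sum of the four pads to this tolerance


@dataclass(eq=False)
class CrossData:
    """Merged (or single-strain) F2 genotype/phenotype table.

    ``genotypes`` is an (n_individuals, n_markers) int8 array in the coding
    above.  ``phenotypes`` holds trait columns in grams.  ``strain_defs``
    maps strain name to its donor-region definition when known; background
    and segregation checks need it.
    """

    gmap: GeneticMap
    ids: np.ndarray
    strain: np.ndarray
    sex: np.ndarray
    sac_wt: np.ndarray
    genotypes: np.ndarray
    phenotypes: pd.DataFrame
    strain_defs: Mapping[str, CongenicStrainDef] | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.strain = np.asarray(self.strain, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        self.sac_wt = np.asarray(self.sac_wt, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotypes = self.phenotypes.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate(self) -> "CrossData":
        n, m = self.genotypes.shape
        if not (len(self.ids) == len(self.strain) == len(self.sex)
                == len(self.sac_wt) == len(self.phenotypes) == n):
            raise CrossValidationError("inconsistent row counts")
        if m != self.gmap.n_markers:
            raise CrossValidationError("genotype columns do not match the map")
        if len(set(self.ids)) != n:
            raise DuplicateIndividualError("duplicate individual ids")
        bad = ~np.isin(self.genotypes, (GENO_B, GENO_H, GENO_C, GENO_MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise UnknownGenotypeCodeError(
                f"invalid genotype code at individual {self.ids[i]!r}, "
                f"marker {self.gmap.names[j]!r}")
        if not set(self.sex) <= {"F", "M"}:
            raise CrossValidationError("sex must be F or M")
        self._check_total_fat()
        self._check_background()
        return self

    def _check_total_fat(self) -> None:
        cols = set(self.phenotypes.columns)
        if TOTAL_FAT in cols and set(FAT_PADS) <= cols:
            tf = self.phenotypes[TOTAL_FAT].to_numpy(float)
            total = sum(self.phenotypes[p].to_numpy(float) for p in FAT_PADS)
            ok = np.isfinite(tf) & np.isfinite(total)
            if np.any(np.abs(tf[ok] - total[ok]) > TF_TOL):
                raise CrossValidationError("TF does not equal GFP+MFP+RFP+FFP")

    def _check_background(self) -> None:
        """Observed donor alleles outside a strain's donor region are errors.

        Background coding never silently overwrites an observed H or C: such
        an observation contradicts the strain definition and is rejected.
        """
        if self.strain_defs is None:
            return
        pos = self.gmap.positions
        for name in np.unique(self.strain.astype(str)):
            sdef = self.strain_defs.get(name)
            if sdef is None:
                continue
            lo, hi = sdef.expanded()
            outside = (pos < lo - 1e-9) | (pos > hi + 1e-9)
            if not outside.any():
                continue
            g = self.genotypes[self.strain == name][:, outside]
            if np.any((g == GENO_H) | (g == GENO_C)):
                raise ConflictingGenotypeError(
                    f"strain {name}: observed donor allele outside the donor "
                    f"region (background must be homozygous B)")

    def subset(self, mask=None, strain: str | None = None) -> "CrossData":
        if strain is not None:
            mask = self.strain == strain
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CrossData(
            self.gmap, self.ids[idx], self.strain[idx], self.sex[idx],
            self.sac_wt[idx], self.genotypes[idx],
            self.phenotypes.iloc[idx].reset_index(drop=True),
            self.strain_defs)

    def replace_genotypes(self, genotypes: np.ndarray) -> "CrossData":
        return CrossData(self.gmap, self.ids, self.strain, self.sex,
                         self.sac_wt, genotypes, self.phenotypes,
                         self.strain_defs)


def _union_map(strain_datasets: Sequence[CrossData]) -> GeneticMap:
    chrom = strain_datasets[0].gmap.chromosome
    seen: dict[str, tuple[float, str]] = {}
    for ds in strain_datasets:
        if ds.gmap.chromosome != chrom:
            raise CrossValidationError("datasets are on different chromosomes")
        kinds = ds.gmap.kinds or ["SNP"] * ds.gmap.n_markers
        for nm, p, k in zip(ds.gmap.names, ds.gmap.positions, kinds):
            if nm in seen and abs(seen[nm][0] - p) > 1e-9:
                raise DuplicateMarkerError(
                    f"marker {nm!r} has conflicting positions "
                    f"({seen[nm][0]} vs {p})")
            seen.setdefault(nm, (float(p), k))
    order = sorted(seen, key=lambda nm: seen[nm][0])
    return GeneticMap(chrom, order, [seen[nm][0] for nm in order],
                      [seen[nm][1] for nm in order])


def assemble_merged_cross(strain_datasets: Sequence[CrossData],
                          union_map: GeneticMap | None = None) -> CrossData:
    """Merge per-strain F2 datasets onto one marker map.

    For each individual, markers its strain never genotyped are coded ``B``
    when they lie outside the strain's (uncertainty-expanded) donor region —
    the background there is fixed by construction of the congenic — and
    ``missing`` when they lie inside it, where the HMM must marginalize over
    the unobserved genotype.  Observed codes are copied through unchanged;
    a donor allele observed outside the donor region fails validation.
    """
    if not strain_datasets:
        raise CrossValidationError("no datasets to merge")
    if union_map is None:
        union_map = _union_map(strain_datasets)

    strain_defs: dict[str, CongenicStrainDef] = {}
    for ds in strain_datasets:
        if ds.strain_defs is None:
            raise CrossValidationError(
                "each dataset needs strain_defs to be merged")
        strain_defs.update(ds.strain_defs)

    pos = union_map.positions
    name_to_col = {nm: j for j, nm in enumerate(union_map.names)}

    blocks, ids, strain, sex, sac, phen = [], [], [], [], [], []
    for ds in strain_datasets:
        cols = []
        for nm in ds.gmap.names:
            if nm not in name_to_col:
                raise CrossValidationError(
                    f"marker {nm!r} missing from the union map")
            cols.append(name_to_col[nm])
        cols = np.asarray(cols)
        geno = np.full((ds.n, union_map.n_markers), GENO_MISSING, dtype=np.int8)
        for s in np.unique(ds.strain.astype(str)):
            sdef = strain_defs.get(s)
            if sdef is None:
                raise CrossValidationError(f"no strain definition for {s!r}")
            lo, hi = sdef.expanded()
            outside = (pos < lo - 1e-9) | (pos > hi + 1e-9)
            rows = ds.strain == s
            geno[np.ix_(rows, outside)] = GENO_B
        geno[:, cols] = ds.genotypes
        blocks.append(geno)
        ids.append(ds.ids)
        strain.append(ds.strain)
        sex.append(ds.sex)
        sac.append(ds.sac_wt)
        phen.append(ds.phenotypes)

    merged = CrossData(
        union_map,
        np.concatenate(ids), np.concatenate(strain), np.concatenate(sex),
        np.concatenate(sac), np.vstack(blocks),
        pd.concat(phen, ignore_index=True, sort=False),
        strain_defs)
    merged.validate()
    logger.info("merged %d strains into n=%d individuals, %d markers",
                len(strain_datasets), merged.n, union_map.n_markers)
    return merged


def infer_strain_defs(cross: CrossData) -> dict[str, CongenicStrainDef]:
    """Infer donor regions from the data when no definitions were given.

    A congenic strain's donor region is the span of markers at which any of
    its individuals carries a donor allele (H or C); everything outside is
    fixed background by construction.  Boundary uncertainty is set to zero
    since the genotyped extent is all the data can support.
    """
    pos = cross.gmap.positions
    defs = {}
    for name in np.unique(cross.strain.astype(str)):
        g = cross.genotypes[cross.strain == name]
        seg = np.flatnonzero(((g == GENO_H) | (g == GENO_C)).any(axis=0))
        if len(seg) == 0:
            raise CrossValidationError(
                f"strain {name}: no segregating markers, cannot infer a "
                f"donor region")
        defs[name] = CongenicStrainDef(name, float(pos[seg[0]]),
                                       float(pos[seg[-1]]), 0.0)
    return defs


def validate_segregation(cross: CrossData):
    """Per-strain 1:2:1 genotype and 1:1 sex-ratio chi-square tests.

    Returns ``(genotype_table, sex_table)``: the first has one row per
    strain x donor-region marker with observed counts, the chi-square
    statistic against the F2 1:2:1 expectation (2 df) and its p-value; the
    second has one row per strain for the sex ratio (1 df).
    """
    if cross.strain_defs is None:
        raise CrossValidationError("segregation checks need strain_defs")
    pos = cross.gmap.positions
    geno_rows, sex_rows = [], []
    for name in np.unique(cross.strain.astype(str)):
        sdef = cross.strain_defs.get(name)
        if sdef is None:
            raise CrossValidationError(f"no strain definition for {name!r}")
        rows = cross.strain == name
        donor = (pos >= sdef.donor_start - 1e-9) & (pos <= sdef.donor_end + 1e-9)
        g = cross.genotypes[rows][:, donor]
        names = [cross.gmap.names[j] for j in np.flatnonzero(donor)]
        any_typed = False
        for j, mname in enumerate(names):
            col = g[:, j]
            counts = np.array([(col == GENO_B).sum(), (col == GENO_H).sum(),
                               (col == GENO_C).sum()], dtype=float)
            tot = counts.sum()
            if tot == 0:
                continue
            any_typed = True
            chi2, p = stats.chisquare(counts, f_exp=tot * np.array([0.25, 0.5, 0.25]))
            geno_rows.append({"strain": name, "marker": mname,
                              "n_B": int(counts[0]), "n_H": int(counts[1]),
                              "n_C": int(counts[2]), "chi2": float(chi2),
                              "p": float(p)})
        if not any_typed:
            raise CrossValidationError(
                f"strain {name}: no genotyped markers inside the donor region")
        n_f = int(np.sum(cross.sex[rows] == "F"))
        n_m = int(np.sum(cross.sex[rows] == "M"))
        chi2, p = stats.chisquare(np.array([n_f, n_m], dtype=float))
        sex_rows.append({"strain": name, "n_F": n_f, "n_M": n_m,
                         "chi2": float(chi2), "p": float(p)})
    return pd.DataFrame(geno_rows), pd.DataFrame(sex_rows)
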