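"""On-disk dialect: map CSV, cross CSV, scan TSV and JSON reports.

Two CSV files define the interchange format for the whole toolkit:

* map CSV — columns ``marker,chr,pos_mb[,kind]``, one row per marker,
  sorted by position;
* cross CSV — one row per individual, columns
  ``id,strain,sex,sac_wt,<traits...>,<marker columns>`` where marker
  columns hold ``B``/``H``/``C`` or ``-`` for missing.

Lines starting with ``#`` are comments (output files carry the tool
version and parameters there).  Scan TSVs are written with fixed 6-decimal
formatting so identical runs produce byte-identical files.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cross import (CHAR_CODES, CODE_CHARS, CrossData, CrossValidationError,
                    DuplicateMarkerError, GeneticMap, UnknownGenotypeCodeError,
                    UnsortedMapError)
from .scan import ScanResult

logger = logging.getLogger(__name__)

META_COLUMNS = ("id", "strain", "sex", "sac_wt")


def _header_lines(params: dict | None) -> str:
    lines = [f"# subqtl {__version__}"]
    if params:
        kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        lines.append(f"# {kv}")
    return "\n".join(lines) + "\n"


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"marker", "chr", "pos_mb"}
    if not required <= set(df.columns):
        raise CrossValidationError(f"map CSV needs columns {sorted(required)}")
    chroms = df["chr"].astype(str).unique()
    if len(chroms) != 1:
        raise CrossValidationError("map spans multiple chromosomes")
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise DuplicateMarkerError(f"duplicate marker {dup!r} in map CSV")
    pos = df["pos_mb"].to_numpy(float)
    if not np.all(np.diff(pos) > 0):
        j = int(np.argmax(np.diff(pos) <= 0))
        raise UnsortedMapError(
            f"map CSV not sorted by position (rows {j + 1} and {j + 2})")
    kinds = df["kind"].tolist() if "kind" in df.columns else None
    return GeneticMap(chroms[0], df["marker"].astype(str).tolist(), pos, kinds)


def write_map(gmap: GeneticMap, path, params: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        gmap.to_frame().to_csv(fh, index=False, float_format="%.17g")


def read_cross(map_csv, cross_csv, strain_defs=None) -> CrossData:
    """Load and validate a cross from the two-file dialect.

    Individuals missing sex or sacrifice weight are dropped with a logged
    warning (never imputed).  Unknown genotype codes, unsorted maps and
    duplicate markers each raise their own validation error naming the
    offending row/column.
    """
    gmap = read_map(map_csv)
    df = pd.read_csv(cross_csv, comment="#", dtype={"id": str},
                     float_precision="round_trip")
    missing_cols = set(META_COLUMNS) - set(df.columns)
    if missing_cols:
        raise CrossValidationError(
            f"cross CSV lacks columns {sorted(missing_cols)}")
    absent = [nm for nm in gmap.names if nm not in df.columns]
    if absent:
        raise CrossValidationError(
            f"cross CSV lacks marker columns {absent[:5]}")

    ok = df["sex"].isin(["F", "M"]).to_numpy() & np.isfinite(
        pd.to_numeric(df["sac_wt"], errors="coerce").to_numpy())
    if not ok.all():
        logger.warning("dropping %d individuals with missing sex/sac_wt",
                       int((~ok).sum()))
        df = df.loc[ok].reset_index(drop=True)

    geno = np.empty((len(df), gmap.n_markers), dtype=np.int8)
    for j, nm in enumerate(gmap.names):
        col = df[nm].astype(str).str.strip()
        codes = col.map(CHAR_CODES)
        if codes.isna().any():
            i = int(codes.isna().idxmax())
            raise UnknownGenotypeCodeError(
                f"unknown genotype code {col.iloc[i]!r} at row {i + 1}, "
                f"marker column {nm!r}")
        geno[:, j] = codes.to_numpy(dtype=np.int8)

    traits = [c for c in df.columns
              if c not in META_COLUMNS and c not in gmap.names]
    cross = CrossData(
        gmap, df["id"].to_numpy(object), df["strain"].to_numpy(object),
        df["sex"].to_numpy(object), df["sac_wt"].to_numpy(float), geno,
        df[traits].astype(float), strain_defs)
    cross.validate()
    logger.info("read cross: n=%d, %d markers, traits %s",
                cross.n, gmap.n_markers, traits)
    return cross


def write_cross(cross: CrossData, map_csv, cross_csv,
                params: dict | None = None) -> None:
    """Write the two-file dialect (lossless round trip)."""
    write_map(cross.gmap, map_csv, params)
    df = pd.DataFrame({"id": cross.ids, "strain": cross.strain,
                       "sex": cross.sex, "sac_wt": cross.sac_wt})
    for col in cross.phenotypes.columns:
        df[col] = cross.phenotypes[col].to_numpy()
    chars = np.vectorize(CODE_CHARS.get)(cross.genotypes)
    for j, nm in enumerate(cross.gmap.names):
        df[nm] = chars[:, j]
    with open(cross_csv, "w") as fh:
        fh.write(_header_lines(params))
        df.to_csv(fh, index=False, float_format="%.17g")


def write_scan(scan: ScanResult, path, params: dict | None = None) -> None:
    frame = scan.to_frame()
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def write_json(obj: dict, path, params: dict | None = None) -> None:
    payload = {"tool": f"subqtl {__version__}"}
    if params:
        payload["params"] = {k: str(v) for k, v in sorted(params.items())}
    payload.update(obj)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
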