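"""Readers and writers for the plain-text formats the pipeline consumes.

Formats
-------
β matrix      TSV, probe ids in the first column (``probe_id``), sample ids in
              the header row; values in [0, 1] written to 6 decimals.
manifest      CSV with columns probe_id, chrom, pos, genes, region, cgi,
              flag_snp, flag_ch, flag_xreactive. Multi-gene annotation uses
              ';' as separator ("TRAPPC9;REV3L"). Positions are 1-based
              (Illumina manifest convention).
sample sheet  CSV with columns sample_id, subject_id, group, age, sex, slide,
              pasi, timepoint. Missing PASI is an empty field, distinct from 0.
gene sets     Standard GMT: set name, description, then gene symbols,
              tab-separated.
DMR output    BED (0-based half-open; conversion happens at the writer only)
              plus a companion CSV carrying the statistics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BetaMatrix,
    FormatError,
    GeneSetCollection,
    MMatrix,
    ProbeManifest,
    SampleSheet,
)

_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False,
                "t": True, "f": False, "yes": True, "no": False}


def _parse_bool(value, where: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    tok = str(value).strip().lower()
    if tok not in _BOOL_TOKENS:
        raise FormatError(f"cannot parse boolean {value!r} in {where}")
    return _BOOL_TOKENS[tok]


def read_beta_matrix(path, detection_path=None) -> BetaMatrix:
    """Read a probe-by-sample β matrix from TSV.

    Raises :class:`FormatError` naming the offending probe and sample for
    out-of-range values, and on duplicate ids or empty input.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise FormatError(f"no probes in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric beta value in {path}: {exc}") from exc
    fail = None
    if detection_path is not None:
        fail = read_bool_matrix(detection_path)
        fail = fail.reindex(index=df.index, columns=df.columns)
        if fail.isna().any().any():
            raise FormatError("detection mask does not cover the beta matrix")
        fail = fail.astype(bool)
    return BetaMatrix(df, fail)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.df.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6f")


def read_bool_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.map(lambda v: _parse_bool(v, str(path)))


def write_bool_matrix(mask: pd.DataFrame, path) -> None:
    mask.astype(int).to_csv(path, sep="\t", index_label="probe_id")


def read_manifest(path) -> ProbeManifest:
    df = pd.read_csv(path, dtype={"probe_id": str, "chrom": str})
    required = ["probe_id", "chrom", "pos", "genes", "region", "cgi",
                "flag_snp", "flag_ch", "flag_xreactive"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} missing column(s): {missing}")
    df = df.set_index("probe_id")
    genes = df["genes"].fillna("")
    df["genes"] = [[] if g == "" else [p.strip().upper() for p in g.split(";") if p.strip()]
                   for g in genes]
    for col in ("cgi", "flag_snp", "flag_ch", "flag_xreactive"):
        df[col] = [_parse_bool(v, f"manifest column {col}") for v in df[col]]
    df["pos"] = df["pos"].astype(int)
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path) -> None:
    df = manifest.df.copy()
    df["genes"] = [";".join(g) for g in df["genes"]]
    for col in ("cgi", "flag_snp", "flag_ch", "flag_xreactive"):
        df[col] = df[col].astype(int)
    df.to_csv(path, index_label="probe_id")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str,
                                  "slide": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"sample sheet {path} missing column 'sample_id'")
    if "group" not in df.columns:
        raise FormatError(f"sample sheet {path} missing column 'group'")
    df = df.set_index("sample_id")
    if "pasi" in df.columns:
        df["pasi"] = pd.to_numeric(df["pasi"], errors="raise")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="raise")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, "
                                  f"description and >=1 gene")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g.strip()]
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in collection.names:
            desc = descriptions.get(name, name)
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def write_dmp_table(dmps: pd.DataFrame, path) -> None:
    df = dmps.copy()
    if "genes" in df.columns:
        df["genes"] = [";".join(g) if isinstance(g, (list, tuple, set)) else g
                       for g in df["genes"]]
    df.to_csv(path, index_label="probe_id")


def write_dmr_tables(dmrs: pd.DataFrame, bed_path, csv_path) -> None:
    """Write DMRs as BED (0-based half-open) plus a statistics CSV.

    Internal DMR coordinates are already 0-based half-open; the CSV carries
    the same coordinates alongside the statistics.
    """
    with open(bed_path, "w") as fh:
        for i, row in dmrs.iterrows():
            name = f"DMR_{i}"
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{name}\t"
                     f"{row['n_cpg']}\n")
    df = dmrs.copy()
    if "probes" in df.columns:
        df["probes"] = [";".join(p) for p in df["probes"]]
    df.to_csv(csv_path, index_label="dmr_id")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
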