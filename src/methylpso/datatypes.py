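"""Validated in-memory containers for methylation-array data.

The pipeline works with four primary objects:

* :class:`ProbeManifest` — per-probe genomic annotation (chromosome, position,
  gene mapping, region class, QC flags) in Illumina-manifest style.
* :class:`BetaMatrix` / :class:`MMatrix` — probe-by-sample methylation values on
  the proportion (β) and logit2 (M) scales respectively.
* :class:`SampleSheet` — per-sample phenotype: group, age, sex, slide (batch),
  PASI disease-activity score and treatment timepoint.
* :class:`GeneSetCollection` — named gene-symbol sets (GMT-style), e.g. type I /
  type II interferon-regulated genes or an IL-17/TNF pathway list.

Containers validate on construction and raise :class:`FormatError` /
:class:`ConfigError` rather than silently coercing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

REGIONS = ("TSS1500", "TSS200", "5'UTR", "Body", "3'UTR", "IGR")
PROMOTER_REGIONS = ("TSS1500", "TSS200", "5'UTR")
GROUPS = ("HC", "PsO", "PsA")
SEXES = ("M", "F")
TIMEPOINTS = ("naive", "post1", "post2")

#: clipping margin used when mapping β to the logit scale
BETA_EPS = 0.001


class FormatError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration or precondition violation."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what} id(s): {dup}")


@dataclass
class ProbeManifest:
    """Per-probe annotation table indexed by probe id.

    Columns: ``chrom`` (str), ``pos`` (1-based int), ``genes`` (list of gene
    symbols, possibly empty), ``region`` (one of :data:`REGIONS`), ``cgi``
    (bool, CpG-island flag) and boolean QC flags ``flag_snp``, ``flag_ch``,
    ``flag_xreactive``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "genes", "region", "cgi",
                    "flag_snp", "flag_ch", "flag_xreactive"}
        missing = required - set(self.df.columns)
        if missing:
            raise FormatError(f"manifest missing column(s): {sorted(missing)}")
        _check_unique(self.df.index, "probe")
        if (self.df["pos"] < 1).any():
            bad = self.df.index[self.df["pos"] < 1][0]
            raise FormatError(f"manifest position < 1 at probe {bad!r}")
        unknown = set(self.df["region"].unique()) - set(REGIONS)
        if unknown:
            raise FormatError(f"unknown region token(s): {sorted(unknown)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def promoter_mask(self) -> pd.Series:
        """Boolean mask of probes in promoter context (TSS1500/TSS200/5'UTR)."""
        return self.df["region"].isin(PROMOTER_REGIONS)

    def genes_for(self, probe_ids: Iterable[str]) -> set[str]:
        """Union of gene symbols annotated to the given probes."""
        out: set[str] = set()
        for genes in self.df.loc[list(probe_ids), "genes"]:
            out.update(genes)
        return out

    def subset(self, probe_ids: Iterable[str]) -> "ProbeManifest":
        return ProbeManifest(self.df.loc[list(probe_ids)].copy())


@dataclass
class BetaMatrix:
    """Probe-by-sample β values in [0, 1].

    ``detection_fail`` is an optional probe-by-sample boolean mask marking
    detection-p failures (True = failed).
    """

    df: pd.DataFrame
    detection_fail: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "probe")
        _check_unique(self.df.columns, "sample")
        if self.df.shape[0] == 0:
            raise FormatError("no probes")
        vals = self.df.to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < 0.0) | (vals > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value out of [0,1] at probe {self.df.index[i]!r}, "
                f"sample {self.df.columns[j]!r}: {self.df.iat[i, j]!r}"
            )
        if self.detection_fail is not None:
            if not self.detection_fail.index.equals(self.df.index) or \
               not self.detection_fail.columns.equals(self.df.columns):
                raise FormatError("detection_fail mask does not match beta matrix axes")

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.columns

    def subset_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        ids = list(probe_ids)
        fail = None if self.detection_fail is None else self.detection_fail.loc[ids]
        return BetaMatrix(self.df.loc[ids], fail)

    def subset_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        ids = list(sample_ids)
        fail = None if self.detection_fail is None else self.detection_fail[ids]
        return BetaMatrix(self.df[ids], fail)


@dataclass
class MMatrix:
    """Probe-by-sample M values, M = log2(β / (1 − β))."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "probe")
        _check_unique(self.df.columns, "sample")
        if not np.isfinite(self.df.to_numpy(dtype=float)).all():
            raise FormatError("non-finite M value")

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.columns

    def subset_samples(self, sample_ids: Iterable[str]) -> "MMatrix":
        return MMatrix(self.df[list(sample_ids)])


@dataclass
class SampleSheet:
    """Per-sample phenotype table indexed by sample id.

    Columns: ``subject_id``, ``group`` (HC/PsO/PsA), ``age`` (years), ``sex``
    (M/F), ``slide`` (batch label), ``pasi`` (float, NaN allowed — healthy
    controls have no PASI), ``timepoint`` (naive/post1/post2 or NaN).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.df.columns:
            raise FormatError("sample sheet missing required column 'group'")
        _check_unique(self.df.index, "sample")
        unknown = set(self.df["group"].unique()) - set(GROUPS)
        if unknown:
            raise FormatError(f"unknown group label(s): {sorted(unknown)}")
        if "sex" in self.df.columns:
            vals = set(self.df["sex"].dropna().unique()) - set(SEXES)
            if vals:
                raise FormatError(f"unknown sex label(s): {sorted(vals)}")
        if "timepoint" in self.df.columns:
            vals = set(self.df["timepoint"].dropna().unique()) - set(TIMEPOINTS)
            if vals:
                raise FormatError(f"unknown timepoint label(s): {sorted(vals)}")
        if "pasi" in self.df.columns:
            pasi = pd.to_numeric(self.df["pasi"], errors="coerce")
            if ((pasi < 0) & pasi.notna()).any():
                raise FormatError("negative PASI value")

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    @property
    def group(self) -> pd.Series:
        return self.df["group"]

    def resolve_groups(self, spec: str) -> list[str]:
        """Resolve a group-algebra expression to sample ids.

        ``"PsO+PsA"`` denotes the union of groups; single labels name one
        group. Unknown labels raise :class:`ConfigError`.
        """
        labels = [s.strip() for s in spec.split("+")]
        for lab in labels:
            if lab not in GROUPS:
                raise ConfigError(f"unknown group {lab!r} in contrast spec {spec!r}")
        mask = self.df["group"].isin(labels)
        return list(self.df.index[mask])

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        return SampleSheet(self.df.loc[list(sample_ids)].copy())


class GeneSetCollection(Mapping[str, frozenset]):
    """Named gene-symbol sets; symbols are uppercased on construction."""

    def __init__(self, sets: Mapping[str, Iterable[str]]):
        self._sets: dict[str, frozenset] = {}
        for name, genes in sets.items():
            if name in self._sets:
                raise FormatError(f"duplicate gene-set name {name!r}")
            self._sets[name] = frozenset(g.upper() for g in genes)

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def all_genes(self) -> frozenset:
        out: set[str] = set()
        for s in self._sets.values():
            out |= s
        return frozenset(out)


def align_samples(beta: BetaMatrix | MMatrix, sheet: SampleSheet):
    """Check that matrix and sample sheet describe exactly the same samples.

    Samples present in only one source are an error, never silently dropped —
    silent sample loss corrupts group statistics. Returns ``(matrix, sheet)``
    with the sheet reordered to the matrix column order.
    """
    mat_ids = set(beta.sample_ids)
    sheet_ids = set(sheet.sample_ids)
    only_mat = sorted(mat_ids - sheet_ids)
    only_sheet = sorted(sheet_ids - mat_ids)
    if only_mat or only_sheet:
        raise FormatError(
            f"sample mismatch between matrix and sheet: "
            f"matrix-only={only_mat[:5]}, sheet-only={only_sheet[:5]}"
        )
    return beta, sheet.subset(list(beta.sample_ids))


@dataclass
class FilterReport:
    """Accounting of probe-level QC filtering."""

    n_input: int
    n_detection_fail: int
    n_snp: int
    n_ch: int
    n_xreactive: int
    n_retained: int
    removed: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_detection_fail": self.n_detection_fail,
            "n_snp": self.n_snp,
            "n_ch": self.n_ch,
            "n_xreactive": self.n_xreactive,
            "n_retained": self.n_retained,
            "removed": {k: sorted(v) for k, v in self.removed.items()},
        }
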