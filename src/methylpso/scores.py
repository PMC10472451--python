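"""Gene-set methylation scores and interferon-membership classification.

A score model standardizes each member DMP against the healthy-control (HC)
group:

    SV = (value − Mean_HC) / SD_HC

with Mean_HC and SD_HC computed exclusively on HC samples (population SD by
default, so every SV has mean 0 and SD exactly 1 over HC). Per-sample total
score = sum of SVs over member probes; the HC mean total score is therefore
0 by construction, and disease-associated deviations show up as non-zero
totals.

`correlation_filter_score` implements the disease-activity-tracking variant:
member probes are first filtered on the Pearson correlation between their β
values and PASI across samples with a recorded PASI, keeping only probes with
|r| above a cutoff (default 0.7), before the HC-standardized score is fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import BetaMatrix, ConfigError, FormatError, SampleSheet, align_samples
from .stats import TestResult, compare_groups

IFN_LABELS = ("type I only", "type II only", "type I+II", "non-IFN")


@dataclass
class IfnClassification:
    """Four-way partition of genes by interferon-pathway membership."""

    labels: dict[str, str]

    @property
    def counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in IFN_LABELS}
        for lab in self.labels.values():
            out[lab] += 1
        return out

    @property
    def percentages(self) -> dict[str, float]:
        n = len(self.labels)
        return {lab: round(100.0 * c / n, 1) for lab, c in self.counts.items()}

    @property
    def n_ifn_related(self) -> int:
        return sum(c for lab, c in self.counts.items() if lab != "non-IFN")

    @property
    def ifn_related_percent(self) -> float:
        return round(100.0 * self.n_ifn_related / len(self.labels), 1)

    def table(self) -> pd.DataFrame:
        counts = self.counts
        pct = self.percentages
        return pd.DataFrame({"count": counts, "percent": pct})


def classify_ifn(dmp_genes, ifn1, ifn2) -> IfnClassification:
    """Partition differentially methylated genes by type I / type II IFN
    membership; proportions are reported to one decimal."""
    genes = {g.upper() for g in dmp_genes}
    if not genes:
        raise ConfigError("empty gene list")
    s1 = {g.upper() for g in ifn1}
    s2 = {g.upper() for g in ifn2}
    labels = {}
    for g in sorted(genes):
        in1, in2 = g in s1, g in s2
        if in1 and in2:
            labels[g] = "type I+II"
        elif in1:
            labels[g] = "type I only"
        elif in2:
            labels[g] = "type II only"
        else:
            labels[g] = "non-IFN"
    return IfnClassification(labels)


@dataclass
class ScoreModel:
    """HC-reference standardization parameters for one gene set."""

    gene_set_name: str
    probe_ids: list[str]
    mean_hc: pd.Series
    sd_hc: pd.Series
    sd_ddof: int = 0
    excluded_zero_sd: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gene_set_name": self.gene_set_name,
            "probe_ids": list(self.probe_ids),
            "mean_hc": self.mean_hc.to_dict(),
            "sd_hc": self.sd_hc.to_dict(),
            "sd_ddof": self.sd_ddof,
            "excluded_zero_sd": list(self.excluded_zero_sd),
        }


@dataclass
class ScoreResult:
    """Per-sample standardized values and total scores."""

    sv: pd.DataFrame            # probes x samples
    total: pd.Series            # per sample
    groups: pd.Series | None = None

    def group_test(self, group_a: str, group_b: str) -> TestResult:
        """Two-sided Mann–Whitney on total scores between two groups."""
        if self.groups is None:
            raise ConfigError("no group labels attached to score result")
        a = self.total[self.groups == group_a]
        b = self.total[self.groups == group_b]
        return compare_groups(a.to_numpy(), b.to_numpy(), kind="mwu")


def _member_probes(dmps: pd.DataFrame, gene_set) -> list[str]:
    if "genes" not in dmps.columns:
        raise ConfigError("DMP table lacks gene annotation; pass a manifest "
                          "when calling DMPs")
    gs = {g.upper() for g in gene_set}
    return [pid for pid, genes in dmps["genes"].items()
            if gs & {g.upper() for g in genes}]


def fit_score_model(beta: BetaMatrix, sheet: SampleSheet, dmps: pd.DataFrame,
                    gene_set, gene_set_name: str = "score",
                    sd_ddof: int = 0) -> ScoreModel:
    """Fit Mean_HC / SD_HC over the HC samples for every DMP whose gene
    annotation intersects `gene_set`. Zero-variance probes are excluded with
    a warning; an empty member set is an error."""
    beta, sheet = align_samples(beta, sheet)
    hc_ids = sheet.resolve_groups("HC")
    if len(hc_ids) < 2:
        raise ConfigError("need at least 2 HC samples to fit a score model")
    members = _member_probes(dmps, gene_set)
    if not members:
        raise ConfigError("empty score set: no DMP maps to the gene set")
    hc = beta.df.loc[members, hc_ids]
    mean_hc = hc.mean(axis=1)
    sd_hc = hc.std(axis=1, ddof=sd_ddof)
    zero = sd_hc.index[sd_hc == 0.0].tolist()
    if zero:
        warnings.warn(f"excluding {len(zero)} zero-variance probe(s) from "
                      f"score model: {zero[:5]}")
        members = [p for p in members if p not in set(zero)]
        if not members:
            raise ConfigError("empty score set after zero-variance exclusion")
        mean_hc = mean_hc.loc[members]
        sd_hc = sd_hc.loc[members]
    return ScoreModel(gene_set_name, members, mean_hc, sd_hc, sd_ddof, zero)


def score_samples(model: ScoreModel, beta: BetaMatrix,
                  sheet: SampleSheet | None = None) -> ScoreResult:
    """Standardized values and total score per sample."""
    missing = [p for p in model.probe_ids if p not in beta.df.index]
    if missing:
        raise FormatError(f"probe(s) missing from matrix: {missing[:5]}")
    vals = beta.df.loc[model.probe_ids]
    sv = vals.sub(model.mean_hc, axis=0).div(model.sd_hc, axis=0)
    total = sv.sum(axis=0)
    groups = None
    if sheet is not None:
        _, sheet = align_samples(beta, sheet)
        groups = sheet.group
    return ScoreResult(sv=sv, total=total, groups=groups)


@dataclass
class FilteredScore:
    """Outcome of the PASI-correlation-filtered score."""

    kept_probes: list[str]
    probe_r: pd.Series
    model: ScoreModel
    result: ScoreResult
    r_score_vs_pasi: float
    p_score_vs_pasi: float


def correlation_filter_score(beta: BetaMatrix, sheet: SampleSheet,
                             dmps: pd.DataFrame, pathway_set,
                             pathway_name: str = "pathway",
                             r_threshold: float = 0.7,
                             sd_ddof: int = 0) -> FilteredScore:
    """Disease-activity-filtered gene-set score.

    Candidate probes are the DMPs mapping to `pathway_set`. For each, the
    Pearson correlation between β and PASI is computed over the samples with
    a recorded PASI; only probes with |r| strictly above `r_threshold` are
    kept. The score model is then fit on HC samples and the correlation of
    total scores with PASI is reported.
    """
    beta, sheet = align_samples(beta, sheet)
    if "pasi" not in sheet.df.columns:
        raise ConfigError("sample sheet has no 'pasi' column")
    pasi = pd.to_numeric(sheet.df["pasi"], errors="coerce")
    with_pasi = pasi.index[pasi.notna()].tolist()
    if len(with_pasi) < 3:
        raise ConfigError("need at least 3 samples with PASI")
    pasi_vals = pasi.loc[with_pasi].to_numpy(float)
    if np.ptp(pasi_vals) == 0:
        raise ConfigError("PASI values all equal: correlation undefined")

    candidates = _member_probes(dmps, pathway_set)
    if not candidates:
        raise ConfigError("no DMP maps to the pathway gene set")
    sub = beta.df.loc[candidates, with_pasi]
    r_values = {}
    for pid in candidates:
        x = sub.loc[pid].to_numpy(float)
        if np.ptp(x) == 0:
            warnings.warn(f"dropping constant probe {pid!r} (undefined r)")
            continue
        r_values[pid] = float(sps.pearsonr(x, pasi_vals).statistic)
    probe_r = pd.Series(r_values, dtype=float)
    kept = probe_r.index[probe_r.abs() > r_threshold].tolist()
    if not kept:
        raise ConfigError(f"no probe passes |r| > {r_threshold}")

    kept_dmps = dmps.loc[kept]
    model = fit_score_model(beta, sheet, kept_dmps, pathway_set,
                            gene_set_name=pathway_name, sd_ddof=sd_ddof)
    result = score_samples(model, beta, sheet)
    totals = result.total.loc[with_pasi].to_numpy(float)
    r, p = sps.pearsonr(totals, pasi_vals)
    return FilteredScore(kept_probes=kept, probe_r=probe_r, model=model,
                         result=result, r_score_vs_pasi=float(r),
                         p_score_vs_pasi=float(p))
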