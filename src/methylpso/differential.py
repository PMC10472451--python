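"""Differentially methylated position (DMP) and region (DMR) calling.

DMPs: per-probe ordinary least squares on M values with covariates, followed
by empirical-Bayes variance shrinkage toward a scaled inverse-chi-square
prior (the moderated t-test). The prior degrees of freedom d0 and prior
variance s0² are fit by the method of moments on the log sample variances,
with a Newton solve of the inverse trigamma. The moderated statistic for
probe g is

    t_g = beta_g / (s̃_g * sqrt(v)),   s̃²_g = (d0*s0² + d_g*s²_g) / (d0 + d_g)

on d0 + d_g degrees of freedom. A probe is a DMP when its BH-adjusted p is
below `q_threshold` and the group-mean β difference exceeds
`delta_beta_threshold` in magnitude (defaults 0.05 and 0.1).

DMRs: transparent greedy clustering of individually qualifying probes —
consecutive qualifying CpGs on a chromosome with inter-probe gap at most
`max_gap_bp` form a candidate, candidates with at least `min_cpg` probes are
emitted with a Stouffer-combined p (BH-adjusted across candidates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .datatypes import (
    BetaMatrix,
    ConfigError,
    FormatError,
    MMatrix,
    ProbeManifest,
    PROMOTER_REGIONS,
    SampleSheet,
    align_samples,
)
from .preprocess import _covariate_design
from .stats import bh_adjust

#: prior-df value treated as "effectively infinite"
D0_CAP = 1e6


@dataclass
class ModeratedFitParams:
    """Empirical-Bayes variance-shrinkage hyperparameters."""

    d0: float           # prior degrees of freedom (np.inf allowed)
    s0_sq: float        # prior variance
    df_resid: float     # residual df per probe (common design)

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_resid


def trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ConfigError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def fit_f_dist(s_sq: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of (d0, s0²) from per-probe sample variances with common
    residual df, on the log scale (unbiased via digamma/trigamma offsets)."""
    s_sq = np.maximum(np.asarray(s_sq, float), 1e-300)
    z = np.log(s_sq)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        if d0 > D0_CAP:
            d0 = np.inf
            s0_sq = float(np.exp(z.mean()))
        else:
            s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                                 - np.log(d0 / 2.0)))
    else:
        # no excess dispersion beyond sampling noise: variances are shared
        d0 = np.inf
        s0_sq = float(np.exp(z.mean()))
    return d0, s0_sq


def _design_for_contrast(sheet: SampleSheet, contrast, covariates):
    ref_spec, comp_spec = contrast
    ref_ids = sheet.resolve_groups(ref_spec)
    comp_ids = sheet.resolve_groups(comp_spec)
    overlap = set(ref_ids) & set(comp_ids)
    if overlap:
        raise ConfigError(f"contrast groups overlap: {sorted(overlap)[:5]}")
    if len(ref_ids) < 2 or len(comp_ids) < 2:
        raise ConfigError("each contrast group needs at least 2 samples")
    ids = ref_ids + comp_ids
    sub = sheet.subset(ids)
    indicator = np.array([0.0] * len(ref_ids) + [1.0] * len(comp_ids))
    C, cov_names = _covariate_design(sub, covariates)
    # drop covariate columns constant within the contrast subset
    keep = [j for j in range(C.shape[1]) if np.ptp(C[:, j]) > 0]
    C = C[:, keep]
    cov_names = [cov_names[j] for j in keep]
    X = np.column_stack([np.ones(len(ids)), indicator, *C.T]) \
        if C.size else np.column_stack([np.ones(len(ids)), indicator])
    return ids, ref_ids, comp_ids, X, cov_names


def fit_moderated(m: MMatrix, sheet: SampleSheet, contrast,
                  covariates=(), prior_df: float | None = None,
                  prior_var: float | None = None):
    """Per-probe moderated t for `contrast` = (reference_spec, comparison_spec).

    Group specs use '+' for unions (e.g. ``("HC", "PsO+PsA")``). Covariates
    are sample-sheet columns entering the linear model alongside the group
    indicator. ``prior_df`` overrides the fitted d0 (0 recovers the ordinary
    per-probe t; ``np.inf`` gives the fully pooled-variance t).

    Returns ``(stats_df, params)`` where stats_df has one row per probe with
    columns coef (M-scale group difference), s_sq, t_mod, p, df.
    """
    m, sheet = align_samples(m, sheet)
    ids, ref_ids, comp_ids, X, _ = _design_for_contrast(sheet, contrast, covariates)
    Y = m.df[ids].to_numpy(float).T          # samples x probes
    n, p_cols = X.shape
    df_resid = n - p_cols
    if df_resid < 1:
        raise ConfigError("zero residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ Y                 # p_cols x probes
    resid = Y - X @ coef
    s_sq = (resid ** 2).sum(axis=0) / df_resid
    v = xtx_inv[1, 1]                        # unscaled variance of the group coef

    if prior_df is None:
        d0, s0_sq = fit_f_dist(s_sq, df_resid)
    else:
        d0 = float(prior_df)
        if prior_var is not None:
            s0_sq = float(prior_var)
        elif d0 == 0:
            s0_sq = float(np.mean(s_sq))     # unused when d0 = 0
        else:
            _, s0_sq = fit_f_dist(s_sq, df_resid)
            if not np.isfinite(d0):
                s0_sq = float(np.mean(s_sq))

    if np.isinf(d0):
        s_post = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_post = (d0 * s0_sq + df_resid * s_sq) / (d0 + df_resid)
        df_total = d0 + df_resid

    beta1 = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = beta1 / np.sqrt(s_post * v)
    t_mod = np.where(np.isfinite(t_mod), t_mod, 0.0)
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * sps.t.sf(np.abs(t_mod), df_total)
    # identical group values => zero effect, zero variance: p = 1 by contract
    p = np.where((beta1 == 0.0), 1.0, p)

    stats_df = pd.DataFrame(
        {"coef": beta1, "s_sq": s_sq, "t_mod": t_mod, "p": p,
         "df": df_total}, index=m.df.index)
    params = ModeratedFitParams(d0=d0, s0_sq=s0_sq, df_resid=df_resid)
    params.ref_ids = ref_ids
    params.comp_ids = comp_ids
    return stats_df, params


def dmp_statistics(m: MMatrix, beta: BetaMatrix, sheet: SampleSheet, contrast,
                   covariates=(), prior_df: float | None = None):
    """Full per-probe table: moderated t, BH q and β-scale effect size.

    Δβ = mean β(comparison) − mean β(reference), computed on the supplied
    (normalized) β matrix; its sign defines hypo- (negative) versus
    hypermethylation in the comparison group.
    """
    if not beta.probe_ids.equals(m.probe_ids):
        raise FormatError("beta and M matrices list different probes")
    stats_df, params = fit_moderated(m, sheet, contrast, covariates, prior_df)
    b = beta.df
    delta = b[params.comp_ids].mean(axis=1) - b[params.ref_ids].mean(axis=1)
    stats_df = stats_df.copy()
    stats_df["delta_beta"] = delta
    stats_df["q"] = bh_adjust(stats_df["p"].to_numpy())
    return stats_df, params


def call_dmps(m: MMatrix, beta: BetaMatrix, sheet: SampleSheet, contrast,
              covariates=(), q_threshold: float = 0.05,
              delta_beta_threshold: float = 0.1,
              manifest: ProbeManifest | None = None,
              prior_df: float | None = None) -> pd.DataFrame:
    """Call DMPs for one contrast: q < q_threshold and |Δβ| > delta_beta_threshold.

    Returns a DataFrame indexed by probe id with columns contrast, delta_beta,
    t_mod, p, q, direction (hypo/hyper) and, when a manifest is given, genes
    and region.
    """
    stats_df, _ = dmp_statistics(m, beta, sheet, contrast, covariates, prior_df)
    keep = (stats_df["q"] < q_threshold) & \
           (stats_df["delta_beta"].abs() > delta_beta_threshold)
    out = stats_df.loc[keep, ["delta_beta", "t_mod", "p", "q"]].copy()
    out.insert(0, "contrast", f"{contrast[0]} vs {contrast[1]}")
    out["direction"] = np.where(out["delta_beta"] < 0, "hypo", "hyper")
    if manifest is not None:
        ann = manifest.df.loc[out.index]
        out["genes"] = list(ann["genes"])
        out["region"] = list(ann["region"])
    return out


def summarize_dmps(dmps: pd.DataFrame) -> tuple[int, int, int, int]:
    """(n_hypo, n_hyper, n_total, n_unique_genes) for a DMP table.

    Multi-gene probes contribute all their symbols to the unique-gene union;
    gene-less probes contribute none.
    """
    if len(dmps) == 0:
        return (0, 0, 0, 0)
    n_hypo = int((dmps["direction"] == "hypo").sum())
    n_hyper = int((dmps["direction"] == "hyper").sum())
    genes: set[str] = set()
    if "genes" in dmps.columns:
        for g in dmps["genes"]:
            genes.update(g)
    return (n_hypo, n_hyper, n_hypo + n_hyper, len(genes))


def promoter_subset(dmps: pd.DataFrame,
                    manifest: ProbeManifest) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict DMPs to promoter context (TSS1500/TSS200/5'UTR) and partition
    into (hypo, hyper) tables."""
    regions = manifest.df.loc[dmps.index, "region"]
    prom = dmps.loc[regions.isin(PROMOTER_REGIONS).to_numpy()]
    return (prom.loc[prom["direction"] == "hypo"],
            prom.loc[prom["direction"] == "hyper"])


def call_dmrs(stats_df: pd.DataFrame, manifest: ProbeManifest,
              min_cpg: int = 5, max_gap_bp: int = 1000,
              q_threshold: float = 0.05, delta_beta_threshold: float = 0.1,
              combine: str = "stouffer") -> pd.DataFrame:
    """Aggregate qualifying probes into differentially methylated regions.

    `stats_df` is the full per-probe table from :func:`dmp_statistics`
    (all probes, not just called DMPs). Probes must appear position-sorted
    within each chromosome of the manifest.
    """
    if combine not in ("stouffer", "min_q"):
        raise ConfigError(f"unknown combine rule {combine!r}")
    ann = manifest.df.loc[stats_df.index]
    for _, sub in ann.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise FormatError("manifest probes not position-sorted within chromosome")
    qual = stats_df.loc[(stats_df["q"] < q_threshold) &
                        (stats_df["delta_beta"].abs() > delta_beta_threshold)]
    if len(qual) == 0:
        return _empty_dmr_table()
    qual_ann = ann.loc[qual.index]
    order = np.lexsort((qual_ann["pos"].to_numpy(),
                        qual_ann["chrom"].to_numpy()))
    probes = qual_ann.index.to_numpy()[order]
    chroms = qual_ann["chrom"].to_numpy()[order]
    poss = qual_ann["pos"].to_numpy()[order]

    clusters: list[list[int]] = []
    current = [0]
    for i in range(1, len(probes)):
        if chroms[i] == chroms[i - 1] and poss[i] - poss[i - 1] <= max_gap_bp:
            current.append(i)
        else:
            clusters.append(current)
            current = [i]
    clusters.append(current)

    rows = []
    for cluster in clusters:
        if len(cluster) < min_cpg:
            continue
        ids = list(probes[cluster])
        member = stats_df.loc[ids]
        z = np.sign(member["t_mod"]) * sps.norm.isf(
            np.clip(member["p"], 1e-300, 1.0) / 2.0)
        z_comb = z.sum() / np.sqrt(len(ids))
        p_comb = 2.0 * sps.norm.sf(abs(z_comb))
        rows.append({
            "chrom": chroms[cluster[0]],
            "start": int(poss[cluster[0]]) - 1,   # 0-based half-open
            "end": int(poss[cluster[-1]]),
            "n_cpg": len(ids),
            "probes": ids,
            "mean_delta_beta": float(member["delta_beta"].mean()),
            "p_comb": float(p_comb),
            "min_q": float(member["q"].min()),
        })
    if not rows:
        return _empty_dmr_table()
    out = pd.DataFrame(rows)
    if combine == "stouffer":
        out["q_comb"] = bh_adjust(out["p_comb"].to_numpy())
    else:
        out["q_comb"] = out["min_q"]
    return out.reset_index(drop=True)


def _empty_dmr_table() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "n_cpg", "probes",
                                 "mean_delta_beta", "p_comb", "min_q", "q_comb"])
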