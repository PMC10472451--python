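"""Probe QC filtering, β↔M conversion, quantile normalization and
empirical-Bayes batch adjustment.

The statistical modeling in this package runs on M values
(M = log2(β / (1 − β)), variance-stabilized), while effect sizes and scores
are reported on the β scale; β is clipped to [ε, 1 − ε] (ε = 0.001 by
default) before the logit so M stays finite.

Batch adjustment is the parametric empirical-Bayes location/scale model
(ComBat): per-probe standardization under a covariate design that protects
the biological terms, per-batch location (γ) and scale (δ²) estimates shrunk
toward a normal and an inverse-gamma prior fit by the method of moments, then
removal of the shrunken effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    BETA_EPS,
    BetaMatrix,
    ConfigError,
    FilterReport,
    FormatError,
    MMatrix,
    ProbeManifest,
    SampleSheet,
    align_samples,
)


def filter_probes(beta: BetaMatrix, manifest: ProbeManifest,
                  max_fail_fraction: float = 0.0) -> tuple[BetaMatrix, FilterReport]:
    """Remove flagged and detection-failed probes.

    A probe is removed when it is flagged as SNP-associated, non-CpG (CH) or
    cross-reactive in the manifest, or when its detection-failure fraction
    across samples exceeds ``max_fail_fraction`` (the default 0.0 drops a
    probe failing in any sample, the strictest reading). Categories may
    overlap; the union is removed once.
    """
    missing = beta.probe_ids.difference(manifest.probe_ids)
    if len(missing):
        raise FormatError(f"manifest does not cover probe(s): "
                          f"{list(missing[:5])}")
    ann = manifest.df.loc[beta.probe_ids]
    removed: dict[str, set] = {
        "snp": set(beta.probe_ids[ann["flag_snp"].to_numpy(bool)]),
        "ch": set(beta.probe_ids[ann["flag_ch"].to_numpy(bool)]),
        "xreactive": set(beta.probe_ids[ann["flag_xreactive"].to_numpy(bool)]),
        "detection": set(),
    }
    if beta.detection_fail is not None:
        frac = beta.detection_fail.mean(axis=1)
        removed["detection"] = set(frac.index[frac > max_fail_fraction])
    union = set().union(*removed.values())
    keep = [p for p in beta.probe_ids if p not in union]
    if not keep:
        raise FormatError("zero probes retained after filtering")
    report = FilterReport(
        n_input=len(beta.probe_ids),
        n_detection_fail=len(removed["detection"]),
        n_snp=len(removed["snp"]),
        n_ch=len(removed["ch"]),
        n_xreactive=len(removed["xreactive"]),
        n_retained=len(keep),
        removed={k: sorted(v) for k, v in removed.items()},
    )
    return beta.subset_probes(keep), report


def beta_to_m(beta: BetaMatrix, epsilon: float = BETA_EPS) -> MMatrix:
    """M = log2(β / (1 − β)) after clipping β to [ε, 1 − ε]."""
    b = beta.df.clip(lower=epsilon, upper=1.0 - epsilon)
    return MMatrix(np.log2(b / (1.0 - b)))


def m_to_beta(m: MMatrix) -> BetaMatrix:
    """Inverse logit2: β = 2^M / (1 + 2^M)."""
    e = np.exp2(m.df)
    return BetaMatrix(e / (1.0 + e))


def quantile_normalize(m: MMatrix) -> MMatrix:
    """Force every sample onto the mean-of-sorted-columns reference
    distribution; ties within a column receive the mean of the reference
    values over their rank span."""
    X = m.df.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_probes)
        assigned[order] = ref
        # average over tie groups
        vals, inv = np.unique(col, return_inverse=True)
        if vals.size < n_probes:
            sums = np.bincount(inv, weights=assigned)
            counts = np.bincount(inv)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    return MMatrix(pd.DataFrame(out, index=m.df.index, columns=m.df.columns))


@dataclass
class BatchModel:
    """Fitted location/scale batch effects, for audit.

    ``gamma_star`` and ``delta_star_sq`` are per-batch, per-probe shrunken
    effects on the standardized scale; ``gamma_star_m`` converts the location
    effect back to M units. ``hyperparams`` holds the per-batch prior fit.
    """

    batches: list[str]
    gamma_star: pd.DataFrame          # batches x probes (standardized)
    delta_star_sq: pd.DataFrame       # batches x probes
    gamma_star_m: pd.DataFrame        # batches x probes (M units)
    hyperparams: pd.DataFrame         # per batch: gamma_bar, tau_sq, a_prior, b_prior
    covariates: list[str]


def _covariate_design(sheet: SampleSheet, covariates) -> tuple[np.ndarray, list[str]]:
    """Build a no-intercept covariate design (numeric columns as-is,
    categoricals as drop-first dummies)."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    df = sheet.df
    for cov in covariates:
        if cov not in df.columns:
            raise ConfigError(f"covariate {cov!r} not in sample sheet")
        series = df[cov]
        if pd.api.types.is_numeric_dtype(series):
            if series.isna().any():
                raise ConfigError(f"covariate {cov!r} has missing values")
            cols.append(series.to_numpy(float))
            names.append(cov)
        else:
            levels = pd.unique(series)
            for lev in levels[1:]:
                cols.append((series == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
    if not cols:
        return np.empty((len(df), 0)), []
    return np.column_stack(cols), names


def screen_covariates(m: MMatrix, sheet: SampleSheet,
                      candidates=("age", "sex", "group"),
                      n_components: int = 5, alpha: float = 0.05) -> dict[str, float]:
    """Associate candidate covariates with the top principal components of the
    M matrix (ANOVA for categoricals, correlation for numerics); returns the
    minimum p-value per covariate. Covariates with p < alpha are the ones
    worth protecting/adjusting; the decision is left to the caller."""
    X = m.df.to_numpy(float).T
    Xc = X - X.mean(axis=0)
    k = min(n_components, min(Xc.shape) - 1)
    if k < 1:
        raise ConfigError("too few samples for covariate screening")
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    pcs = Xc @ vt[:k].T
    out: dict[str, float] = {}
    for cov in candidates:
        if cov not in sheet.df.columns:
            continue
        series = sheet.df[cov]
        pvals = []
        for j in range(k):
            if pd.api.types.is_numeric_dtype(series):
                mask = series.notna().to_numpy()
                if mask.sum() < 3 or np.ptp(series[mask].to_numpy(float)) == 0:
                    continue
                pvals.append(sps.pearsonr(pcs[mask, j],
                                          series[mask].to_numpy(float)).pvalue)
            else:
                parts = [pcs[(series == lev).to_numpy(), j]
                         for lev in pd.unique(series.dropna())]
                parts = [p for p in parts if p.size >= 2]
                if len(parts) >= 2:
                    pvals.append(sps.f_oneway(*parts).pvalue)
        out[cov] = float(min(pvals)) if pvals else 1.0
    return out


def combat_adjust(m: MMatrix, sheet: SampleSheet, batch_var: str = "slide",
                  covariates=("age", "sex", "group"), tol: float = 1e-6,
                  max_iter: int = 200) -> tuple[MMatrix, BatchModel | None]:
    """Parametric empirical-Bayes location/scale batch adjustment on M values.

    Biological covariates enter the design and are protected: the batch
    effects are estimated orthogonally to them and only the batch terms are
    removed. A single-batch input is returned unchanged with a warning; a
    batch aliased with a protected covariate raises :class:`ConfigError`.
    """
    m, sheet = align_samples(m, sheet)
    if batch_var not in sheet.df.columns:
        raise ConfigError(f"batch variable {batch_var!r} not in sample sheet")
    batch = sheet.df[batch_var].astype(str)
    levels = list(pd.unique(batch))
    if len(levels) < 2:
        warnings.warn("single batch: no adjustment performed")
        return m, None
    sizes = np.array([(batch == lev).sum() for lev in levels])
    if (sizes < 2).any():
        small = [lev for lev, s in zip(levels, sizes) if s < 2]
        raise ConfigError(f"batch(es) with fewer than 2 samples: {small}")

    covariates = [c for c in covariates if c in sheet.df.columns]
    B = np.column_stack([(batch == lev).to_numpy(float) for lev in levels])
    C, cov_names = _covariate_design(sheet, covariates)
    X = np.hstack([B, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigError("batch confounded with protected covariate")

    Y = m.df.to_numpy(float).T          # samples x probes
    n = Y.shape[0]
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    grand = (sizes / n) @ coef[:len(levels)]           # per-probe grand mean
    stand_mean = grand[None, :] + C @ coef[len(levels):]
    resid = Y - X @ coef
    var_pooled = (resid ** 2).mean(axis=0)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd_pooled = np.sqrt(var_pooled)
    Z = (Y - stand_mean) / sd_pooled

    g_rows, d_rows, hyper_rows = [], [], []
    Z_adj = Z.copy()
    for lev, ni in zip(levels, sizes):
        idx = (batch == lev).to_numpy()
        Zi = Z[idx]
        g_hat = Zi.mean(axis=0)
        d_hat = Zi.var(axis=0, ddof=1)
        g_bar = g_hat.mean()
        tau_sq = g_hat.var(ddof=1)
        V = d_hat.mean()
        S = max(d_hat.var(ddof=1), 1e-12)
        a_prior = (2.0 * S + V ** 2) / S
        b_prior = (V * S + V ** 3) / S
        g_star = g_hat.copy()
        d_star = d_hat.copy()
        for _ in range(max_iter):
            g_new = (ni * tau_sq * g_hat + d_star * g_bar) / (ni * tau_sq + d_star)
            sum_sq = ((Zi - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * sum_sq + b_prior) / (ni / 2.0 + a_prior - 1.0)
            change = max(np.max(np.abs(g_new - g_star)),
                         np.max(np.abs(d_new - d_star)))
            g_star, d_star = g_new, d_new
            if change < tol:
                break
        Z_adj[idx] = (Zi - g_star[None, :]) / np.sqrt(d_star[None, :])
        g_rows.append(g_star)
        d_rows.append(d_star)
        hyper_rows.append((g_bar, tau_sq, a_prior, b_prior))

    Y_adj = Z_adj * sd_pooled + stand_mean
    adjusted = MMatrix(pd.DataFrame(Y_adj.T, index=m.df.index,
                                    columns=m.df.columns))
    probes = m.df.index
    model = BatchModel(
        batches=levels,
        gamma_star=pd.DataFrame(g_rows, index=levels, columns=probes),
        delta_star_sq=pd.DataFrame(d_rows, index=levels, columns=probes),
        gamma_star_m=pd.DataFrame(np.asarray(g_rows) * sd_pooled[None, :],
                                  index=levels, columns=probes),
        hyperparams=pd.DataFrame(hyper_rows, index=levels,
                                 columns=["gamma_bar", "tau_sq", "a_prior", "b_prior"]),
        covariates=cov_names,
    )
    return adjusted, model
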