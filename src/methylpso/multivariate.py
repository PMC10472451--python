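"""Unsupervised (PCA) and supervised (PLS-DA) projections of DMP methylation.

Samples are observations, DMP β values are features. PCA is the singular
value decomposition of the column-centered data; PLS-DA is NIPALS PLS2
regression of the centered data against a centered one-hot encoding of the
group labels (2- and 3-class cases handled natively). Neither scales
features to unit variance by default.

`correlation_circle` ranks probes by the Pearson correlation between their
values and a latent-component score vector — the standard way to read which
CpGs drive a PLS-DA component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import BetaMatrix, ConfigError, MMatrix


@dataclass
class LatentProjection:
    """Fitted low-dimensional projection."""

    method: str                      # "PCA" | "PLSDA"
    scores: pd.DataFrame             # samples x components
    loadings: pd.DataFrame           # probes x components
    explained_variance: np.ndarray   # fraction of (X) variance per component
    weights: pd.DataFrame | None = None   # PLS weight vectors


def _as_sample_matrix(data) -> tuple[np.ndarray, pd.Index, pd.Index]:
    """probes-x-samples container -> samples-x-probes array."""
    if isinstance(data, (BetaMatrix, MMatrix)):
        df = data.df
    else:
        df = data
    return df.to_numpy(float).T, df.columns, df.index


def pca(data, n_components: int = 2, scale: bool = False) -> LatentProjection:
    """Principal component analysis of column-centered sample data."""
    X, samples, probes = _as_sample_matrix(data)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ConfigError("PCA needs at least 2 samples and 2 probes")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd == 0, 1.0, sd)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        raise ConfigError(f"n_components={n_components} exceeds rank {rank}")
    total = (s ** 2).sum()
    frac = (s[:n_components] ** 2) / total
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    return LatentProjection(
        method="PCA",
        scores=pd.DataFrame(scores, index=samples, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=probes, columns=comp_names),
        explained_variance=frac,
    )


def _one_hot(groups: pd.Series | np.ndarray) -> tuple[np.ndarray, list[str]]:
    labels = pd.Series(groups).astype(str)
    levels = sorted(pd.unique(labels))   # stable under sample reordering
    Y = np.column_stack([(labels == lev).to_numpy(float) for lev in levels])
    return Y, levels


def nipals_pls(X: np.ndarray, Y: np.ndarray, n_components: int,
               tol: float = 1e-10, max_iter: int = 500):
    """NIPALS PLS2 on already-centered X (n x p) and Y (n x q).

    Deterministic initialization: u starts from the Y column with the largest
    variance. Returns (T, W, P, Q) — scores, weights, X-loadings, Y-loadings,
    each with `n_components` columns; X and Y are deflated in place copies.
    """
    X = X.copy()
    Y = Y.copy()
    n, p = X.shape
    T = np.zeros((n, n_components))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    for a in range(n_components):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        if np.allclose(u, 0):
            raise ConfigError("response deflated to zero; too many components")
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ConfigError("degenerate weight vector in NIPALS")
            w = w / nw
            t = X @ w
            q = Y.T @ t / (t @ t)
            u = Y @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol:
                break
            t_old = t
        p_load = X.T @ t / (t @ t)
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, q)
        T[:, a], W[:, a], P[:, a], Q[:, a] = t, w, p_load, q
    return T, W, P, Q


def plsda(data, groups, n_components: int = 2, scale: bool = False) -> LatentProjection:
    """PLS-DA: NIPALS PLS2 against centered one-hot group labels."""
    X, samples, probes = _as_sample_matrix(data)
    labels = pd.Series(np.asarray(groups), index=samples)
    Y, levels = _one_hot(labels)
    if len(levels) < 2:
        raise ConfigError("PLS-DA needs at least 2 groups")
    counts = Y.sum(axis=0)
    if (counts < 2).any():
        raise ConfigError("every group needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd == 0, 1.0, sd)
    Yc = Y - Y.mean(axis=0)
    T, W, P, Q = nipals_pls(Xc, Yc, n_components)
    total = (Xc ** 2).sum()
    frac = np.array([(np.outer(T[:, a], P[:, a]) ** 2).sum() / total
                     for a in range(n_components)])
    comp_names = [f"comp{i+1}" for i in range(n_components)]
    return LatentProjection(
        method="PLSDA",
        scores=pd.DataFrame(T, index=samples, columns=comp_names),
        loadings=pd.DataFrame(P, index=probes, columns=comp_names),
        explained_variance=frac,
        weights=pd.DataFrame(W, index=probes, columns=comp_names),
    )


def correlation_circle(projection: LatentProjection, data, component: int = 1,
                       r_cutoff: float = 0.9, top_n: int = 20) -> pd.DataFrame:
    """Rank probes by |Pearson r| between probe values and the scores of one
    component (1-based); keep |r| > r_cutoff, truncate to the top `top_n`."""
    if not 1 <= component <= projection.scores.shape[1]:
        raise ConfigError(f"component {component} out of range")
    X, samples, probes = _as_sample_matrix(data)
    if not projection.scores.index.equals(samples):
        raise ConfigError("projection was fitted on different samples")
    t = projection.scores.iloc[:, component - 1].to_numpy(float)
    rows = []
    for i, pid in enumerate(probes):
        x = X[:, i]
        if np.ptp(x) == 0:
            continue
        r = float(sps.pearsonr(x, t).statistic)
        if abs(r) > r_cutoff:
            rows.append((pid, r))
    out = pd.DataFrame(rows, columns=["probe_id", "r"]).set_index("probe_id")
    out = out.reindex(out["r"].abs().sort_values(ascending=False).index)
    return out.head(top_n)
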