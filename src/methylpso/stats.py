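"""General statistical helpers: multiple-testing adjustment and group tests.

`bh_adjust` is the Benjamini–Hochberg step-up used throughout the pipeline.
`compare_groups` wraps the pairwise and multi-group tests used for phenotype
tables and score comparisons (t / Mann–Whitney / ANOVA+Tukey /
Kruskal–Wallis+Dunn / Fisher / chi-square / Pearson), with a Shapiro–Wilk
normality screen to choose between parametric and non-parametric branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ConfigError


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, where p_(1..m) are the
    sorted p-values. Input order is preserved in the output.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ConfigError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni_adjust(p, m: int | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = p.size if m is None else m
    return np.minimum(p * m, 1.0)


@dataclass
class TestResult:
    """Outcome of a group comparison."""

    kind: str
    statistic: float
    p: float
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def shapiro_normal(x, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk screen; True if normality is not rejected at `alpha`."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ConfigError("normality screen needs n >= 3")
    if np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue >= alpha


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-tests on mean ranks after Kruskal–Wallis, with a tie
    correction and BH adjustment over the pairwise family."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in names:
        k = groups[g].size
        mean_rank[g] = ranks[start:start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            na, nb = groups[a].size, groups[b].size
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
            z = (mean_rank[a] - mean_rank[b]) / se
            rows.append((a, b, z, 2 * sps.norm.sf(abs(z))))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


def compare_groups(*samples, groups=None, values=None, kind: str,
                   table=None, alpha: float = 0.05) -> TestResult:
    """Run the requested comparison.

    Parameters
    ----------
    samples
        For two-sample kinds (``t``, ``mwu``, ``pearson``): two arrays.
    groups, values
        For multi-group kinds (``anova_tukey``, ``kw_dunn``): parallel label
        and value vectors.
    table
        2x2 (or RxC for chi2) contingency table for ``fisher`` / ``chi2``.
    kind
        One of t, mwu, anova_tukey, kw_dunn, fisher, chi2, pearson, auto_pair.
        ``auto_pair`` runs Shapiro–Wilk on each sample and picks Student's t
        when both pass, Mann–Whitney otherwise (or when n < 3, with warning).
    """
    if kind == "auto_pair":
        x, y = (np.asarray(s, float) for s in samples)
        if min(x.size, y.size) < 3:
            warnings.warn("n < 3: normality screen unavailable, "
                          "falling back to Mann-Whitney")
            kind = "mwu"
        else:
            kind = "t" if (shapiro_normal(x, alpha) and shapiro_normal(y, alpha)) \
                else "mwu"

    if kind == "t":
        x, y = samples
        if np.ptp(x) == 0 and np.ptp(y) == 0 and np.mean(x) == np.mean(y):
            return TestResult("t", 0.0, 1.0)
        stat, p = sps.ttest_ind(x, y)
        return TestResult("t", float(stat), float(p))
    if kind == "mwu":
        x, y = samples
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        return TestResult("mwu", float(stat), float(p))
    if kind == "pearson":
        x, y = samples
        r, p = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
        return TestResult("pearson", float(r), float(p))
    if kind == "anova_tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels = np.asarray(groups)
        vals = np.asarray(values, float)
        parts = {g: vals[labels == g] for g in pd.unique(labels)}
        stat, p = sps.f_oneway(*parts.values())
        tk = pairwise_tukeyhsd(vals, labels)
        posthoc = pd.DataFrame(tk.summary().data[1:],
                               columns=[str(c) for c in tk.summary().data[0]])
        return TestResult("anova_tukey", float(stat), float(p), posthoc)
    if kind == "kw_dunn":
        labels = np.asarray(groups)
        vals = np.asarray(values, float)
        parts = {g: vals[labels == g] for g in pd.unique(labels)}
        stat, p = sps.kruskal(*parts.values())
        return TestResult("kw_dunn", float(stat), float(p), _dunn_posthoc(parts))
    if kind == "fisher":
        stat, p = sps.fisher_exact(np.asarray(table))
        return TestResult("fisher", float(stat), float(p))
    if kind == "chi2":
        res = sps.chi2_contingency(np.asarray(table))
        return TestResult("chi2", float(res.statistic), float(res.pvalue))
    raise ConfigError(f"unknown test kind {kind!r}")
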