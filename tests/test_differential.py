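"""Moderated t, BH adjustment, DMP/DMR calling and group comparisons."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from methylpso import (
    BetaMatrix,
    ConfigError,
    FormatError,
    MMatrix,
    SimConfig,
    bh_adjust,
    call_dmps,
    call_dmrs,
    compare_groups,
    dmp_statistics,
    fit_moderated,
    generate_cohort,
    promoter_subset,
    summarize_dmps,
)

from conftest import make_beta, make_manifest, make_sheet


def _fixture_mm(n_probes=50, n_per_group=6, effect_probes=0, effect=0.0,
                seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n_probes, 2 * n_per_group)) \
        * rng.uniform(0.5, 2.0, n_probes)[:, None]
    X[:effect_probes, n_per_group:] += effect
    cols = [f"S{j:02d}" for j in range(2 * n_per_group)]
    m = MMatrix(pd.DataFrame(X, index=[f"cg{i:05d}" for i in range(n_probes)],
                             columns=cols))
    sheet = make_sheet(["HC"] * n_per_group + ["PsO"] * n_per_group)
    return m, sheet


class TestModeratedT:
    def test_identical_groups_give_t0_p1(self):
        vals = np.tile(np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]), (5, 1))
        m = MMatrix(pd.DataFrame(vals, columns=[f"S{j:02d}" for j in range(6)]))
        sheet = make_sheet(["HC"] * 3 + ["PsO"] * 3)
        stats_df, _ = fit_moderated(m, sheet, ("HC", "PsO"))
        assert stats_df["t_mod"].abs().max() < 1e-10
        assert (stats_df["p"] > 1 - 1e-10).all()

    def test_d0_zero_equals_per_probe_ols_oracle(self):
        m, sheet = _fixture_mm(seed=1)
        stats_df, _ = fit_moderated(m, sheet, ("HC", "PsO"), prior_df=0)
        g = np.array([0.0] * 6 + [1.0] * 6)
        X = np.column_stack([np.ones(12), g])
        for pid, row in m.df.iterrows():
            y = row.to_numpy()
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            s2 = res[0] / (12 - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            t_ols = coef[1] / se
            assert stats_df.loc[pid, "t_mod"] == pytest.approx(t_ols, abs=1e-8)
            p_ols = 2 * sps.t.sf(abs(t_ols), 10)
            assert stats_df.loc[pid, "p"] == pytest.approx(p_ols, abs=1e-8)

    def test_d0_infinite_equals_pooled_variance_oracle(self):
        m, sheet = _fixture_mm(seed=2)
        stats_df, params = fit_moderated(m, sheet, ("HC", "PsO"),
                                         prior_df=np.inf)
        diffs = m.df.iloc[:, 6:].mean(axis=1) - m.df.iloc[:, :6].mean(axis=1)
        g = np.array([0.0] * 6 + [1.0] * 6)
        X = np.column_stack([np.ones(12), g])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        resid = m.df.to_numpy() @ (np.eye(12) - H).T
        s2 = (resid ** 2).sum(axis=1) / 10
        pooled = s2.mean()
        t_oracle = diffs / np.sqrt(pooled * (1 / 6 + 1 / 6))
        np.testing.assert_allclose(stats_df["t_mod"], t_oracle, atol=1e-8)

    def test_shared_variance_degenerates_to_infinite_prior(self):
        # every probe has the same within-group sample pattern -> identical
        # residual variances -> d0 capped at infinity, s0^2 = common variance
        rng = np.random.default_rng(3)
        pattern = rng.normal(size=8)
        mu = rng.normal(size=20)
        X = mu[:, None] + pattern[None, :]
        m = MMatrix(pd.DataFrame(X, columns=[f"S{j:02d}" for j in range(8)]))
        sheet = make_sheet(["HC"] * 4 + ["PsO"] * 4)
        _, params = fit_moderated(m, sheet, ("HC", "PsO"))
        assert np.isinf(params.d0)
        g = np.array([0.0] * 4 + [1.0] * 4)
        des = np.column_stack([np.ones(8), g])
        H = des @ np.linalg.inv(des.T @ des) @ des.T
        resid = X @ (np.eye(8) - H).T
        common_var = (resid[0] ** 2).sum() / 6
        assert params.s0_sq == pytest.approx(common_var, rel=1e-9)

    def test_group_smaller_than_two_rejected(self):
        m, _ = _fixture_mm(n_per_group=2)
        sheet = make_sheet(["HC"] * 1 + ["PsO"] * 3)
        with pytest.raises(ConfigError, match="2 samples"):
            fit_moderated(m, sheet, ("HC", "PsO"))


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(deadline=None, max_examples=100)
    def test_monotone_capped_and_dominates_p(self, p):
        q = bh_adjust(p)
        assert (q <= 1.0).all() and (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


class TestCallDmps:
    def test_thresholds_on_constructed_effects(self):
        # probe 0: strong, |delta beta| = 0.15 -> retained hypo
        # probe 1: strong but |delta beta| = 0.05 -> excluded by effect filter
        rng = np.random.default_rng(6)
        n = 40
        base = np.full((n, 16), 0.5) + rng.normal(0, 0.002, (n, 16))
        base[0, 8:] -= 0.15
        base[1, 8:] += 0.05
        beta = make_beta(np.clip(base, 0.001, 0.999),
                         sample_ids=[f"S{j:02d}" for j in range(16)])
        sheet = make_sheet(["HC"] * 8 + ["PsO"] * 8)
        from methylpso import beta_to_m

        dmps = call_dmps(beta_to_m(beta), beta, sheet, ("HC", "PsO"))
        assert "cg00000" in dmps.index
        assert dmps.loc["cg00000", "direction"] == "hypo"
        assert "cg00001" not in dmps.index

    def test_null_cohort_yields_almost_no_dmps(self):
        counts = []
        for seed in range(1, 11):
            cfg = SimConfig(n_probes=20_000, n_planted_dmp=10,
                            delta_beta_effect=0.0, slide_shift_m=0.0,
                            score_gene_fraction=0.0, seed=seed)
            sheet, beta, _ = generate_cohort(cfg)
            from methylpso import beta_to_m

            dmps = call_dmps(beta_to_m(beta), beta, sheet, ("HC", "PsO+PsA"))
            counts.append(len(dmps))
        assert max(counts) <= 3


class TestSummaries:
    def test_total_is_hypo_plus_hyper(self):
        df = pd.DataFrame({
            "direction": ["hypo"] * 433 + ["hyper"] * 450,
            "genes": [[] for _ in range(883)],
        }, index=[f"cg{i}" for i in range(883)])
        assert summarize_dmps(df) == (433, 450, 883, 0)

    def test_unique_genes_union(self):
        df = pd.DataFrame({
            "direction": ["hypo", "hyper", "hypo"],
            "genes": [["A", "B"], ["A"], ["C"]],
        }, index=["cg1", "cg2", "cg3"])
        assert summarize_dmps(df) == (2, 1, 3, 3)

    def test_empty_table(self):
        assert summarize_dmps(pd.DataFrame()) == (0, 0, 0, 0)

    def test_promoter_partition(self):
        man = make_manifest(3)
        man.df.loc["cg00000", "region"] = "Body"
        man.df.loc["cg00001", "region"] = "TSS200"
        man.df.loc["cg00002", "region"] = "5'UTR"
        dmps = pd.DataFrame({
            "direction": ["hyper", "hyper", "hypo"],
            "delta_beta": [0.2, 0.2, -0.2],
        }, index=["cg00000", "cg00001", "cg00002"])
        hypo, hyper = promoter_subset(dmps, man)
        assert list(hyper.index) == ["cg00001"]  # Body probe excluded
        assert list(hypo.index) == ["cg00002"]

    def test_all_body_gives_empty_partitions(self):
        man = make_manifest(2, region="Body")
        dmps = pd.DataFrame({"direction": ["hypo", "hyper"],
                             "delta_beta": [-0.2, 0.2]},
                            index=["cg00000", "cg00001"])
        hypo, hyper = promoter_subset(dmps, man)
        assert hypo.empty and hyper.empty


def _stats_frame(qs, deltas, ts=None):
    n = len(qs)
    return pd.DataFrame({
        "q": qs, "delta_beta": deltas, "p": np.asarray(qs) / 2,
        "t_mod": ts if ts is not None else np.sign(deltas) * 5.0,
    }, index=[f"cg{i:05d}" for i in range(n)])


class TestCallDmrs:
    def test_five_close_cpgs_form_one_region(self):
        man = make_manifest(5, start=1000, step=100)
        stats = _stats_frame([0.01] * 5, [0.2] * 5)
        dmrs = call_dmrs(stats, man)
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert row["n_cpg"] == 5
        assert (row["start"], row["end"]) == (999, 1400)  # 0-based half-open

    def test_four_cpgs_not_enough(self):
        man = make_manifest(4, start=1000, step=100)
        dmrs = call_dmrs(_stats_frame([0.01] * 4, [0.2] * 4), man)
        assert len(dmrs) == 0

    def test_gap_splits_cluster(self):
        man = make_manifest(5, start=1000, step=100)
        man.df.loc[["cg00003", "cg00004"], "pos"] = [6300, 6400]  # 5 kb gap
        dmrs = call_dmrs(_stats_frame([0.01] * 5, [0.2] * 5), man,
                         max_gap_bp=1000)
        assert len(dmrs) == 0  # split 3 + 2, both below min_cpg

    def test_members_must_pass_dmp_thresholds(self):
        man = make_manifest(6, start=1000, step=100)
        stats = _stats_frame([0.01] * 5 + [0.5], [0.2] * 5 + [0.2])
        dmrs = call_dmrs(stats, man)
        assert len(dmrs) == 1 and dmrs.iloc[0]["n_cpg"] == 5
        assert "cg00005" not in dmrs.iloc[0]["probes"]

    def test_unsorted_manifest_rejected(self):
        man = make_manifest(5)
        man.df.iloc[2, man.df.columns.get_loc("pos")] = 10  # out of order
        with pytest.raises(FormatError, match="sorted"):
            call_dmrs(_stats_frame([0.01] * 5, [0.2] * 5), man)


class TestCompareGroups:
    def test_identical_groups_t(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], kind="t")
        assert res.statistic == 0.0 and res.p == 1.0

    def test_perfect_linear_pearson(self):
        res = compare_groups([1.0, 2.0, 3.0], [2.0, 4.0, 6.0], kind="pearson")
        assert res.statistic == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[3, 1], [1, 3]])
        res = compare_groups(table=table, kind="fisher")
        # two-sided Fisher: sum of probabilities of all tables with fixed
        # margins that are no more probable than the observed one
        r1, r2 = table.sum(axis=1)
        c1 = table[:, 0].sum()
        n = table.sum()

        def prob(a):
            return (comb(r1, a) * comb(r2, c1 - a)) / comb(n, c1)

        p_obs = prob(3)
        p_exact = sum(prob(a) for a in range(max(0, c1 - r2), min(r1, c1) + 1)
                      if prob(a) <= p_obs + 1e-12)
        assert res.p == pytest.approx(p_exact, abs=1e-12)

    def test_anova_tukey_has_posthoc_table(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10),
                               rng.normal(0, 1, 10)])
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = compare_groups(groups=groups, values=vals, kind="anova_tukey")
        assert res.p < 0.01
        assert len(res.posthoc) == 3

    def test_kruskal_dunn_has_adjusted_pairs(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(2.5, 1, 12)])
        groups = ["a"] * 12 + ["b"] * 12
        res = compare_groups(groups=groups, values=vals, kind="kw_dunn")
        assert res.p < 0.01
        assert {"z", "p", "p_adj"} <= set(res.posthoc.columns)

    def test_small_n_falls_back_to_nonparametric(self):
        with pytest.warns(UserWarning, match="Mann-Whitney"):
            res = compare_groups([1.0, 2.0], [5.0, 6.0], kind="auto_pair")
        assert res.kind == "mwu"
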