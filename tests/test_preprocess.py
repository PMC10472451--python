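"""Filtering, scale conversion, quantile normalization and batch adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylpso import (
    BetaMatrix,
    ConfigError,
    MMatrix,
    SampleSheet,
    beta_to_m,
    combat_adjust,
    filter_probes,
    m_to_beta,
    quantile_normalize,
    screen_covariates,
)

from conftest import make_beta, make_manifest, make_sheet


class TestFilterProbes:
    def _beta_with_flags(self):
        beta = make_beta(np.full((10, 4), 0.5))
        flags = {
            "flag_snp": [True, True] + [False] * 8,
            "flag_ch": [False, False, True] + [False] * 7,
            "flag_xreactive": [False] * 3 + [True] + [False] * 6,
        }
        man = make_manifest(10, **flags)
        fail = pd.DataFrame(False, index=beta.df.index, columns=beta.df.columns)
        fail.iloc[4, 0] = True
        return BetaMatrix(beta.df, fail), man

    def test_disjoint_reasons_remove_five(self):
        beta, man = self._beta_with_flags()
        kept, rep = filter_probes(beta, man)
        assert rep.n_input == 10
        assert (rep.n_snp, rep.n_ch, rep.n_xreactive, rep.n_detection_fail) == \
            (2, 1, 1, 1)
        assert rep.n_retained == 5 and len(kept.probe_ids) == 5

    def test_no_flags_is_identity(self):
        beta = make_beta(np.full((6, 3), 0.4))
        man = make_manifest(6)
        kept, rep = filter_probes(beta, man)
        assert rep.n_retained == 6
        pd.testing.assert_frame_equal(kept.df, beta.df)

    def test_overlapping_flags_counted_once(self):
        beta = make_beta(np.full((3, 2), 0.5))
        man = make_manifest(3, flag_snp=[True, False, False],
                            flag_ch=[True, False, False])
        _, rep = filter_probes(beta, man)
        assert rep.n_snp == 1 and rep.n_ch == 1
        assert rep.n_retained == 2  # union removed once

    def test_filtering_is_idempotent(self):
        beta, man = self._beta_with_flags()
        once, _ = filter_probes(beta, man)
        twice, rep = filter_probes(once, man)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert rep.n_retained == rep.n_input


class TestBetaMConversion:
    @pytest.mark.parametrize("b,expected", [
        (0.5, 0.0),
        (0.8, 2.0),
        (1.0, np.log2(0.999 / 0.001)),
    ])
    def test_known_values(self, b, expected):
        m = beta_to_m(make_beta([[b]]))
        assert m.df.iat[0, 0] == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(min_value=0.001, max_value=0.999), min_size=1,
                    max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_identity_on_open_interval(self, values):
        beta = make_beta(np.array(values)[:, None])
        back = m_to_beta(beta_to_m(beta))
        np.testing.assert_allclose(back.df.to_numpy(), beta.df.to_numpy(),
                                   atol=1e-12)


class TestQuantileNormalize:
    def test_two_column_reference(self):
        m = MMatrix(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]},
                                 index=["p1", "p2", "p3"]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.df["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.df["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        col = np.array([0.3, -1.0, 2.2, 0.0])
        m = MMatrix(pd.DataFrame({"a": col, "b": col}))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.df.to_numpy(), m.df.to_numpy())

    def test_single_sample_unchanged(self):
        m = MMatrix(pd.DataFrame({"a": [2.0, -1.0, 0.5]}))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.df["a"], m.df["a"])

    def test_ties_get_mean_of_rank_span(self):
        m = MMatrix(pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]}))
        out = quantile_normalize(m)
        ref = np.sort(m.df.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2, 4.5]
        assert out.df["a"].iloc[0] == out.df["a"].iloc[1] == \
            pytest.approx((ref[0] + ref[1]) / 2)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=15)
    def test_columns_share_sorted_values_and_keep_rank_order(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 4))
        m = MMatrix(pd.DataFrame(X))
        out = quantile_normalize(m).df.to_numpy()
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(out[:, j]),
                                       atol=1e-12)
        for j in range(4):
            orig_order = np.argsort(X[:, j], kind="mergesort")
            assert (np.diff(out[orig_order, j]) >= -1e-12).all()


class TestCombat:
    def test_single_batch_returns_input_with_warning(self):
        m = MMatrix(pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)),
                                 columns=["S00", "S01", "S02", "S03"]))
        sheet = make_sheet(["HC"] * 4)
        with pytest.warns(UserWarning, match="single batch"):
            out, model = combat_adjust(m, sheet)
        pd.testing.assert_frame_equal(out.df, m.df)
        assert model is None

    def test_pure_additive_offset_symmetric_fixture(self):
        # every probe shares the same within-batch sample pattern, so the
        # EB shrinkage is exact and batch means equalize to machine precision
        rng = np.random.default_rng(1)
        common = rng.normal(size=10)
        mu = rng.normal(size=30)
        X = mu[:, None] + np.tile(common, (30, 2))[:, :20]
        X[:, 10:] += 1.0
        cols = [f"S{j:02d}" for j in range(20)]
        m = MMatrix(pd.DataFrame(X, columns=cols))
        sheet = make_sheet(["HC"] * 20, slides=["slide1"] * 10 + ["slide2"] * 10)
        out, _ = combat_adjust(m, sheet, covariates=())
        means_a = out.df.iloc[:, :10].mean(axis=1)
        means_b = out.df.iloc[:, 10:].mean(axis=1)
        np.testing.assert_allclose(means_a, means_b, atol=1e-6)

    def test_location_recovery_vs_two_sample_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 40))
        X[:, 20:] += 1.0
        cols = [f"S{j:02d}" for j in range(40)]
        m = MMatrix(pd.DataFrame(X, columns=cols))
        sheet = make_sheet(["HC"] * 40,
                           slides=["slide1"] * 20 + ["slide2"] * 20)
        _, model = combat_adjust(m, sheet, covariates=())
        recovered = (model.gamma_star_m.loc["slide2"]
                     - model.gamma_star_m.loc["slide1"]).mean()
        oracle = (m.df.iloc[:, 20:].mean(axis=1)
                  - m.df.iloc[:, :20].mean(axis=1)).mean()
        assert recovered == pytest.approx(1.0, abs=0.05)
        assert recovered == pytest.approx(oracle, abs=0.05)

    def test_null_batch_effect_barely_perturbs(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 100))
        cols = [f"S{j:03d}" for j in range(100)]
        m = MMatrix(pd.DataFrame(X, columns=cols))
        df = pd.DataFrame({"subject_id": cols, "group": ["HC"] * 100,
                           "slide": ["slide1", "slide2"] * 50},
                          index=pd.Index(cols, name="sample_id"))
        out, _ = combat_adjust(m, SampleSheet(df), covariates=())
        change = np.abs(out.df.to_numpy() - X).mean()
        assert change < 0.2  # o(noise sd = 1)

    def test_confounded_batch_rejected(self):
        m = MMatrix(pd.DataFrame(np.random.default_rng(4).normal(size=(5, 8)),
                                 columns=[f"S{j:02d}" for j in range(8)]))
        sheet = make_sheet(["HC"] * 4 + ["PsO"] * 4,
                           slides=["slide1"] * 4 + ["slide2"] * 4)
        with pytest.raises(ConfigError, match="confounded"):
            combat_adjust(m, sheet, covariates=("group",))

    def test_group_signal_survives_adjustment(self, small_cohort):
        sheet, beta = small_cohort["sheet"], small_cohort["beta"]
        truth = small_cohort["truth"]
        m = beta_to_m(beta)
        adj, _ = combat_adjust(m, sheet)
        hc = sheet.resolve_groups("HC")
        pat = sheet.resolve_groups("PsO+PsA")
        planted = truth.planted_delta.index
        diff = (adj.df.loc[planted, pat].mean(axis=1)
                - adj.df.loc[planted, hc].mean(axis=1))
        signed = diff * np.sign(truth.planted_delta)
        assert signed.mean() > 0.5  # M-scale effect retained


def test_covariate_screen_flags_batch_effect(small_cohort):
    m = beta_to_m(small_cohort["beta"])
    pvals = screen_covariates(m, small_cohort["sheet"],
                              candidates=("slide", "sex"))
    assert pvals["slide"] < 0.05
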