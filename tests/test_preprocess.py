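import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dili_ternary import (
    PeakTable, corrupt_with_drift, filter_features, impute_and_scale, qc_rsd,
    qc_svrc_correct, univariate_screen,
)
from dili_ternary.preprocess import CORRECTED, SKIPPED_QC

from conftest import drift_fixture


def flat_qc_table(n_inj=30, n_feat=5, qc_every=5, level=1000.0):
    """Constant-intensity table with interleaved QCs."""
    idx = pd.Index([f"S{i}" for i in range(n_inj)], name="sample_id")
    roles = ["qc" if i % qc_every == 0 else "study" for i in range(n_inj)]
    intens = pd.DataFrame(np.full((n_inj, n_feat), level), index=idx,
                          columns=[f"f{j}" for j in range(n_feat)])
    return PeakTable(intens, pd.Series(["B1"] * n_inj, index=idx),
                     pd.Series(range(1, n_inj + 1), index=idx),
                     pd.Series(roles, index=idx))


class TestQcSvrc:
    def test_flat_qc_trend_leaves_data_unchanged(self):
        pt = flat_qc_table()
        corrected, fit = qc_svrc_correct(pt, min_qc=3)
        rel = np.abs(corrected.intensities / pt.intensities - 1.0)
        assert float(rel.max().max()) < 1e-6
        assert (fit.report["status"] == CORRECTED).all()

    def test_halves_qc_rsd_under_strong_drift(self):
        pt, _ = drift_fixture(seed=3)
        corrupted = corrupt_with_drift(pt, amplitude=0.5)
        before = qc_rsd(corrupted).median()
        corrected, _ = qc_svrc_correct(corrupted, min_qc=5)
        after = qc_rsd(corrected).median()
        assert after <= 0.5 * before

    def test_insufficient_qc_passes_through_flagged(self):
        pt = flat_qc_table(n_inj=12, qc_every=6)  # only 2 QCs
        corrected, fit = qc_svrc_correct(pt, min_qc=5)
        assert (fit.report["status"] == SKIPPED_QC).all()
        pd.testing.assert_frame_equal(corrected.intensities, pt.intensities)

    def test_no_qc_rows_is_an_error(self):
        pt = flat_qc_table()
        pt = PeakTable(pt.intensities, pt.batch, pt.injection_order,
                       pd.Series(["study"] * pt.n_samples,
                                 index=pt.intensities.index))
        with pytest.raises(ValueError, match="no QC samples"):
            qc_svrc_correct(pt)

    def test_preserves_missingness_and_nonnegativity(self):
        pt, _ = drift_fixture(seed=4)
        corrupted = corrupt_with_drift(pt, amplitude=0.3)
        na_before = corrupted.intensities.isna()
        corrected, _ = qc_svrc_correct(corrupted, min_qc=5)
        pd.testing.assert_frame_equal(corrected.intensities.isna(), na_before)
        assert float(corrected.intensities.min().min()) >= 0

    def test_batch_processing_order_independent(self):
        # correction is per-batch: relabelling batches permutes nothing
        pt, _ = drift_fixture(seed=5)
        corrupted = corrupt_with_drift(pt, amplitude=0.3)
        c1, _ = qc_svrc_correct(corrupted, min_qc=5)
        c2, _ = qc_svrc_correct(corrupted, min_qc=5)
        pd.testing.assert_frame_equal(c1.intensities, c2.intensities)


class TestDriftCorruption:
    def test_zero_amplitude_is_identity(self):
        pt, _ = drift_fixture(seed=6)
        out = corrupt_with_drift(pt, amplitude=0.0)
        pd.testing.assert_frame_equal(out.intensities, pt.intensities)

    def test_last_injection_scaled_exactly(self):
        pt = flat_qc_table(n_inj=10, level=100.0)
        out = corrupt_with_drift(pt, amplitude=0.5)
        last = pt.injection_order.idxmax()
        assert out.intensities.loc[last].eq(150.0).all()
        first = pt.injection_order.idxmin()
        assert out.intensities.loc[first].eq(100.0).all()

    def test_corruption_inflates_qc_rsd(self):
        pt, _ = drift_fixture(seed=7)
        before = qc_rsd(pt).median()
        after = qc_rsd(corrupt_with_drift(pt, amplitude=0.2)).median()
        assert after > before

    def test_requires_qc_rows(self):
        pt = flat_qc_table()
        no_qc = PeakTable(pt.intensities, pt.batch, pt.injection_order,
                          pd.Series(["study"] * pt.n_samples,
                                    index=pt.intensities.index))
        with pytest.raises(ValueError, match="QC"):
            corrupt_with_drift(no_qc, amplitude=0.2)


class TestFilterFeatures:
    def _table(self):
        idx = pd.Index(["S1", "S2", "B1r", "B2r"], name="sample_id")
        intens = pd.DataFrame(
            {"good": [1000.0, 1100.0, 10.0, 12.0],
             "background": [30.0, 28.0, 29.0, 31.0],
             "patchy": [np.nan, 500.0, 5.0, 4.0]},
            index=idx)
        return PeakTable(intens, pd.Series(["B1"] * 4, index=idx),
                         pd.Series(range(1, 5), index=idx),
                         pd.Series(["study", "study", "blank", "blank"],
                                   index=idx))

    def test_blank_dominated_feature_dropped(self):
        kept, report = filter_features(self._table(), blank_ratio=3.0,
                                       max_missing=0.6)
        assert "background" not in kept.feature_ids
        assert "good" in kept.feature_ids

    def test_missingness_filter(self):
        kept, report = filter_features(self._table(), blank_ratio=0.0,
                                       max_missing=0.4)
        # patchy is missing in 1/2 study samples > 0.4
        assert "patchy" not in kept.feature_ids

    def test_no_blanks_skips_blank_filter_with_warning(self):
        pt = flat_qc_table()
        with pytest.warns(UserWarning, match="blank"):
            kept, _ = filter_features(pt, max_missing=0.5)
        assert kept.n_features == pt.n_features

    def test_all_dropped_raises(self):
        pt = self._table()
        with pytest.raises(ValueError, match="all features"):
            filter_features(pt, blank_ratio=1e9, max_missing=0.0)


class TestImputeAndScale:
    def test_train_columns_standardized(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(3, 1, size=(20, 6)),
                          columns=[f"f{i}" for i in range(6)])
        train_scaled, applied, _ = impute_and_scale(df, df)
        assert np.allclose(train_scaled.mean(), 0, atol=1e-9)
        assert np.allclose(train_scaled.std(ddof=1), 1, atol=1e-9)
        pd.testing.assert_frame_equal(train_scaled, applied)

    def test_constant_feature_excluded_and_reported(self):
        df = pd.DataFrame({"c": [5.0] * 8,
                           "v": np.arange(1.0, 9.0)})
        with pytest.warns(UserWarning, match="zero-variance"):
            train_scaled, _, scaler = impute_and_scale(df)
        assert scaler.excluded == ["c"]
        assert list(train_scaled.columns) == ["v"]

    def test_scaler_round_trip(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.lognormal(2, 0.5, size=(15, 4)),
                          columns=list("abcd"))
        scaled, _, scaler = impute_and_scale(df)
        back = scaler.inverse_transform(scaled)
        assert np.allclose(back.to_numpy(), df.to_numpy(), rtol=1e-9)

    def test_half_minimum_imputation_from_train_only(self):
        train = pd.DataFrame({"f": [10.0, 20.0, 40.0]})
        apply = pd.DataFrame({"f": [np.nan]})
        _, applied, scaler = impute_and_scale(train, apply)
        # missing cell imputed at half the training minimum (5.0)
        assert scaler.inverse_transform(applied)["f"].iloc[0] == pytest.approx(5.0)


class TestUnivariateScreen:
    def test_bh_hand_computation(self):
        # p = (.01,.02,.03,.04), m=4 -> all q = 0.04
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(10, 4)),
                         columns=list("wxyz"))
        res = univariate_screen(X, X.index[:5], X.index[5:])
        from statsmodels.stats.multitest import multipletests
        _, q_ref, _, _ = multipletests(res.table["p"], method="fdr_bh")
        assert np.allclose(res.table["q"], q_ref)
        hand = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(hand, 0.04)

    def test_identical_groups_give_t0_p1(self):
        X = pd.DataFrame(np.tile(np.arange(1.0, 5.0), (6, 1)).T,
                         index=[f"s{i}" for i in range(4)])
        X2 = pd.concat([X, X.set_axis([f"t{i}" for i in range(4)])])
        res = univariate_screen(X2, [f"s{i}" for i in range(4)],
                                [f"t{i}" for i in range(4)])
        assert (res.table["t"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_small_group_raises(self):
        X = pd.DataFrame(np.random.default_rng(3).normal(size=(4, 3)))
        with pytest.raises(ValueError, match="at least 2"):
            univariate_screen(X, X.index[:1], X.index[1:])

    def test_type_one_error_rate_under_null(self):
        # two null groups, 500 features x 50 replicates: raw p<0.05 in [3%, 7%]
        rng = np.random.default_rng(4)
        hits, total = 0, 0
        for _ in range(50):
            X = pd.DataFrame(rng.normal(size=(24, 500)))
            res = univariate_screen(X, X.index[:12], X.index[12:])
            hits += int((res.table["p"] < 0.05).sum())
            total += 500
        assert 0.03 <= hits / total <= 0.07

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_bh_monotone_in_p(self, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(12, 30)))
        res = univariate_screen(X, X.index[:6], X.index[6:])
        t = res.table.sort_values("p")
        assert (t["q"].diff().dropna() >= -1e-12).all()
        assert (t["q"] >= t["p"] - 1e-12).all()
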