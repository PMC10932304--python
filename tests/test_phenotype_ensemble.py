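import numpy as np
import pandas as pd
import pytest

from dili_ternary import (
    SimulationConfig, build_fold_plan, double_cv_evaluate, load_ensemble,
    make_subject_folds, mixed_type_patients, save_ensemble, select_n_lv,
    simulate_cohort, train_ensemble, train_ovr,
)
from dili_ternary.phenotype_ensemble import FoldError


@pytest.fixture(scope="module")
def cohort_frames(small_cohort):
    cohort, truth = small_cohort
    clin = cohort.clinical_frame()
    return (cohort.study_intensities, clin["clinician_label"],
            clin["patient_id"], truth)


class TestFolds:
    def test_round_robin_partition(self):
        folds = make_subject_folds([f"P{i}" for i in range(6)], 2, seed=0)
        assert sorted(len(f) for f in folds) == [3, 3]
        flat = [p for f in folds for p in f]
        assert sorted(flat) == [f"P{i}" for i in range(6)]

    def test_same_seed_same_plan(self):
        ids = [f"P{i}" for i in range(11)]
        assert make_subject_folds(ids, 3, 7) == make_subject_folds(ids, 3, 7)

    def test_k_larger_than_patients_raises(self):
        with pytest.raises(FoldError):
            make_subject_folds(["P1", "P2"], 3, 0)

    def test_nested_plan_excludes_mixed_patients_everywhere(self):
        ids = [f"P{i}" for i in range(10)]
        plan = build_fold_plan(ids, 3, 2, seed=1, exclude={"P3", "P7"})
        everywhere = {p for f in plan.outer_folds for p in f}
        for inner in plan.inner_folds.values():
            everywhere |= {p for f in inner for p in f}
        assert not everywhere & {"P3", "P7"}

    def test_patient_never_split_across_folds(self, cohort_frames):
        _, labels, patients, _ = cohort_frames
        folds = make_subject_folds(patients, 4, seed=3)
        membership = {}
        for fi, fold in enumerate(folds):
            for p in fold:
                assert p not in membership
                membership[p] = fi
        # sample-level membership is derived purely from patient membership
        sample_folds = patients.map(membership)
        assert sample_folds.groupby(patients).nunique().eq(1).all()

    def test_mixed_detection(self):
        labels = pd.Series(["mixed", "recovered", "cholestatic"],
                           index=["a", "b", "c"])
        patients = pd.Series(["P1", "P1", "P2"], index=labels.index)
        assert mixed_type_patients(labels, patients) == {"P1"}


class TestLvSelection:
    def test_max_lv_one_returns_one(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        from dili_ternary import encode_labels
        y = pd.Series(encode_labels(labels, "recovered"), index=labels.index)
        folds = make_subject_folds(patients, 3, 0)
        n_lv, curve = select_n_lv(X, y, patients, folds, max_lv=1)
        assert n_lv == 1 and len(curve) == 1

    def test_informative_labels_beat_noise_labels(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        from dili_ternary import encode_labels
        folds = make_subject_folds(patients, 3, 0)
        y_true = pd.Series(encode_labels(labels, "recovered"),
                           index=labels.index)
        _, curve_true = select_n_lv(X, y_true, patients, folds, max_lv=3)
        rng = np.random.default_rng(0)
        y_noise = pd.Series(rng.permutation(y_true.to_numpy()),
                            index=labels.index)
        _, curve_noise = select_n_lv(X, y_noise, patients, folds, max_lv=3)
        assert curve_true["cv_accuracy"].max() > curve_noise["cv_accuracy"].max()

    def test_noise_labels_within_chance_band(self, cohort_frames):
        X, _, patients, _ = cohort_frames
        rng = np.random.default_rng(1)
        y = pd.Series(rng.integers(0, 2, size=len(patients)).astype(float),
                      index=patients.index)
        folds = make_subject_folds(patients, 3, 0)
        _, curve = select_n_lv(X, y, patients, folds, max_lv=3)
        n = len(y)
        band = 3 * np.sqrt(0.25 / n) + 0.5
        assert (curve["cv_accuracy"] < band + 0.15).all()


class TestTrainOvr:
    def test_vip_selection_recovers_informative_features(self, cohort_frames):
        X, labels, patients, truth = cohort_frames
        excl = mixed_type_patients(labels, patients)
        use = ~patients.isin(excl)
        folds = make_subject_folds(patients[use], 3, 0)
        m = train_ovr(X.loc[use], labels[use], patients[use], "cholestatic",
                      folds, max_lv=3)
        hit = len(set(truth.informative_c) & set(m.selected_features))
        assert hit / len(truth.informative_c) >= 0.70

    def test_vip_threshold_zero_keeps_all_features(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        excl = mixed_type_patients(labels, patients)
        use = ~patients.isin(excl)
        folds = make_subject_folds(patients[use], 3, 0)
        m = train_ovr(X.loc[use], labels[use], patients[use], "recovered",
                      folds, max_lv=2, vip_threshold=0.0)
        assert set(m.selected_features) == set(m.stage1_scaler.features)

    def test_selected_features_subset_of_stage1(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        excl = mixed_type_patients(labels, patients)
        use = ~patients.isin(excl)
        folds = make_subject_folds(patients[use], 3, 0)
        m = train_ovr(X.loc[use], labels[use], patients[use],
                      "hepatocellular", folds, max_lv=3)
        assert set(m.selected_features) <= set(m.stage1_scaler.features)


class TestEnsemble:
    def test_three_models_with_cv_accuracy(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        ens = train_ensemble(X, labels, patients, seed=0, max_lv=3)
        assert set(ens.models) == {"cholestatic", "hepatocellular",
                                   "recovered"}
        for m in ens.models.values():
            assert np.isfinite(m.cv_accuracy)

    def test_no_mixed_patient_samples_in_training(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        ens = train_ensemble(X, labels, patients, seed=0, max_lv=3)
        mixed = mixed_type_patients(labels, patients)
        trained_patients = set(patients.loc[ens.training_samples])
        assert not trained_patients & mixed

    def test_pure_pole_predictions_put_target_first(self, cohort_frames):
        X, labels, patients, truth = cohort_frames
        ens = train_ensemble(X, labels, patients, seed=0, max_lv=3)
        pure_c = truth.patient_type[truth.patient_type == "pure_c"].index
        sel = patients.index[patients.isin(pure_c)
                             & (labels == "cholestatic")]
        raw = ens.predict_raw(X.loc[sel])
        frac = (raw.idxmax(axis=1) == "y_c").mean()
        assert frac >= 0.90

    def test_retrain_same_seed_identical(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        e1 = train_ensemble(X, labels, patients, seed=4, max_lv=2)
        e2 = train_ensemble(X, labels, patients, seed=4, max_lv=2)
        for c in e1.models:
            assert (e1.models[c].model.coef == e2.models[c].model.coef).all()

    def test_missing_class_raises(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        only_two = labels.replace("hepatocellular", "recovered")
        with pytest.raises(ValueError, match="missing training classes"):
            train_ensemble(X, only_two, patients, seed=0, max_lv=2)

    def test_serialization_round_trip(self, cohort_frames, tmp_path):
        X, labels, patients, _ = cohort_frames
        ens = train_ensemble(X, labels, patients, seed=0, max_lv=2)
        save_ensemble(ens, tmp_path / "model")
        back = load_ensemble(tmp_path / "model")
        pd.testing.assert_frame_equal(back.predict_raw(X.head(10)),
                                      ens.predict_raw(X.head(10)))


class TestDoubleCV:
    def test_each_sample_predicted_exactly_once(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        res = double_cv_evaluate(X, labels, patients, k_outer=3, k_inner=3,
                                 max_lv=3, seed=0)
        assert res.predictions.index.is_unique
        usable = labels.isin(["cholestatic", "hepatocellular", "recovered"])
        mixed = mixed_type_patients(labels, patients)
        expected = usable & ~patients.isin(mixed)
        assert set(res.predictions.index) == set(labels.index[expected])

    def test_outer_test_patients_disjoint_from_training(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        mixed = mixed_type_patients(labels, patients)
        plan = build_fold_plan(patients, 3, 3, seed=0, exclude=mixed)
        for i, fold in enumerate(plan.outer_folds):
            inner_patients = {p for f in plan.inner_folds[i] for p in f}
            assert not inner_patients & set(fold)

    def test_full_2cv_bit_reproducible(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        r1 = double_cv_evaluate(X, labels, patients, k_outer=3, k_inner=3,
                                max_lv=2, seed=5)
        r2 = double_cv_evaluate(X, labels, patients, k_outer=3, k_inner=3,
                                max_lv=2, seed=5)
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)

    def test_strong_signal_high_balanced_accuracy(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        res = double_cv_evaluate(X, labels, patients, k_outer=3, k_inner=3,
                                 max_lv=3, seed=0)
        assert res.balanced_accuracy >= 0.90

    def test_permuted_labels_fall_to_chance(self, cohort_frames):
        X, labels, patients, _ = cohort_frames
        rng = np.random.default_rng(0)
        # permute patient-level label blocks to respect subject structure
        pts = patients.unique()
        pt_label = {p: labels[patients == p].iloc[0] for p in pts}
        perm = rng.permutation(list(pt_label.values()))
        shuffled = patients.map(dict(zip(pts, perm)))
        res = double_cv_evaluate(X, shuffled, patients, k_outer=3, k_inner=3,
                                 max_lv=2, seed=0)
        assert abs(res.balanced_accuracy - 1 / 3) < 0.25
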