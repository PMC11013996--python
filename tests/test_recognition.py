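import numpy as np
import pandas as pd
import pytest

from kinerehab import landmarks as lm
from kinerehab.pose_model import extract_signals
from kinerehab.recognition import (FEATURE_NAMES, FeatureVector, N_FEATURES,
                                   extract_features, fit_pca, load_model,
                                   predict_exercise, save_model,
                                   select_basic_signals, split_by_subject,
                                   train_and_evaluate)
from kinerehab.signal_prep import MotionSignal
from conftest import single_phase

FS = 29.0


def fifteen(values_fn, n=64):
    return [MotionSignal(values_fn(i, n), FS, ("r", "a")) for i in range(15)]


def time_domain_oracle(x):
    """Direct-formula oracle for the 12 time-domain features."""
    n = x.size
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    std = var ** 0.5
    rms = (sum(v * v for v in x) / n) ** 0.5
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    return {
        "mean": mean, "max": max(x), "min": min(x), "rms": rms,
        "variance": var, "std": std,
        "crest_factor": max(abs(v) for v in x) / rms,
        "kurtosis": m4 / var ** 2, "skewness": m3 / var ** 1.5,
        "median": float(np.median(x)), "peak_to_peak": max(x) - min(x),
        "energy": sum(v * v for v in x),
    }


class TestBasicSignals:
    def test_fifteen_signals_in_stable_order(self):
        seq, _ = single_phase("SS", 40, 2.0, 2)
        ss = extract_signals(seq)
        basic1 = select_basic_signals(ss)
        basic2 = select_basic_signals(ss)
        assert len(basic1) == 15
        assert [s.label for s in basic1] == [s.label for s in basic2]

    def test_wrist_signal_matches_trace(self):
        seq, _ = single_phase("SA", 150, 3.0, 2)
        basic = select_basic_signals(extract_signals(seq))
        wrist_y = next(s for s in basic if s.label == ("left_arm", "y"))
        np.testing.assert_array_equal(wrist_y.values, seq.data[:, lm.LEFT_WRIST, 1])

    def test_torso_is_mid_hip(self):
        seq, _ = single_phase("SQT", 85, 3.0, 2)
        basic = select_basic_signals(extract_signals(seq))
        torso_y = next(s for s in basic if s.label == ("torso", "y"))
        mid = (seq.data[:, lm.LEFT_HIP, 1] + seq.data[:, lm.RIGHT_HIP, 1]) / 2
        np.testing.assert_allclose(torso_y.values, mid)


class TestFeatures:
    def test_dimension_is_285_with_unique_names(self):
        fv = extract_features(fifteen(lambda i, n: np.sin(np.arange(n) / 3.0)))
        assert fv.values.shape == (285,)
        assert len(set(fv.names)) == 285

    def test_constant_signal_closed_forms(self):
        fv = extract_features(fifteen(lambda i, n: np.full(n, 0.5)))
        d = dict(zip(fv.names, fv.values))
        assert d["torso_x_mean"] == pytest.approx(0.5)
        assert d["torso_x_max"] == pytest.approx(0.5)
        assert d["torso_x_min"] == pytest.approx(0.5)
        assert d["torso_x_rms"] == pytest.approx(0.5)
        assert d["torso_x_variance"] == pytest.approx(0.0)
        assert d["torso_x_peak_to_peak"] == pytest.approx(0.0)
        assert d["torso_x_crest_factor"] == pytest.approx(1.0)
        assert d["torso_x_kurtosis"] == pytest.approx(0.0)

    def test_unit_sinusoid_rms_and_peak_frequency(self):
        n, cycles = 116, 8  # integer cycles at 2 Hz, fs 29
        t = np.arange(n) / FS
        f0 = cycles / (n / FS)
        fv = extract_features(fifteen(lambda i, _: np.sin(2 * np.pi * f0 * t), n))
        d = dict(zip(fv.names, fv.values))
        assert d["torso_x_rms"] == pytest.approx(1 / np.sqrt(2), abs=1e-6)
        assert d["torso_x_bp_peak_freq"] == pytest.approx(f0, abs=FS / n)

    def test_time_domain_features_match_direct_formulas(self, rng):
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(8, 80)))
            fv = extract_features(fifteen(lambda i, n: x, x.size))
            d = dict(zip(fv.names, fv.values))
            for name, want in time_domain_oracle(x).items():
                assert d[f"torso_x_{name}"] == pytest.approx(want, abs=1e-10), name

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            extract_features(fifteen(lambda i, n: np.zeros(4), 4))


class TestPCA:
    def test_constructed_rank_three(self, rng):
        basis = rng.normal(size=(3, N_FEATURES))
        X = rng.normal(size=(120, 3)) @ basis
        X += 1e-8 * rng.normal(size=X.shape)
        model = fit_pca(X, 0.90)
        assert model.n_retained == 3

    def test_components_orthonormal_and_variance_nonincreasing(self, rng):
        X = rng.normal(size=(80, N_FEATURES))
        model = fit_pca(X, 0.90)
        C = model.components
        np.testing.assert_allclose(C @ C.T, np.eye(C.shape[0]), atol=1e-8)
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_retained_space_explains_target_variance(self, rng):
        X = rng.normal(size=(60, N_FEATURES)) * rng.uniform(0.1, 3, N_FEATURES)
        model = fit_pca(X, 0.90)
        Z = model.transform(X)
        back = model.pca.inverse_transform(Z)
        scaled = model.scaler.transform(X)
        explained = 1 - np.var(scaled - back) / np.var(scaled)
        assert explained >= 0.90 - 1e-6

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((10, N_FEATURES)))


def toy_table(n_subjects=10, reps=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for r in range(reps):
            label = (s + r) % 5 + 1
            feats = rng.normal(size=N_FEATURES) + 3 * label
            row = {"subject_id": f"S{s}", "label": label}
            row.update(dict(zip(FEATURE_NAMES, feats)))
            rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "label", *FEATURE_NAMES])


class TestSplit:
    def test_exact_proportion_with_balanced_subjects(self):
        split = split_by_subject(toy_table(10, 10), 0.30, seed=3)
        assert len(split.test_subjects) == 3
        assert split.test_fraction_actual == pytest.approx(0.30)

    def test_same_seed_reproduces_split(self):
        t = toy_table()
        s1 = split_by_subject(t, 0.30, seed=5)
        s2 = split_by_subject(t, 0.30, seed=5)
        assert s1.test_subjects == s2.test_subjects

    def test_no_subject_straddles(self):
        split = split_by_subject(toy_table(), 0.30, seed=1)
        assert not set(split.train_subjects) & set(split.test_subjects)

    def test_imbalanced_subjects_near_target(self):
        t = toy_table(6, 4, seed=2)
        extra = toy_table(2, 30, seed=3)
        extra["subject_id"] = extra["subject_id"].map({"S0": "B0", "S1": "B1"})
        t = pd.concat([t, extra], ignore_index=True)
        split = split_by_subject(t, 0.30, seed=4)
        counts = t["subject_id"].value_counts()
        frac = counts[split.test_subjects].sum() / counts.sum()
        worst = counts.max() / counts.sum()
        assert abs(frac - 0.30) <= worst

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            split_by_subject(toy_table(1, 10), 0.30, seed=0)


class TestTrainEvaluate:
    def test_separable_toy_data_is_learned(self):
        t = toy_table(10, 8, seed=1)
        split = split_by_subject(t, 0.30, seed=1)
        report = train_and_evaluate(t, split, use_pca=True, cv_folds=3, seed=1)
        assert report.metrics["SVML"]["accuracy"] >= 99.0
        for m in report.metrics.values():
            for key in ("accuracy", "f1", "precision", "sensitivity", "specificity"):
                assert 0.0 <= m[key] <= 100.0
        cm = report.confusion["SVML"]
        assert cm.sum() == report.n_test

    def test_leakage_guard_in_evaluation_path(self):
        t = toy_table(4, 5)
        split = split_by_subject(t, 0.3, seed=0)
        object.__setattr__(split, "train_subjects",
                           split.train_subjects + split.test_subjects[:1])
        with pytest.raises(ValueError, match="leakage|both"):
            train_and_evaluate(t, split, use_pca=False, cv_folds=2, seed=0)


class TestPredict:
    def test_training_instance_predicts_own_label(self, small_feature_table,
                                                  trained_model):
        row = small_feature_table.iloc[0]
        fv = FeatureVector(row[list(FEATURE_NAMES)].to_numpy(float))
        label, score = predict_exercise(trained_model, fv)
        assert int(label) == int(row["label"])
        assert np.isfinite(score)

    def test_held_out_subject_recognized(self, trained_model):
        seq, _ = single_phase("SA", 160, 2.8, 3, fps=29, noise=0.003, seed=999)
        from kinerehab.pipeline import repetition_feature_rows

        rows = repetition_feature_rows(seq)
        fv = FeatureVector(np.array([rows[0][n] for n in FEATURE_NAMES]))
        label, _ = predict_exercise(trained_model, fv)
        assert label.name == "SA"

    def test_zero_vector_is_handled(self, trained_model):
        label, score = predict_exercise(trained_model,
                                        FeatureVector(np.zeros(N_FEATURES)))
        assert label is not None and np.isfinite(score)

    def test_feature_spec_mismatch_rejected(self, trained_model):
        fv = FeatureVector(np.zeros(N_FEATURES),
                           tuple(f"x{i}" for i in range(N_FEATURES)))
        with pytest.raises(ValueError, match="mismatch"):
            predict_exercise(trained_model, fv)

    def test_model_roundtrip_via_bundle(self, tmp_path, trained_model):
        path = tmp_path / "model.joblib"
        save_model(trained_model, path)
        back = load_model(path)
        fv = FeatureVector(np.zeros(N_FEATURES))
        assert predict_exercise(back, fv) == predict_exercise(trained_model, fv)
        with pytest.raises(ValueError):
            load_model(path, expected_features=["wrong"])
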