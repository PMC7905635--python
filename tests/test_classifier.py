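from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from orfrf import classifier
from orfrf.classifier import (
    TrainingConfig,
    feature_importance,
    load_model,
    predict,
    save_model,
    train,
    vote_fraction,
)
from orfrf.errors import ModelError, ModelFormatError
from orfrf.features import FEATURE_NAMES, FeatureVector
from orfrf.labeling import LabeledInstance


def instance(label: str, ref_i: int, **overrides) -> LabeledInstance:
    base = dict(
        length_nt=300, gc=0.5, gc1=0.5, gc2=0.5, gc3=0.5,
        var2=0.01, var3=0.001, var4=0.0005, var5=0.0002, var6=0.0001,
        c_weight=0.8,
    )
    base.update(overrides)
    return LabeledInstance(
        FeatureVector(**base), label, (f"i{ref_i}", 1, base["length_nt"], "+")
    )


class TestTrainingConfig:
    def test_protocol_shape_defaults(self):
        cfg = TrainingConfig()
        assert cfg.n_trees == 100
        assert 3 in cfg.mtry_grid
        assert (cfg.cv_folds, cfg.cv_repeats) == (5, 5)
        assert classifier.ALLOWED_TREE_COUNTS == (100, 200, 500, 700)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(n_trees=150)
        with pytest.raises(ValueError):
            TrainingConfig(mtry_grid=(0,))
        with pytest.raises(ValueError):
            TrainingConfig(mtry_grid=(12,))


class TestTrain:
    def test_separable_on_length_reaches_near_perfect_cv(self, toy_length_model):
        model, cv_results, _ = toy_length_model
        assert max(r.mean_accuracy for r in cv_results) > 0.99
        assert model.chosen_mtry in (2, 3)

    def test_tie_break_prefers_smaller_mtry(self, toy_length_model):
        model, cv_results, _ = toy_length_model
        best = max(r.mean_accuracy for r in cv_results)
        tied = [r.mtry for r in cv_results if r.mean_accuracy == best]
        assert model.chosen_mtry == min(tied)

    def test_single_class_rejected(self):
        with pytest.raises(ModelError, match="both classes"):
            train([instance("coding", i) for i in range(10)])

    def test_nan_feature_names_instance(self):
        bad = [instance("coding", i) for i in range(5)] + [
            instance("intergenic", i + 10) for i in range(5)
        ]
        arr = bad[3].features.as_array()
        object.__setattr__(bad[3].features, "gc", np.nan)
        with pytest.raises(ModelError, match="i3"):
            train(bad, TrainingConfig(mtry_grid=(2,), cv_repeats=2))

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        data = [
            instance(
                "coding" if i % 2 else "intergenic",
                i,
                length_nt=int(rng.integers(60, 999)) // 3 * 3,
                gc=float(rng.uniform(0.3, 0.7)),
            )
            for i in range(60)
        ]
        cfg = TrainingConfig(mtry_grid=(2, 3), cv_repeats=2, seed=5)
        m1, cv1 = train(data, cfg)
        m2, cv2 = train(data, cfg)
        assert cv1 == cv2
        assert m1.chosen_mtry == m2.chosen_mtry
        X = np.vstack([d.features.as_array() for d in data])
        assert np.array_equal(vote_fraction(m1, X), vote_fraction(m2, X))


class TestPredict:
    def test_recovers_training_labels_on_separable_data(self, toy_length_model):
        model, _, instances = toy_length_model
        X = np.vstack([i.features.as_array() for i in instances])
        preds = predict(model, X, refs=[i.orf_ref for i in instances])
        assert [p.label for p in preds] == [i.label for i in instances]

    def test_threshold_one_requires_unanimity(self, toy_length_model):
        model, _, instances = toy_length_model
        X = np.vstack([i.features.as_array() for i in instances])
        preds = predict(model, X, threshold=1.0)
        for p in preds:
            assert (p.label == "coding") == (p.p_coding == 1.0)

    def test_repeated_calls_identical(self, toy_length_model):
        model, _, instances = toy_length_model
        X = np.vstack([i.features.as_array() for i in instances[:50]])
        assert predict(model, X) == predict(model, X)

    def test_dataframe_column_mismatch_lists_expected_order(self, toy_length_model):
        model, _, _ = toy_length_model
        df = pd.DataFrame(np.zeros((2, 11)), columns=list(reversed(FEATURE_NAMES)))
        with pytest.raises(ModelError, match="length_nt, gc, gc1"):
            predict(model, df)

    def test_wrong_width_rejected(self, toy_length_model):
        model, _, _ = toy_length_model
        with pytest.raises(ModelError):
            predict(model, np.zeros((3, 7)))


class TestFeatureImportance:
    def test_length_ranks_first_on_length_separable_data(self, toy_length_model):
        model, _, _ = toy_length_model
        ranked = feature_importance(model)
        assert ranked[0][0] == "length_nt"
        assert ranked[0][1] == 100.0

    def test_noise_features_rank_near_zero(self, toy_length_model):
        model, _, _ = toy_length_model
        ranked = dict(feature_importance(model))
        # all 10 non-length features are iid noise in the toy set
        for name in FEATURE_NAMES[1:]:
            assert ranked[name] < 10.0

    def test_exactly_eleven_entries_both_kinds(self, toy_length_model):
        model, _, _ = toy_length_model
        assert len(feature_importance(model, "permutation")) == 11
        assert len(feature_importance(model, "gini")) == 11
        with pytest.raises(ValueError):
            feature_importance(model, "shap")


class TestPersistence:
    def test_round_trip_predictions_identical(self, toy_length_model, tmp_path):
        model, _, instances = toy_length_model
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        X = np.vstack([i.features.as_array() for i in instances])
        assert np.array_equal(vote_fraction(model, X), vote_fraction(loaded, X))
        assert loaded.chosen_mtry == model.chosen_mtry
        assert loaded.orf_config == model.orf_config
        assert loaded.variance_convention == model.variance_convention

    def test_corrupted_file_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.joblib"
        path.write_bytes(b"not a model at all")
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "absent.joblib")

    def test_version_mismatch_refused(self, toy_length_model, tmp_path):
        import joblib

        model, _, _ = toy_length_model
        path = tmp_path / "model.joblib"
        save_model(model, path)
        payload = joblib.load(path)
        payload["format_version"] = "999"
        joblib.dump(payload, path)
        with pytest.raises(ModelFormatError, match="999"):
            load_model(path)
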