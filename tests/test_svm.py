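import numpy as np
import pytest

from psbinder.io import Peptide
from psbinder.svm import (
    DEFAULT_C_GRID,
    DEFAULT_G_GRID,
    SVMConfig,
    grid_search,
    load_model,
    predict,
    predictions_tsv,
    save_model,
    train,
)


@pytest.fixture(scope="module")
def blobs():
    """Two well-separated Gaussian blobs, fixed seed."""
    rng = np.random.default_rng(42)
    n = 30
    X = np.vstack([
        rng.normal(loc=2.0, scale=0.3, size=(n, 2)),
        rng.normal(loc=-2.0, scale=0.3, size=(n, 2)),
    ])
    y = np.array([1] * n + [0] * n)
    return X, y


@pytest.fixture(scope="module")
def overlapping():
    rng = np.random.default_rng(7)
    n = 40
    X = np.vstack([
        rng.normal(0.6, 1.0, size=(n, 2)),
        rng.normal(-0.6, 1.0, size=(n, 2)),
    ])
    return X, np.array([1] * n + [0] * n)


def test_config_requires_positive_hyperparameters():
    with pytest.raises(ValueError):
        SVMConfig(c=0.0, g=1.0)
    with pytest.raises(ValueError):
        SVMConfig(c=1.0, g=-1.0)


def test_canonical_grid_bounds():
    assert DEFAULT_C_GRID[0] == 2.0**-5 and DEFAULT_C_GRID[-1] == 2.0**15
    assert DEFAULT_G_GRID[0] == 2.0**-15 and DEFAULT_G_GRID[-1] == 2.0**3


class TestGridSearch:
    def test_separable_reaches_perfect_cv(self, blobs):
        X, y = blobs
        config, acc = grid_search(X, y, seed=0)
        assert acc == 1.0
        assert config.c > 0 and config.g > 0

    def test_deterministic_given_seed(self, blobs):
        X, y = blobs
        a, _ = grid_search(X, y, seed=0)
        b, _ = grid_search(X, y, seed=0)
        assert a == b

    def test_beats_near_default_point(self, overlapping):
        from psbinder.evaluation import kfold_split
        from psbinder.svm import cv_accuracy

        X, y = overlapping
        folds = kfold_split(y, seed=0)
        _, best_acc = grid_search(X, y, folds=folds)
        baseline = cv_accuracy(X, y, SVMConfig(c=1.0, g=1.0 / X.shape[1]), folds)
        assert best_acc >= baseline

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((4, 2)), [1, 1, 1, 1])


class TestTrainPredict:
    def test_separable_resubstitution_perfect(self, blobs):
        X, y = blobs
        model = train(X, y, SVMConfig(c=8.0, g=0.5), seed=0)
        assert np.mean(model.svc.predict(X) == y) == 1.0

    def test_reproducible_probabilities(self, blobs):
        X, y = blobs
        cfg = SVMConfig(c=8.0, g=0.5)
        p1 = train(X, y, cfg, seed=5).predict_proba(X)
        p2 = train(X, y, cfg, seed=5).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            train(np.zeros((4, 2)), [1, 1, 1, 1], SVMConfig(1.0, 1.0))

    def test_subset_dimensionality_mismatch(self, blobs):
        X, y = blobs
        with pytest.raises(ValueError, match="feature"):
            train(X, y, SVMConfig(1.0, 1.0), feature_indices=[0, 1, 2])


@pytest.fixture(scope="module")
def peptide_model():
    """Tiny model on AAC(W) + AAC(A): tryptophan-rich vs alanine-rich."""
    from psbinder.features import FEATURE_NAMES, feature_matrix

    pos = ["WWWA", "WWAW", "AWWW", "WWWW", "WAWW", "WWWAA"]
    neg = ["AAAW", "AAWA", "AWAA", "AAAA", "WAAA", "AAAWW"]
    idx = [FEATURE_NAMES.index("W"), FEATURE_NAMES.index("A")]
    X = feature_matrix(pos + neg, idx)
    y = np.array([1] * 6 + [0] * 6)
    return train(X, y, SVMConfig(c=8.0, g=2.0), feature_indices=idx, seed=0)


class TestPeptidePrediction:
    def test_labels_follow_probability_threshold(self, peptide_model):
        rows = predict(peptide_model, ["WWWWA", "AAAAW"])
        for r in rows:
            assert r.error is None and 0.0 <= r.probability <= 1.0
            assert (r.label == "PSBP") == (r.probability >= 0.5)
        assert rows[0].probability > rows[1].probability

    def test_invalid_rows_annotated_not_fatal(self, peptide_model):
        rows = predict(
            peptide_model,
            [Peptide(id="ok", sequence="WWWA"), "WXA", "W"],
        )
        assert rows[0].error is None and rows[0].label is not None
        assert "ambiguous" in rows[1].error
        assert "length-1" in rows[2].error

    def test_prediction_is_deterministic(self, peptide_model):
        a = predict(peptide_model, ["WWAWA"])
        b = predict(peptide_model, ["WWAWA"])
        assert a[0].probability == b[0].probability

    def test_tsv_rendering(self, peptide_model):
        rows = predict(peptide_model, ["WWWA", "WXA"])
        tsv = predictions_tsv(rows)
        lines = tsv.strip().split("\n")
        assert lines[0].split("\t") == [
            "id", "sequence", "label", "probability", "error",
        ]
        assert "PSBP" in lines[1]
        assert "ambiguous" in lines[2]


class TestPersistence:
    def test_roundtrip_identical_probabilities(self, peptide_model, tmp_path):
        path = str(tmp_path / "model.joblib")
        save_model(peptide_model, path)
        loaded = load_model(path)
        probes = ["WWAWA", "AAWAA", "WAWAW", "AAAAA"]
        before = [r.probability for r in predict(peptide_model, probes)]
        after = [r.probability for r in predict(loaded, probes)]
        assert before == after
        assert loaded.feature_names == peptide_model.feature_names

    def test_tampered_subset_rejected(self, peptide_model, tmp_path):
        import joblib

        path = str(tmp_path / "model.joblib")
        save_model(peptide_model, path)
        payload = joblib.load(path)
        payload["feature_indices"] = payload["feature_indices"] + [3]
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="inconsistent"):
            load_model(path)

    def test_missing_path_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(str(tmp_path / "nope.joblib"))

    def test_foreign_file_rejected(self, tmp_path):
        import joblib

        path = str(tmp_path / "junk.joblib")
        joblib.dump({"hello": 1}, path)
        with pytest.raises(ValueError, match="not a psbinder model"):
            load_model(path)
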