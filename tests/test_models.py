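"""Zoo definition, splitting, grid-searched training and importances."""

import warnings

import numpy as np
import pandas as pd
import pytest

from phycysid.features import FEATURE_NAMES
from phycysid.models import (CV_FOLDS, DEFAULT_GRIDS, IMPORTANCE_KIND,
                             MODEL_NAMES, build_zoo,
                             extract_feature_importance, load_grids,
                             split_dataset, train_with_grid_search)


def _separable_data(n=200, n_features=6, seed=0, informative=0):
    """Two classes separated along one feature; the rest is noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    y = np.array(["1"] * (n // 2) + ["0"] * (n - n // 2))
    X[: n // 2, informative] += 6.0
    cols = [f"f{i}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), y


def test_zoo_has_fifteen_specs_with_declared_importance_kinds():
    zoo = build_zoo(seed=1)
    assert len(zoo) == 15 and set(zoo) == set(MODEL_NAMES)
    impurity = {n for n, s in zoo.items() if s.importance_kind == "impurity"}
    coeff = {n for n, s in zoo.items() if s.importance_kind == "coefficient"}
    none = {n for n, s in zoo.items() if s.importance_kind == "none"}
    assert impurity == {"RF", "GB", "AdaBoost", "DecisionT"}
    assert coeff == {"LR", "RC", "Perceptron", "LDA", "SGDC", "MLPC"}
    assert none == {"QDA", "GNB", "BNB", "KNN", "Bagging"}


def test_split_sizes_stratification_and_determinism():
    X, y = _separable_data(n=1074, seed=2)
    split = split_dataset(X, y, seed=7)
    assert len(split.test_X) == 323          # ceil(0.30 * 1074)
    assert len(split.train_X) == 1074 - 323
    # class proportions preserved
    _, counts = np.unique(split.test_y, return_counts=True)
    assert set(counts) <= {161, 162}
    again = split_dataset(X, y, seed=7)
    assert list(split.test_X.index) == list(again.test_X.index)
    other = split_dataset(X, y, seed=8)
    assert list(split.test_X.index) != list(other.test_X.index)


def test_split_balanced_two_class_composition():
    X, y = _separable_data(n=1000, seed=3)
    split = split_dataset(X, y, seed=1)
    _, counts = np.unique(split.test_y, return_counts=True)
    assert counts.tolist() == [150, 150]


def test_split_rejects_singleton_class():
    X, _ = _separable_data(n=10)
    y = np.array(["a"] * 9 + ["b"])
    with pytest.raises(ValueError, match="single member"):
        split_dataset(X, y)


def test_linear_model_on_separable_data_and_cv_contract():
    X, y = _separable_data(n=300, seed=4)
    split = split_dataset(X, y, seed=4)
    zoo = build_zoo(seed=4)
    model = train_with_grid_search(zoo["LR"], split)
    acc = (model.predict(split.test_X) == split.test_y).mean()
    assert acc >= 0.95
    assert len(model.cv_fold_accuracies) == CV_FOLDS
    assert model.cv_accuracy_mean == pytest.approx(
        model.cv_fold_accuracies.mean())
    assert model.best_grid_point.keys() <= DEFAULT_GRIDS["LR"].keys()


def test_single_point_grid_equals_plain_fit():
    X, y = _separable_data(n=200, seed=5)
    split = split_dataset(X, y, seed=5)
    zoo = build_zoo(seed=5, grids={**DEFAULT_GRIDS, "LDA": {"solver": ["svd"]}})
    model = train_with_grid_search(zoo["LDA"], split)
    assert model.best_grid_point == {"solver": "svd"}


def test_constant_labels_rejected():
    X, _ = _separable_data(n=60, seed=6)
    y = np.array(["1"] * 60)
    split = type("S", (), {})()
    from phycysid.models import DatasetSplit
    split = DatasetSplit(X, X.iloc[:0], y, y[:0], seed=0)
    zoo = build_zoo(seed=6)
    with pytest.raises(ValueError, match="single class"):
        train_with_grid_search(zoo["LR"], split)


def test_zero_variance_feature_warns():
    X, y = _separable_data(n=120, seed=7)
    X["f5"] = 1.0
    split = split_dataset(X, y, seed=7)
    zoo = build_zoo(seed=7)
    with pytest.warns(UserWarning, match="zero-variance"):
        train_with_grid_search(zoo["GNB"], split)


def test_retraining_reproduces_cv_mean_exactly():
    X, y = _separable_data(n=240, seed=8)
    split = split_dataset(X, y, seed=8)
    zoo = build_zoo(seed=8)
    m1 = train_with_grid_search(zoo["RF"], split)
    m2 = train_with_grid_search(zoo["RF"], split)
    assert abs(m1.cv_accuracy_mean - m2.cv_accuracy_mean) < 1e-12


def test_label_shuffle_gives_chance_level_cv():
    """CV accuracy on shuffled labels sits near the majority-class rate."""
    X, y = _separable_data(n=400, seed=9)
    rng = np.random.default_rng(9)
    y_shuffled = rng.permutation(y)
    split = split_dataset(X, y_shuffled, seed=9)
    zoo = build_zoo(seed=9)
    model = train_with_grid_search(zoo["GNB"], split)
    assert abs(model.cv_accuracy_mean - 0.5) < 0.05


def test_importances_ranges_and_kinds():
    X, y = _separable_data(n=240, n_features=len(FEATURE_NAMES), seed=10,
                           informative=3)
    X.columns = list(FEATURE_NAMES)
    split = split_dataset(X, y, seed=10)
    zoo = build_zoo(seed=10)

    knn = train_with_grid_search(zoo["KNN"], split)
    assert extract_feature_importance(knn) is None

    rf = train_with_grid_search(zoo["RF"], split)
    imp = extract_feature_importance(rf)
    assert imp.sum() == pytest.approx(1.0)
    assert ((imp >= 0) & (imp <= 1)).all()
    assert imp.idxmax() == FEATURE_NAMES[3]  # single informative feature

    lr = train_with_grid_search(zoo["LR"], split)
    w = extract_feature_importance(lr)
    assert w.max() == 1.0 and w.min() == 0.0
    assert w.idxmax() == FEATURE_NAMES[3]

    mlp = train_with_grid_search(zoo["MLPC"], split)
    wm = extract_feature_importance(mlp)
    assert wm.max() == 1.0 and wm.min() == 0.0


def test_grid_override_loading(tmp_path):
    p = tmp_path / "grids.yaml"
    p.write_text("KNN:\n  n_neighbors: [1]\nMLPC:\n  hidden_layer_sizes:\n"
                 "  - [10]\n")
    grids = load_grids(p)
    assert grids["KNN"] == {"n_neighbors": [1]}
    assert grids["MLPC"] == {"hidden_layer_sizes": [(10,)]}
    assert grids["RF"] == DEFAULT_GRIDS["RF"]
    with pytest.raises(ValueError, match="unknown model"):
        p2 = tmp_path / "bad.yaml"
        p2.write_text("SVM:\n  C: [1]\n")
        load_grids(p2)
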