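"""Forest training, AUC vs the pair-count oracle, grid search, baselines."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from helpers import (
    auc_pair_count_oracle,
    generator_posterior_oracle,
    planted_onehot_matrix,
)
from pathometa.encoders import EncodedMatrix, encode_onehot, onehot_column_names
from pathometa.models import (
    RFConfig,
    default_mtry_grid,
    gini_importance,
    grid_search,
    kfold_auc,
    train_baseline,
    train_rf,
)
from pathometa.preprocess import filter_complete_cases, split_by_role
from pathometa.synthetic import SyntheticSpec, simulate_variants


def train_data(n, concordance, seed, missing_rate=0.0):
    spec = SyntheticSpec(
        n_benign=n // 2, n_pathogenic=n - n // 2, n_vus=0, n_ci=0,
        concordance=concordance, missing_rate=missing_rate, seed=seed,
    )
    table, _ = filter_complete_cases(simulate_variants(spec))
    return table


# -- AUC oracle ------------------------------------------------------------


def test_auc_equals_pair_count_oracle(rng):
    """Trapezoid ROC AUC is the Mann-Whitney concordant-pair fraction."""
    for _ in range(10):
        y = rng.integers(0, 2, size=20)
        if y.min() == y.max():
            continue
        # quantized scores force ties, exercising the 1/2 credit
        s = np.round(rng.random(20), 1)
        assert roc_auc_score(y, s) == pytest.approx(auc_pair_count_oracle(y, s), abs=1e-12)


# -- forests ---------------------------------------------------------------


def test_train_rf_separable_oob():
    table = train_data(200, concordance=1.0, seed=0)
    X = encode_onehot(table)
    model = train_rf(X, table.binary_labels(), RFConfig(n_trees=100, mtry=2, seed=0))
    assert model.oob_error <= 0.02


def test_unanimous_rows_score_exactly_zero_or_one():
    table = train_data(100, concordance=1.0, seed=1)
    X = encode_onehot(table)
    y = table.binary_labels()
    model = train_rf(X, y, RFConfig(n_trees=50, mtry=4, seed=1))
    probs = model.predict_proba_pathogenic(X.values)
    assert set(np.unique(probs)) <= {0.0, 1.0}
    assert (probs == y).all()


def test_single_class_rejected():
    table = train_data(40, concordance=0.9, seed=2)
    X = encode_onehot(table)
    with pytest.raises(ValueError):
        train_rf(X, np.ones(len(table), dtype=int), RFConfig(50, 2))


def test_kfold_no_signal_null(rng):
    table = train_data(400, concordance=0.9, seed=3)
    X = encode_onehot(table)
    y = rng.permutation(table.binary_labels())
    ev = kfold_auc(X, y, RFConfig(n_trees=100, mtry=2, seed=3), k=5)
    assert abs(ev.auc - 0.5) < 0.1


def test_oob_tracks_cv_at_moderate_signal():
    table = train_data(1000, concordance=0.75, seed=4)
    X = encode_onehot(table)
    y = table.binary_labels()
    cfg = RFConfig(n_trees=200, mtry=4, seed=4)
    model = train_rf(X, y, cfg)
    errs = []
    for tr, te in StratifiedKFold(10, shuffle=True, random_state=4).split(X.values, y):
        m = train_rf(
            EncodedMatrix(X.values[tr], X.column_names, "onehot"), y[tr], cfg
        )
        pred = (m.predict_proba_pathogenic(X.values[te]) >= 0.5).astype(int)
        errs.append(float(np.mean(pred != y[te])))
    assert abs(model.oob_error - np.mean(errs)) <= 0.05


def test_auc_monotone_in_concordance():
    aucs = []
    for conc in (0.6, 0.75, 0.9):
        table = train_data(800, concordance=conc, seed=5)
        X = encode_onehot(table)
        ev = kfold_auc(X, table.binary_labels(), RFConfig(100, 4, seed=5), k=5)
        aucs.append(ev.auc)
    assert aucs[0] < aucs[1] < aucs[2]


# -- grid search -----------------------------------------------------------


@pytest.mark.parametrize(
    "d,expected", [(23, (2, 4, 11, 23)), (8, (2, 4, 8)), (2, (1, 2)), (1, (1,))]
)
def test_default_mtry_grid(d, expected):
    assert default_mtry_grid(d) == expected


def test_grid_search_shape_and_determinism():
    table = train_data(200, concordance=0.9, seed=6)
    kw = dict(
        encodings=("onehot",), tree_grid=(50, 100), mtry_grid=(2, 4), seed=6, k=5
    )
    r1 = grid_search(table, **kw)
    r2 = grid_search(table, **kw)
    assert len(r1.entries) == 4
    assert r1.best_index == r2.best_index
    assert [e.evaluation.auc for e in r1.entries] == [
        e.evaluation.auc for e in r2.entries
    ]
    assert [e.evaluation.oob_error for e in r1.entries] == [
        e.evaluation.oob_error for e in r2.entries
    ]
    best = r1.best.evaluation
    assert all(best.auc >= e.evaluation.auc for e in r1.entries)


def test_grid_search_empty_grid_rejected():
    table = train_data(60, concordance=0.9, seed=7)
    with pytest.raises(ValueError):
        grid_search(table, encodings=("onehot",), tree_grid=())


def test_grid_search_mtry_clipped_to_dimension():
    """mtry values above the encoded d are dropped per encoding."""
    table = train_data(120, concordance=0.9, seed=8)
    r = grid_search(
        table, encodings=("label",), tree_grid=(50,), mtry_grid=(2, 23), seed=8, k=4
    )
    assert [e.rf_config.mtry for e in r.entries] == [2]


# -- importances -----------------------------------------------------------


def test_gini_importance_normalized_and_planted_recovery(rng):
    Z, names, y = planted_onehot_matrix(rng, n=1000, informative="PROVEAN", signal=0.8)
    X = EncodedMatrix(Z, names, "onehot")
    model = train_rf(X, y, RFConfig(n_trees=100, mtry=2, seed=0))
    imp = gini_importance(model)
    assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(v >= 0 for v in imp.values())
    assert max(imp, key=imp.get) == "PROVEAN"
    assert set(imp) == set(n.split("=")[0] for n in names)


def test_all_noise_importances_flat(rng):
    """No planted signal: importances spread, none dominates strongly."""
    Z, names, y = planted_onehot_matrix(rng, n=5000, informative="PROVEAN", signal=0.5)
    # signal=0.5 on a 2-category predictor is exactly uninformative
    X = EncodedMatrix(Z, names, "onehot")
    model = train_rf(X, y, RFConfig(n_trees=100, mtry=4, seed=1))
    imp = gini_importance(model)
    assert max(imp.values()) < 3 * min(imp.values())


# -- baselines -------------------------------------------------------------


@pytest.mark.parametrize("kind", ["naive_bayes", "svm_linear", "svm_rbf"])
def test_baselines_on_separable_data(kind):
    table = train_data(300, concordance=1.0, seed=9)
    X = encode_onehot(table)
    _, ev = train_baseline(X, table.binary_labels(), kind, k=5, seed=9)
    assert ev.auc >= 0.95


def test_naive_bayes_approaches_generator_bayes_optimum():
    """NB on class-conditionally independent calls nears the closed-form
    posterior's AUC."""
    conc = 0.8
    table = train_data(2000, concordance=conc, seed=10)
    X = encode_onehot(table)
    y = table.binary_labels()
    _, ev = train_baseline(X, y, "naive_bayes", k=10, seed=10)
    oracle_auc = roc_auc_score(y, generator_posterior_oracle(table, conc))
    assert abs(ev.auc - oracle_auc) < 0.02


def test_baseline_permuted_labels_null(rng):
    table = train_data(400, concordance=0.9, seed=11)
    X = encode_onehot(table)
    y = rng.permutation(table.binary_labels())
    _, ev = train_baseline(X, y, "naive_bayes", k=5, seed=11)
    assert abs(ev.auc - 0.5) < 0.1


def test_unknown_baseline_kind():
    table = train_data(40, concordance=0.9, seed=12)
    X = encode_onehot(table)
    with pytest.raises(ValueError):
        train_baseline(X, table.binary_labels(), "logistic")
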