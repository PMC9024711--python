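"""Random-forest training, grid search, importances and baselines.

The metapredictor is a bagged forest of fully grown decision trees: each
tree fits a bootstrap sample of the training rows with ``mtry`` candidate
features per split, and the pathogenic probability of a variant (RFprob) is
the fraction of trees voting pathogenic. Fully grown trees have pure
leaves, so scikit-learn's averaged per-tree probabilities coincide with the
vote fraction, and a row on which all trees agree scores exactly 0 or 1.
No probability calibration is applied — the downstream RFprob >= 0.9
high-confidence rule relies on raw vote fractions.

Model quality is measured two ways, which should roughly agree: the
out-of-bag error (each tree scored on the rows its bootstrap left out) and
stratified 10-fold cross-validated ROC AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.svm import SVC

from .encoders import (
    ENCODING_KINDS,
    AutoencoderConfig,
    EncodedMatrix,
    FittedEncoder,
    fit_encoder,
)
from .preprocess import FeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFConfig:
    """Forest size, per-split feature draw (mtry) and RNG seed."""

    n_trees: int
    mtry: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class EvaluationResult:
    """Cross-validated AUC plus (when available) the out-of-bag error."""

    auc: float
    oob_error: float | None
    fold_aucs: tuple[float, ...]

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1)) if len(self.fold_aucs) > 1 else 0.0


@dataclass
class TrainedModel:
    """A fitted classifier with a uniform probability interface."""

    estimator: object
    kind: str
    feature_names: tuple[str, ...]
    oob_error: float | None = None

    def predict_proba_pathogenic(self, X: np.ndarray) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            return proba[:, list(est.classes_).index(1)]
        # SVM without probability estimates: monotone logistic of the margin.
        return 1.0 / (1.0 + np.exp(-est.decision_function(X)))


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class; cannot fit")
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y


def _forest(config: RFConfig, d: int, oob: bool) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=min(config.mtry, d),
        bootstrap=True,
        oob_score=oob,
        random_state=config.seed,
        n_jobs=1,
    )


def train_rf(X: EncodedMatrix, y: np.ndarray, config: RFConfig) -> TrainedModel:
    """Fit the forest on the full training matrix; OOB error from the fit."""
    y = _check_binary(y)
    rf = _forest(config, X.d, oob=True).fit(X.values, y)
    return TrainedModel(
        estimator=rf,
        kind="random_forest",
        feature_names=X.column_names,
        oob_error=float(1.0 - rf.oob_score_),
    )


def kfold_auc(
    X: EncodedMatrix,
    y: np.ndarray,
    config: RFConfig,
    k: int = 10,
    seed: int | None = None,
) -> EvaluationResult:
    """Stratified k-fold cross-validated ROC AUC of the forest.

    Folds containing a single class in their test split are skipped with a
    warning. Also fits once on the full data for the out-of-bag error.
    """
    y = _check_binary(y)
    if len(y) < k:
        raise ValueError(f"need at least k={k} rows, got {len(y)}")
    seed = config.seed if seed is None else seed
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    for tr, te in skf.split(X.values, y):
        if np.unique(y[te]).size < 2 or np.unique(y[tr]).size < 2:
            logger.warning("skipping single-class fold")
            continue
        rf = _forest(config, X.d, oob=False).fit(X.values[tr], y[tr])
        scores = rf.predict_proba(X.values[te])[:, list(rf.classes_).index(1)]
        fold_aucs.append(float(roc_auc_score(y[te], scores)))
    full = train_rf(X, y, config)
    return EvaluationResult(
        auc=float(np.mean(fold_aucs)),
        oob_error=full.oob_error,
        fold_aucs=tuple(fold_aucs),
    )


def default_mtry_grid(d: int) -> tuple[int, ...]:
    """{2, floor(sqrt(d)), floor(d/2), d}, clipped to [1, d], deduplicated."""
    raw = (2, math.floor(math.sqrt(d)), math.floor(d / 2), d)
    return tuple(sorted({min(max(m, 1), d) for m in raw}))


DEFAULT_TREE_GRID: tuple[int, ...] = tuple(range(50, 1001, 50))


@dataclass
class GridEntry:
    encoding_kind: str
    encoder_params: dict
    rf_config: RFConfig
    evaluation: EvaluationResult


@dataclass
class GridSearchResult:
    """All (encoding x RF config) evaluations plus the selected best entry.

    Best = maximum CV AUC; ties broken by lower OOB error, then fewer trees,
    then smaller mtry.
    """

    entries: list[GridEntry]
    best_index: int
    encoders: dict = field(default_factory=dict)

    @property
    def best(self) -> GridEntry:
        return self.entries[self.best_index]

    def best_encoder(self) -> FittedEncoder:
        e = self.best
        return self.encoders[(e.encoding_kind, _params_key(e.encoder_params))]


def _params_key(params: dict) -> tuple:
    return tuple(sorted(params.items()))


def grid_search(
    table: FeatureTable,
    encodings: tuple[str, ...] = ENCODING_KINDS,
    tree_grid: tuple[int, ...] | None = None,
    mtry_grid: tuple[int, ...] | None = None,
    seed: int = 0,
    k: int = 10,
    autoencoder_grid: tuple[AutoencoderConfig, ...] | None = None,
) -> GridSearchResult:
    """Exhaustive benchmark of encodings x forest hyperparameters.

    ``mtry_grid=None`` uses the per-encoding default (it depends on the
    encoded dimensionality d); the default tree grid is 50..1000 step 50.
    ``autoencoder_grid`` enumerates encoder hyperparameters for the
    autoencoder representation (default: a single 20-unit/20-epoch
    rectifier configuration).
    """
    trees = tuple(tree_grid) if tree_grid is not None else DEFAULT_TREE_GRID
    if not trees or not encodings:
        raise ValueError("empty grid")
    y = table.binary_labels()
    entries: list[GridEntry] = []
    encoders: dict = {}
    for kind in encodings:
        if kind == "autoencoder":
            ae_grid = autoencoder_grid or (AutoencoderConfig(seed=seed),)
            variants = [
                (
                    {
                        "hidden_units": c.hidden_units,
                        "activation": c.activation,
                        "epochs": c.epochs,
                    },
                    fit_encoder(table, kind, autoencoder_config=c),
                )
                for c in ae_grid
            ]
        else:
            variants = [({}, fit_encoder(table, kind))]
        for params, encoder in variants:
            encoders[(kind, _params_key(params))] = encoder
            X = encoder.transform(table)
            mtries = (
                tuple(m for m in mtry_grid if m <= X.d)
                if mtry_grid is not None
                else default_mtry_grid(X.d)
            )
            if not mtries:
                raise ValueError(f"empty mtry grid for encoding {kind!r} (d={X.d})")
            for n_trees in trees:
                for mtry in mtries:
                    cfg = RFConfig(n_trees=n_trees, mtry=mtry, seed=seed)
                    entries.append(
                        GridEntry(kind, params, cfg, kfold_auc(X, y, cfg, k=k))
                    )
    best = min(
        range(len(entries)),
        key=lambda i: (
            -entries[i].evaluation.auc,
            entries[i].evaluation.oob_error,
            entries[i].rf_config.n_trees,
            entries[i].rf_config.mtry,
        ),
    )
    return GridSearchResult(entries=entries, best_index=best, encoders=encoders)


def gini_importance(model: TrainedModel) -> dict[str, float]:
    """Mean-decrease-in-impurity importance, normalized to sum 1.

    For one-hot features (column names like ``SIFT=D``) the per-predictor
    importance is the sum over that predictor's category columns.
    """
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    agg: dict[str, float] = {}
    for name, w in zip(model.feature_names, imp):
        predictor = name.split("=")[0]
        agg[predictor] = agg.get(predictor, 0.0) + float(w)
    total = sum(agg.values())
    if total > 0:
        agg = {k: v / total for k, v in agg.items()}
    return agg


BASELINE_KINDS = ("naive_bayes", "svm_linear", "svm_rbf")


def train_baseline(
    X: EncodedMatrix,
    y: np.ndarray,
    kind: str,
    k: int = 10,
    seed: int = 0,
) -> tuple[TrainedModel, EvaluationResult]:
    """Naive Bayes or SVM comparison models with 10-fold CV AUC.

    Naive Bayes uses Bernoulli likelihoods on binary matrices (one-hot) and
    Gaussian otherwise. SVM scores are ranked via the decision margin (AUC
    is invariant to the monotone logistic used for probabilities).
    """
    y = _check_binary(y)

    def make():
        if kind == "naive_bayes":
            vals = np.asarray(X.values)
            if np.isin(vals, (0, 1)).all():
                return BernoulliNB()
            return GaussianNB()
        if kind == "svm_linear":
            return SVC(kernel="linear", random_state=seed)
        if kind == "svm_rbf":
            return SVC(kernel="rbf", random_state=seed)
        raise ValueError(f"unknown baseline kind {kind!r}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    for tr, te in skf.split(X.values, y):
        if np.unique(y[te]).size < 2 or np.unique(y[tr]).size < 2:
            logger.warning("skipping single-class fold")
            continue
        est = make().fit(X.values[tr], y[tr])
        if hasattr(est, "predict_proba"):
            scores = est.predict_proba(X.values[te])[:, list(est.classes_).index(1)]
        else:
            scores = est.decision_function(X.values[te])
        fold_aucs.append(float(roc_auc_score(y[te], scores)))
    model = TrainedModel(
        estimator=make().fit(X.values, y), kind=kind, feature_names=X.column_names
    )
    return model, EvaluationResult(
        auc=float(np.mean(fold_aucs)), oob_error=None, fold_aucs=tuple(fold_aucs)
    )
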