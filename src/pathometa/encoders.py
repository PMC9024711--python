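"""Four numeric representations of the categorical predictor calls.

* **label** — per predictor, categories coded 0..k-1 in lexicographic order
  (n x 8 integers).
* **onehot** — the indicator matrix Z: one binary column per category,
  J = 23 columns, exactly one 1 per predictor block per row.
* **mca** — multiple correspondence analysis of the indicator matrix,
  implemented from first principles (correspondence analysis of Z), keeping
  the first two row principal coordinates.
* **autoencoder** — a symmetric bottleneck network 23 -> h -> 2 -> h -> 23
  trained to reconstruct the one-hot rows; the representation is the 2-unit
  bottleneck activation.

MCA follows the indicator-matrix formulation: with n rows and Q = 8
predictors, the correspondence matrix is P = Z/(nQ); row masses r = 1/n,
column masses c = column sums of P; the matrix of standardized residuals
S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} is decomposed by SVD, S = U S V^T, and
row principal coordinates are D_r^{-1/2} U S. New rows are projected through
the transition formula: coordinates = (z/Q) B with B = D_c^{-1/2} V the
category standard coordinates. Total inertia (sum of squared singular
values) equals (J - Q)/Q when every category is observed. No
Benzecri/Greenacre eigenvalue correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .preprocess import FeatureTable
from .vocab import PREDICTOR_ORDER, VOCABULARIES

EncodingKind = Literal["label", "onehot", "mca", "autoencoder"]

ENCODING_KINDS: tuple[str, ...] = ("label", "onehot", "mca", "autoencoder")


@dataclass
class EncodedMatrix:
    """A numeric design matrix plus the provenance of its encoding."""

    values: np.ndarray
    column_names: tuple[str, ...]
    encoding_kind: str
    fit_metadata: object | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("values shape must be (n, len(column_names))")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def onehot_column_names(
    predictor_order: tuple[str, ...] = PREDICTOR_ORDER,
) -> tuple[str, ...]:
    return tuple(
        f"{p}={c}" for p in predictor_order for c in VOCABULARIES[p].categories
    )


def encode_label(table: FeatureTable) -> EncodedMatrix:
    """Integer codes 0..k-1 per predictor, lexicographic category order."""
    cols = []
    for p in table.predictor_order:
        codes = {c: i for i, c in enumerate(VOCABULARIES[p].categories)}
        cols.append([codes[v.calls[p]] for v in table.rows])
    values = np.array(cols, dtype=int).T.reshape(len(table), len(table.predictor_order))
    return EncodedMatrix(values, tuple(table.predictor_order), "label")


def encode_onehot(table: FeatureTable) -> EncodedMatrix:
    """The n x J indicator matrix (J = 23 for the full vocabularies)."""
    names = onehot_column_names(table.predictor_order)
    col_of = {name: j for j, name in enumerate(names)}
    Z = np.zeros((len(table), len(names)), dtype=int)
    for i, v in enumerate(table.rows):
        for p in table.predictor_order:
            Z[i, col_of[f"{p}={v.calls[p]}"]] = 1
    return EncodedMatrix(Z, names, "onehot")


# ---------------------------------------------------------------------------
# Multiple correspondence analysis
# ---------------------------------------------------------------------------


@dataclass
class MCAModel:
    """Fitted indicator-matrix MCA.

    ``principal_axes`` holds the category *standard* coordinates
    B = D_c^{-1/2} V for the retained axes; projecting a one-hot row z gives
    its principal coordinates as (z/Q) B. ``singular_values`` are the
    retained singular values; ``all_singular_values`` the full spectrum
    (their squared sum is the total inertia).
    """

    column_names: tuple[str, ...]
    category_masses: np.ndarray
    row_mass: float
    singular_values: np.ndarray
    principal_axes: np.ndarray
    all_singular_values: np.ndarray
    n_predictors: int
    retained_dims: int = 2

    @property
    def total_inertia(self) -> float:
        return float(np.sum(self.all_singular_values**2))


def fit_mca(onehot: EncodedMatrix, retained_dims: int = 2) -> MCAModel:
    """Correspondence analysis of the indicator matrix.

    Requires at least 3 distinct rows and at least ``retained_dims`` positive
    singular values. Per-axis sign is fixed by making the largest-magnitude
    category loading positive, so fits are deterministic.
    """
    if onehot.encoding_kind != "onehot":
        raise ValueError("fit_mca expects a onehot EncodedMatrix")
    Z = np.asarray(onehot.values, dtype=float)
    n, J = Z.shape
    if np.unique(Z, axis=0).shape[0] < 3:
        raise ValueError("MCA needs at least 3 distinct rows")
    Q = int(round(Z[0].sum()))
    total = n * Q
    P = Z / total
    r = np.full(n, 1.0 / n)
    c = P.sum(axis=0)
    pos = c > 0
    # Standardized residuals on observed categories only; unobserved
    # categories carry zero mass and zero loading.
    S = np.zeros_like(P)
    S[:, pos] = (P[:, pos] - np.outer(r, c[pos])) / np.sqrt(
        np.outer(r, c[pos])
    )
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sig > 1e-12
    sig_pos = sig[keep]
    if sig_pos.size < retained_dims:
        raise ValueError(
            f"only {sig_pos.size} positive singular values; "
            f"cannot retain {retained_dims} dimensions"
        )
    V = Vt[:retained_dims].T  # J x k
    B = np.zeros((J, retained_dims))
    B[pos] = V[pos] / np.sqrt(c[pos])[:, None]
    # Deterministic sign: largest |loading| per axis made positive.
    for k in range(retained_dims):
        j = int(np.argmax(np.abs(B[:, k])))
        if B[j, k] < 0:
            B[:, k] = -B[:, k]
    return MCAModel(
        column_names=onehot.column_names,
        category_masses=c,
        row_mass=1.0 / n,
        singular_values=sig[:retained_dims].copy(),
        principal_axes=B,
        all_singular_values=sig_pos.copy(),
        n_predictors=Q,
    )


def transform_mca(model: MCAModel, onehot: EncodedMatrix) -> EncodedMatrix:
    """Row principal coordinates of (new) one-hot rows under a fitted MCA."""
    if onehot.column_names != model.column_names:
        raise ValueError("onehot columns do not match the fitted MCA")
    Z = np.asarray(onehot.values, dtype=float)
    coords = (Z / model.n_predictors) @ model.principal_axes
    names = tuple(f"MCA{k + 1}" for k in range(model.retained_dims))
    return EncodedMatrix(coords, names, "mca", fit_metadata=model)


# ---------------------------------------------------------------------------
# Bottleneck autoencoder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AutoencoderConfig:
    """Hyperparameters of the bottleneck autoencoder.

    The benchmark grid uses hidden_units and epochs in {10, 20, 30} and the
    three activations below; any hidden_units >= bottleneck and epochs >= 1
    are accepted. Dropout (rectifier_dropout only) acts on the two hidden
    layers during training; inference is deterministic.
    """

    hidden_units: int = 20
    bottleneck_units: int = 2
    activation: str = "rectifier"
    dropout_rate: float = 0.2
    epochs: int = 20
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.activation not in ("rectifier", "rectifier_dropout", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.hidden_units < self.bottleneck_units:
            raise ValueError("hidden_units must be >= bottleneck_units")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class Autoencoder:
    """Symmetric MSE autoencoder d -> h -> b -> h -> d trained by SGD.

    Weights are Glorot-initialized from a seeded generator; training runs
    ``epochs`` full shuffled passes in minibatches. The bottleneck layer is
    linear; the hidden layers use the configured activation. A fixed seed
    gives bit-identical weights and representations.
    """

    def __init__(self, config: AutoencoderConfig):
        self.config = config
        self._weights: list[np.ndarray] | None = None
        self._biases: list[np.ndarray] | None = None
        self.loss_history_: list[float] = []
        self.input_columns: tuple[str, ...] | None = None

    # -- internals ---------------------------------------------------------

    def _act(self, x: np.ndarray) -> np.ndarray:
        if self.config.activation == "tanh":
            return np.tanh(x)
        return np.maximum(x, 0.0)

    def _act_grad(self, pre: np.ndarray) -> np.ndarray:
        if self.config.activation == "tanh":
            return 1.0 - np.tanh(pre) ** 2
        return (pre > 0).astype(float)

    def _init(self, d: int, rng: np.random.Generator) -> None:
        sizes = [d, self.config.hidden_units, self.config.bottleneck_units,
                 self.config.hidden_units, d]
        self._weights, self._biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            self._weights.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
            self._biases.append(np.zeros(fan_out))

    def _forward(
        self, X: np.ndarray, rng: np.random.Generator | None
    ) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray | None]]:
        """Returns (pre-activations, activations incl. input, dropout masks)."""
        drop = (
            self.config.dropout_rate
            if self.config.activation == "rectifier_dropout" and rng is not None
            else 0.0
        )
        acts, pres, masks = [X], [], []
        a = X
        for layer, (W, b) in enumerate(zip(self._weights, self._biases)):
            z = a @ W + b
            pres.append(z)
            if layer == 3:  # output layer: linear reconstruction
                a = z
            elif layer == 1:  # bottleneck: linear representation
                a = z
            else:
                a = self._act(z)
            mask = None
            if drop > 0 and layer in (0, 2):  # hidden layers only
                mask = (rng.random(a.shape) >= drop) / (1.0 - drop)
                a = a * mask
            masks.append(mask)
            acts.append(a)
        return pres, acts, masks

    # -- API ---------------------------------------------------------------

    def fit(self, onehot: EncodedMatrix) -> "Autoencoder":
        cfg = self.config
        X = np.asarray(onehot.values, dtype=float)
        n, d = X.shape
        if n == 0:
            raise ValueError("cannot fit on an empty matrix")
        self.input_columns = onehot.column_names
        rng = np.random.default_rng(cfg.seed)
        self._init(d, rng)
        self.loss_history_ = [self.reconstruction_loss(onehot)]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb = X[idx]
                pres, acts, masks = self._forward(Xb, rng)
                m = Xb.shape[0]
                # MSE = mean over batch and features of (recon - x)^2
                delta = 2.0 * (acts[-1] - Xb) / (m * d)
                for layer in range(3, -1, -1):
                    if masks[layer] is not None:
                        delta = delta * masks[layer]
                    if layer in (0, 2):  # activated layers
                        delta = delta * self._act_grad(pres[layer])
                    gW = acts[layer].T @ delta
                    gb = delta.sum(axis=0)
                    if layer > 0:
                        delta = delta @ self._weights[layer].T
                    self._weights[layer] -= cfg.learning_rate * gW
                    self._biases[layer] -= cfg.learning_rate * gb
            loss = self.reconstruction_loss(onehot)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite reconstruction loss")
            self.loss_history_.append(loss)
        return self

    def reconstruction_loss(self, onehot: EncodedMatrix) -> float:
        X = np.asarray(onehot.values, dtype=float)
        _, acts, _ = self._forward(X, rng=None)
        return float(np.mean((acts[-1] - X) ** 2))

    def transform(self, onehot: EncodedMatrix) -> EncodedMatrix:
        if self._weights is None:
            raise RuntimeError("autoencoder is not fitted")
        if onehot.column_names != self.input_columns:
            raise ValueError("onehot columns do not match the fitted autoencoder")
        X = np.asarray(onehot.values, dtype=float)
        _, acts, _ = self._forward(X, rng=None)
        names = tuple(f"AE{k + 1}" for k in range(self.config.bottleneck_units))
        return EncodedMatrix(acts[2], names, "autoencoder", fit_metadata=self)


def fit_autoencoder(onehot: EncodedMatrix, config: AutoencoderConfig) -> Autoencoder:
    return Autoencoder(config).fit(onehot)


def transform_autoencoder(encoder: Autoencoder, onehot: EncodedMatrix) -> EncodedMatrix:
    return encoder.transform(onehot)


# ---------------------------------------------------------------------------
# Uniform encoder front-end used by grid search and the pipeline
# ---------------------------------------------------------------------------


@dataclass
class FittedEncoder:
    """One of the four encodings, fitted on a train table, reusable at
    prediction time."""

    kind: str
    mca: MCAModel | None = None
    autoencoder: Autoencoder | None = None
    params: dict = field(default_factory=dict)

    def transform(self, table: FeatureTable) -> EncodedMatrix:
        if self.kind == "label":
            return encode_label(table)
        onehot = encode_onehot(table)
        if self.kind == "onehot":
            return onehot
        if self.kind == "mca":
            return transform_mca(self.mca, onehot)
        if self.kind == "autoencoder":
            return self.autoencoder.transform(onehot)
        raise ValueError(f"unknown encoding kind {self.kind!r}")


def fit_encoder(
    table: FeatureTable,
    kind: str,
    autoencoder_config: AutoencoderConfig | None = None,
) -> FittedEncoder:
    """Fit (if stateful) one of the four encodings on a train table."""
    if kind in ("label", "onehot"):
        return FittedEncoder(kind=kind)
    onehot = encode_onehot(table)
    if kind == "mca":
        return FittedEncoder(kind=kind, mca=fit_mca(onehot))
    if kind == "autoencoder":
        cfg = autoencoder_config or AutoencoderConfig()
        return FittedEncoder(
            kind=kind,
            autoencoder=fit_autoencoder(onehot, cfg),
            params={
                "hidden_units": cfg.hidden_units,
                "activation": cfg.activation,
                "epochs": cfg.epochs,
            },
        )
    raise ValueError(f"unknown encoding kind {kind!r}")
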