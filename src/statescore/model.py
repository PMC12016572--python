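"""The cell-state scoring model: a single-hidden-node network on binary input.

The architecture is deliberately minimal.  One hidden neuron receives the
binarized detection vector of a cell through per-gene weights ``w`` and a
bias ``b``, applies a ReLU, and feeds a two-node softmax head (``v``, ``c``)
that classifies the cell as state0 or state1.  Training minimizes
class-weighted categorical cross-entropy with an L1 penalty on ``w``
(coefficient 0.01 by default), which drives most gene weights toward zero
and leaves a sparse, directly interpretable weight vector.

The reported per-cell score is the hidden node's *pre-activation*,

    score = orientation * (sum_i w_i * g_i + b),

not the ReLU output: the linear form keeps the score a signed, unbounded
axis along which both poles remain distinguishable.  ``orientation`` is a
+/-1 flag fixed after training so that state1 cells always score high,
regardless of which pole the hidden node happened to encode.

The public surface follows the statsmodels convention: build a
:class:`CellStateModel` from data, call :meth:`~CellStateModel.fit`, and
work with the returned :class:`CellStateResults` (parameters, history,
``summary()``, scoring, weight ranking, query construction).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    BinaryMatrix,
    GeneUniverse,
    LabeledDataset,
    ScoreVector,
    align_and_binarize,
)
from .errors import SchemaError, TrainingError, UniverseMismatchError, ValidationError

MODEL_FORMAT_VERSION = 1
_LOG_EPS = 1e-12  # clamp for log-probabilities inside the loss


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults: L1 coefficient 0.01 on the input weights, Adam with learning
    rate 1e-3, batch size 128, at most 100 epochs, early stopping on a 10%
    stratified validation split with patience 5, best-epoch weights restored.
    """

    l1_coefficient: float = 0.01
    max_epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    patience: int = 5
    seed: int = 0
    restore_best: bool = True

    def __post_init__(self) -> None:
        if self.l1_coefficient < 0:
            raise ValidationError("l1_coefficient must be >= 0")
        if not (0 <= self.validation_fraction < 1):
            raise ValidationError("validation_fraction must be in [0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1 or self.patience < 0:
            raise ValidationError("max_epochs, batch_size >= 1 and patience >= 0")


@dataclass
class TrainHistory:
    """Per-epoch training curves (loss includes the L1 term)."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_accuracy": self.train_accuracy,
            }
        )


@dataclass
class FeatureModel:
    """All learned parameters of one cell-state feature.

    ``w`` (per-gene input weights) and ``b`` (hidden bias) define the score;
    ``v`` and ``c`` are the two-node softmax head; ``orientation`` is +1 or
    -1 so that oriented scores increase toward state1.
    """

    universe: GeneUniverse
    w: np.ndarray
    b: float
    v: np.ndarray
    c: np.ndarray
    orientation: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.w.shape != (len(self.universe),):
            raise ValidationError("need exactly one weight per universe gene")
        if self.v.shape != (2,) or self.c.shape != (2,):
            raise ValidationError("output layer must have two nodes")
        if self.orientation not in (1, -1):
            raise ValidationError("orientation must be +1 or -1")
        for arr in (self.w, self.v, self.c, np.asarray([self.b])):
            if not np.isfinite(arr).all():
                raise ValidationError("model parameters must be finite")

    @property
    def oriented_weights(self) -> pd.Series:
        """Per-gene weights with the orientation sign applied (state1-high)."""
        return pd.Series(
            self.orientation * self.w, index=list(self.universe.symbols), name="weight"
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        """Write a versioned JSON model file (weights keyed by gene symbol)."""
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "weights": {s: float(wi) for s, wi in zip(self.universe.symbols, self.w)},
            "universe": list(self.universe.symbols),
            "bias": float(self.b),
            "output_weights": [float(x) for x in self.v],
            "output_biases": [float(x) for x in self.c],
            "orientation": int(self.orientation),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "FeatureModel":
        try:
            doc = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise SchemaError(f"model file {path} is not valid JSON: {e}") from e
        version = doc.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise SchemaError(
                f"unsupported model format_version {version!r} in {path} "
                f"(this build reads version {MODEL_FORMAT_VERSION})"
            )
        for key in ("weights", "universe", "bias", "output_weights", "output_biases"):
            if key not in doc:
                raise SchemaError(f"model file {path} missing field {key!r}")
        universe = GeneUniverse(tuple(doc["universe"]))
        weights = doc["weights"]
        missing = [s for s in universe.symbols if s not in weights]
        if missing:
            raise SchemaError(f"model file {path} missing weights for {missing[:5]}")
        w = np.array([weights[s] for s in universe.symbols], dtype=float)
        return cls(
            universe=universe,
            w=w,
            b=float(doc["bias"]),
            v=np.asarray(doc["output_weights"], dtype=float),
            c=np.asarray(doc["output_biases"], dtype=float),
            orientation=int(doc.get("orientation", 1)),
            meta=doc.get("meta", {}),
        )


def save_model(model: FeatureModel, path: str | os.PathLike) -> None:
    model.save(path)


def load_model(path: str | os.PathLike) -> FeatureModel:
    return FeatureModel.load(path)


# -- elementary operations ---------------------------------------------------


def class_weights(labels: Sequence[int] | np.ndarray) -> np.ndarray:
    """Balanced class weights ``n_total / (2 * n_k)`` for k in {0, 1}.

    The minority class gets the larger weight; weighted class sizes are
    equal, so neither pole dominates the loss through sample size alone.
    """
    labels = np.asarray(labels, dtype=int)
    n0 = int((labels == 0).sum())
    n1 = int((labels == 1).sum())
    if n0 == 0 or n1 == 0:
        raise TrainingError("both state0 and state1 cells are required")
    n = n0 + n1
    return np.array([n / (2.0 * n0), n / (2.0 * n1)])


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(
    model: FeatureModel, g: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward pass for one cell or a batch of cells.

    Returns ``(z, h, p)``: hidden pre-activation ``z = w . g + b``,
    activation ``h = max(z, 0)``, and the two class probabilities
    ``p = softmax(v h + c)``.
    """
    g = np.asarray(g)
    if not np.isin(g, (0, 1)).all():
        raise ValidationError("input vector must be binary")
    if g.shape[-1] != len(model.universe):
        raise ValidationError(
            f"input has {g.shape[-1]} genes, model expects {len(model.universe)}"
        )
    z = g @ model.w + model.b
    h = np.maximum(z, 0.0)
    logits = np.multiply.outer(h, model.v) + model.c
    return z, h, _softmax(logits)


def loss(
    model: FeatureModel,
    batch: np.ndarray,
    labels: np.ndarray,
    class_wts: np.ndarray,
    l1_coefficient: float,
) -> float:
    """Class-weighted categorical cross-entropy plus L1 penalty on ``w``.

    Mean over cells of ``class_wt[label] * (-log p[label])``, with
    probabilities clamped at 1e-12, plus ``l1_coefficient * sum_i |w_i|``.
    """
    batch = np.atleast_2d(np.asarray(batch))
    labels = np.asarray(labels, dtype=int)
    if batch.shape[0] == 0:
        raise ValidationError("batch must be non-empty")
    _, _, p = forward(model, batch)
    p_label = np.clip(p[np.arange(len(labels)), labels], _LOG_EPS, 1.0)
    ce = float(np.mean(class_wts[labels] * (-np.log(p_label))))
    return ce + l1_coefficient * float(np.abs(model.w).sum())


# -- training ----------------------------------------------------------------


class _Adam:
    """Plain Adam over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _stratified_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified holdout; each class contributes ~fraction."""
    val_idx: list[np.ndarray] = []
    for k in (0, 1):
        idx = np.flatnonzero(labels == k)
        idx = rng.permutation(idx)
        n_val = int(round(fraction * len(idx)))
        n_val = min(n_val, len(idx) - 1)  # keep at least one training cell per class
        val_idx.append(idx[:n_val])
    val = np.sort(np.concatenate(val_idx))
    train = np.setdiff1d(np.arange(len(labels)), val)
    return train, val


def _batched_loss_acc(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    b: float,
    v: np.ndarray,
    c: np.ndarray,
    cw: np.ndarray,
    l1: float,
) -> tuple[float, float]:
    z = X @ w + b
    h = np.maximum(z, 0.0)
    p = _softmax(np.multiply.outer(h, v) + c)
    p_label = np.clip(p[np.arange(len(y)), y], _LOG_EPS, 1.0)
    ce = float(np.mean(cw[y] * (-np.log(p_label))))
    acc = float(np.mean(p.argmax(axis=1) == y))
    return ce + l1 * float(np.abs(w).sum()), acc


def train_feature(
    data: LabeledDataset, config: TrainConfig | None = None
) -> tuple[FeatureModel, TrainHistory]:
    """Train a feature model by seeded mini-batch Adam with early stopping.

    Fully deterministic given ``(data, config)``: initialization, the
    validation split, and the per-epoch shuffles all derive from
    ``config.seed``.  After training the orientation flag is set from the
    class means of the pre-activation score on the training cells, so the
    oriented score of state1 cells exceeds that of state0 cells.
    """
    config = config or TrainConfig()
    X = data.matrix.g.astype(np.float64)
    y = data.labels
    n0, n1 = data.class_counts()
    if n0 == 0 or n1 == 0:
        raise TrainingError("training data must contain both states")
    if len(data.matrix.universe) < 1:
        raise TrainingError("gene universe is empty")
    cw = class_weights(y)
    l1 = config.l1_coefficient

    rng = np.random.default_rng(config.seed)
    G = X.shape[1]
    w = rng.uniform(-0.05, 0.05, size=G)
    b = np.array([0.01])  # small positive bias avoids a dead ReLU at start
    # fan-based uniform init for the 1 -> 2 output layer; a zero start here
    # would block all gradient flow into w while the L1 term erases it
    v = rng.uniform(-np.sqrt(2.0), np.sqrt(2.0), size=2)
    c = np.zeros(2)

    if config.validation_fraction > 0:
        tr_idx, val_idx = _stratified_split(y, config.validation_fraction, rng)
    else:
        tr_idx, val_idx = np.arange(len(y)), np.array([], dtype=int)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = _Adam([w, b, v, c], lr=config.learning_rate)
    history = TrainHistory()
    best = {
        "loss": np.inf,
        "w": w.copy(),
        "b": b.copy(),
        "v": v.copy(),
        "c": c.copy(),
    }
    stale = 0

    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(ytr))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, yb = Xtr[idx], ytr[idx]
            nb = len(idx)
            z = Xb @ w + b[0]
            h = np.maximum(z, 0.0)
            p = _softmax(np.multiply.outer(h, v) + c)
            dlogits = p.copy()
            dlogits[np.arange(nb), yb] -= 1.0
            dlogits *= (cw[yb] / nb)[:, None]
            grad_v = dlogits.T @ h
            grad_c = dlogits.sum(axis=0)
            dh = dlogits @ v
            dz = dh * (z > 0)  # ReLU'(0) taken as 0
            grad_w = Xb.T @ dz + l1 * np.sign(w)
            grad_b = np.array([dz.sum()])
            opt.step([grad_w, grad_b, grad_v, grad_c])

        tr_loss, tr_acc = _batched_loss_acc(Xtr, ytr, w, b[0], v, c, cw, l1)
        if len(yval):
            vl_loss, _ = _batched_loss_acc(Xval, yval, w, b[0], v, c, cw, l1)
        else:
            vl_loss = tr_loss
        history.train_loss.append(tr_loss)
        history.val_loss.append(vl_loss)
        history.train_accuracy.append(tr_acc)

        if vl_loss < best["loss"] - 1e-12:
            best = {
                "loss": vl_loss,
                "w": w.copy(),
                "b": b.copy(),
                "v": v.copy(),
                "c": c.copy(),
            }
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break

    if config.restore_best and np.isfinite(best["loss"]):
        w, b, v, c = best["w"], best["b"], best["v"], best["c"]

    # Orientation: make the oriented score increase toward state1.
    z_all = X @ w + b[0]
    orientation = 1 if z_all[y == 1].mean() >= z_all[y == 0].mean() else -1

    model = FeatureModel(
        universe=data.matrix.universe,
        w=w,
        b=float(b[0]),
        v=v,
        c=c,
        orientation=orientation,
        meta={
            "n_state0": n0,
            "n_state1": n1,
            "epochs_run": history.n_epochs,
            "config": asdict(config),
        },
    )
    return model, history


# -- scoring -----------------------------------------------------------------


def _check_aligned(model: FeatureModel, m: BinaryMatrix) -> None:
    if m.universe != model.universe:
        raise UniverseMismatchError(
            "matrix universe differs from the model universe; run "
            "align_and_binarize(expr, model.universe) first"
        )


def score_cells(model: FeatureModel, m: BinaryMatrix) -> ScoreVector:
    """Per-cell oriented score: ``orientation * (sum_i w_i g_i + b)``.

    This is the hidden node's pre-activation — the linear form, with no
    ReLU — so the score stays informative on both sides of zero.
    """
    _check_aligned(model, m)
    z = m.g.astype(float) @ model.w + model.b
    return ScoreVector(
        cell_ids=list(m.cell_ids), values=model.orientation * z, name="score"
    )


def predict_state(model: FeatureModel, m: BinaryMatrix) -> ScoreVector:
    """Per-cell probability of state1 from the softmax head."""
    _check_aligned(model, m)
    _, _, p = forward(model, m.g)
    return ScoreVector(cell_ids=list(m.cell_ids), values=p[:, 1], name="p_state1")


# -- statsmodels-style front end ---------------------------------------------


class CellStateModel:
    """A cell-state feature model specification bound to labeled data.

    Parameters
    ----------
    data
        Binarized cells x universe matrix plus per-cell {0,1} state labels.
    feature_name
        Human-readable name of the cellular feature (e.g. "T cell
        exhaustion"); carried into the fitted model's metadata.

    Examples
    --------
    >>> model = CellStateModel(dataset, feature_name="exhaustion")
    >>> res = model.fit(seed=0)
    >>> res.score(dataset.matrix).to_series().head()
    """

    def __init__(self, data: LabeledDataset, feature_name: str = "feature"):
        self.data = data
        self.feature_name = feature_name

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        labels: Sequence[int] | pd.Series,
        universe: GeneUniverse | None = None,
        feature_name: str = "feature",
        threshold: float = 0.0,
    ) -> "CellStateModel":
        """Build from a cells x genes count DataFrame.

        The universe defaults to the DataFrame's own gene columns; labels
        given as a Series are aligned by cell id.
        """
        from .containers import ExpressionMatrix

        expr = ExpressionMatrix(
            cell_ids=[str(i) for i in counts.index],
            gene_ids=[str(g) for g in counts.columns],
            counts=counts.to_numpy(),
        )
        if universe is None:
            universe = GeneUniverse(tuple(expr.gene_ids))
        bm = align_and_binarize(expr, universe, threshold=threshold)
        if isinstance(labels, pd.Series):
            labels = labels.reindex(bm.cell_ids).to_numpy()
        return cls(
            LabeledDataset(matrix=bm, labels=np.asarray(labels, dtype=int)),
            feature_name=feature_name,
        )

    @classmethod
    def from_expression(
        cls,
        expr,
        labels,
        universe: GeneUniverse,
        feature_name: str = "feature",
        threshold: float = 0.0,
    ) -> "CellStateModel":
        bm = align_and_binarize(expr, universe, threshold=threshold)
        return cls(LabeledDataset(bm, np.asarray(labels, dtype=int)), feature_name)

    def fit(self, config: TrainConfig | None = None, **kwargs) -> "CellStateResults":
        """Fit and return a :class:`CellStateResults`.

        Keyword arguments override individual :class:`TrainConfig` fields,
        e.g. ``fit(seed=3, l1_coefficient=0.1)``.
        """
        if config is None:
            config = TrainConfig(**kwargs)
        elif kwargs:
            config = TrainConfig(**{**asdict(config), **kwargs})
        params, history = train_feature(self.data, config)
        params.meta["feature_name"] = self.feature_name
        return CellStateResults(self, params, history, config)


class CellStateResults:
    """Fitted cell-state model: parameters, history and derived quantities."""

    def __init__(
        self,
        model: CellStateModel,
        params: FeatureModel,
        history: TrainHistory,
        config: TrainConfig,
    ):
        self.model = model
        self.params = params
        self.history = history
        self.config = config

    @property
    def weights(self) -> pd.Series:
        """Oriented per-gene weights (positive = up in state1)."""
        return self.params.oriented_weights

    def score(self, m: BinaryMatrix | None = None) -> ScoreVector:
        return score_cells(self.params, m if m is not None else self.model.data.matrix)

    def predict_state(self, m: BinaryMatrix | None = None) -> ScoreVector:
        return predict_state(
            self.params, m if m is not None else self.model.data.matrix
        )

    def rank_weights(self) -> pd.DataFrame:
        from .interpret import rank_weights

        return rank_weights(self.params)

    def top_weights(self, n: int = 250, side: str = "both"):
        from .interpret import rank_weights, top_weights

        return top_weights(rank_weights(self.params), n=n, side=side)

    def build_query(self, n: int = 250):
        from .connectivity import build_query

        return build_query(self.params, n=n)

    def save(self, path: str | os.PathLike) -> None:
        self.params.save(path)

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of statsmodels results."""
        p = self.params
        n0, n1 = self.model.data.class_counts()
        wts = self.weights
        nz = int((wts != 0).sum())
        top_pos = wts.sort_values(ascending=False).head(5)
        top_neg = wts.sort_values().head(5)
        sc = self.score().values
        y = self.model.data.labels
        lines = [
            "Cell-State Feature Model Results",
            "=" * 44,
            f"Feature:            {self.model.feature_name}",
            f"Universe genes:     {len(p.universe)}",
            f"Cells (state0/1):   {n0} / {n1}",
            f"Epochs run:         {self.history.n_epochs}",
            f"Final train loss:   {self.history.train_loss[-1]:.4f}",
            f"Final val loss:     {self.history.val_loss[-1]:.4f}",
            f"L1 coefficient:     {self.config.l1_coefficient}",
            f"Orientation:        {p.orientation:+d}",
            f"Nonzero weights:    {nz}",
            f"Mean score state0:  {sc[y == 0].mean():.4f}",
            f"Mean score state1:  {sc[y == 1].mean():.4f}",
            "-" * 44,
            "Top positive weights (up in state1):",
            *(f"  {g:<15s} {v_: .4f}" for g, v_ in top_pos.items()),
            "Top negative weights (down in state1):",
            *(f"  {g:<15s} {v_: .4f}" for g, v_ in top_neg.items()),
        ]
        return "\n".join(lines)
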