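"""Deep-belief-network regression to (SBP, DBP).

The estimator is a stack of restricted Boltzmann machines — a
Gaussian–Bernoulli RBM on the (standardized) 11-feature input followed by
Bernoulli–Bernoulli RBMs — pre-trained greedily with contrastive
divergence, then unrolled into a deterministic feed-forward network
(sigmoid hidden layers, linear 2-unit read-out) and fine-tuned by
momentum SGD on the batch mean-squared error to the standardized SBP/DBP
targets.  Predictions from an ensemble of independently seeded members
are averaged.

Numerical conventions: the GBRBM assumes unit-variance Gaussian visibles,
which is what per-column standardization provides; RBM weights and biases
are initialised uniformly on ``init_range``; the linear read-out (not part
of the pre-trained stack) is initialised at zero so the initial
prediction is the target mean; momentum is classical,
``v ← η·v − ϵ·∇``, ``θ ← θ + v``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .cohort import MeasurementRecord
from .errors import (
    ConfigurationError,
    DivergenceError,
    ShapeError,
    ValidationError,
)

__all__ = [
    "RBMLayer",
    "TrainConfig",
    "Standardizer",
    "DBNModel",
    "standardize",
    "cd_gradient",
    "cd_update",
    "pretrain",
    "fine_tune",
    "predict",
    "ensemble_train_predict",
    "ensemble_predict",
    "train_member",
    "mlp_loss_grads",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    """Hyperparameters of the DBN regression estimator."""

    hidden_sizes: tuple[int, ...] = (32, 32, 32)
    lr_weights: float = 0.001
    lr_vbias: float = 0.01
    lr_hbias: float = 0.01
    momentum: float = 0.9
    epochs_pretrain: int = 200
    epochs_finetune: int = 200
    batch_size: int = 10
    cd_steps: int = 1
    init_range: tuple[float, float] = (-1.0, 1.0)
    ensemble_size: int = 50
    seed: int = 0

    def validate(self) -> None:
        for name in ("lr_weights", "lr_vbias", "lr_hbias"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ConfigurationError("momentum must be in [0, 1)")
        for name in ("epochs_pretrain", "epochs_finetune"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.cd_steps < 1:
            raise ConfigurationError("cd_steps must be >= 1")
        if self.ensemble_size < 1:
            raise ConfigurationError("ensemble_size must be >= 1")
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ConfigurationError("hidden_sizes must be positive")
        lo, hi = self.init_range
        if not lo < hi:
            raise ConfigurationError("init_range must satisfy lo < hi")


@dataclass
class RBMLayer:
    """One RBM: W (visible × hidden), hidden bias b, visible bias c."""

    W: np.ndarray
    b_hidden: np.ndarray
    c_visible: np.ndarray
    visible_kind: str = "bernoulli"  # "gaussian" for the input layer

    def __post_init__(self) -> None:
        nv, nh = self.W.shape
        if self.b_hidden.shape != (nh,) or self.c_visible.shape != (nv,):
            raise ShapeError("RBMLayer bias shapes do not match W")
        if self.visible_kind not in ("gaussian", "bernoulli"):
            raise ValidationError(f"unknown visible_kind {self.visible_kind!r}")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def hidden_probs(self, v: np.ndarray) -> np.ndarray:
        """P(h=1 | v), identical form for both visible kinds on
        unit-variance data: sigm(b + vW)."""
        return expit(self.b_hidden + v @ self.W)

    def visible_mean(self, h: np.ndarray) -> np.ndarray:
        """E[v | h]: sigmoid for Bernoulli visibles, linear (unit-variance
        Gaussian) for the input layer."""
        act = self.c_visible + h @ self.W.T
        if self.visible_kind == "gaussian":
            return act
        return expit(act)


class Standardizer:
    """Per-column affine transform to zero mean, unit sd (n−1)."""

    def __init__(self, mean: np.ndarray, sd: np.ndarray, names: Sequence[str]):
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)
        self.names = list(names)

    @classmethod
    def fit(cls, X: np.ndarray, names: Sequence[str]) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        for j, s in enumerate(sd):
            if s == 0:
                raise ValidationError(
                    f"column {names[j]!r} has zero standard deviation"
                )
        return cls(mean, sd, names)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean


@dataclass
class DBNModel:
    """Pre-trained RBM stack plus linear read-out and standardization."""

    layers: list[RBMLayer]
    output_W: np.ndarray
    output_b: np.ndarray
    feature_stats: Standardizer
    target_stats: Standardizer
    config: TrainConfig = field(default_factory=TrainConfig)

    @property
    def n_features(self) -> int:
        return self.layers[0].n_visible

    def hidden_forward(self, Z: np.ndarray) -> list[np.ndarray]:
        """Activations of every hidden layer for standardized input Z."""
        acts = []
        a = Z
        for layer in self.layers:
            a = layer.hidden_probs(a)
            acts.append(a)
        return acts

    def forward_standardized(self, Z: np.ndarray) -> np.ndarray:
        a = self.hidden_forward(Z)[-1]
        return a @ self.output_W + self.output_b


def records_to_arrays(
    records: Sequence[MeasurementRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """(features, targets) arrays from measurement records."""
    X = np.array([r.features for r in records], dtype=float)
    Y = np.array([[r.ref_sbp, r.ref_dbp] for r in records], dtype=float)
    return X, Y


def standardize(
    records: Sequence[MeasurementRecord],
    model_stats: tuple[Standardizer, Standardizer] | None = None,
) -> tuple[np.ndarray, np.ndarray, Standardizer, Standardizer]:
    """Standardize features and targets.

    Train mode (``model_stats=None``) fits per-column mean/sd on the
    records; apply mode reuses the given stats.  Returns the standardized
    arrays together with the (feature, target) standardizers; a zero-sd
    column raises a :class:`ValidationError` naming it.
    """
    if not records:
        raise ValidationError("no records to standardize")
    X, Y = records_to_arrays(records)
    n_feat = X.shape[1]
    feat_names = [f"feature_{j}" for j in range(n_feat)]
    if model_stats is None:
        fstats = Standardizer.fit(X, feat_names)
        tstats = Standardizer.fit(Y, ["ref_sbp", "ref_dbp"])
    else:
        fstats, tstats = model_stats
    return fstats.transform(X), tstats.transform(Y), fstats, tstats


# ---------------------------------------------------------------------------
# Contrastive divergence


def cd_gradient(
    layer: RBMLayer,
    batch: np.ndarray,
    rng: np.random.Generator,
    k: int = 1,
    sample_visible: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CD-k gradient estimate (ascent direction of the log-likelihood).

    Positive phase uses the data batch with hidden probabilities.  The
    negative phase runs k alternating Gibbs steps with sampled hidden
    states; with ``sample_visible=True`` (default) the visibles are also
    sampled (Bernoulli draws, or Gaussian with unit variance for the
    input layer), so the chain converges to the model distribution as k
    grows and the final statistics — sampled visibles paired with their
    hidden probabilities — are asymptotically unbiased.
    ``sample_visible=False`` replaces visibles by their conditional
    means (the common low-noise CD-1 reconstruction used during
    pre-training).  Returns (dW, dc_visible, db_hidden), each averaged
    over the batch.
    """
    batch = np.asarray(batch, dtype=float)
    if batch.ndim != 2 or batch.shape[1] != layer.n_visible:
        raise ShapeError(
            f"batch must be (n, {layer.n_visible}), got {batch.shape}"
        )
    B = batch.shape[0]
    h_pos = layer.hidden_probs(batch)
    v_neg = batch
    h_prob = h_pos
    for _ in range(k):
        h_sample = (rng.random(h_prob.shape) < h_prob).astype(float)
        v_mean = layer.visible_mean(h_sample)
        if not sample_visible:
            v_neg = v_mean
        elif layer.visible_kind == "gaussian":
            v_neg = v_mean + rng.standard_normal(v_mean.shape)
        else:
            v_neg = (rng.random(v_mean.shape) < v_mean).astype(float)
        h_prob = layer.hidden_probs(v_neg)
    dW = (batch.T @ h_pos - v_neg.T @ h_prob) / B
    dc = (batch - v_neg).mean(axis=0)
    db = (h_pos - h_prob).mean(axis=0)
    return dW, dc, db


@dataclass
class _Velocity:
    W: np.ndarray
    c: np.ndarray
    b: np.ndarray

    @classmethod
    def zeros_like(cls, layer: RBMLayer) -> "_Velocity":
        return cls(
            W=np.zeros_like(layer.W),
            c=np.zeros_like(layer.c_visible),
            b=np.zeros_like(layer.b_hidden),
        )


def cd_update(
    layer: RBMLayer,
    batch: np.ndarray,
    lr: tuple[float, float, float],
    momentum: float,
    velocity: _Velocity | None,
    rng: np.random.Generator,
    k: int = 1,
    sample_visible: bool = False,
) -> tuple[RBMLayer, _Velocity]:
    """One CD-k parameter update with momentum.

    ``lr`` is (weights, visible bias, hidden bias).  Velocities follow
    v ← η·v + ϵ·∇ (ascent on the CD objective); parameters move by v.
    Training defaults to the mean-field reconstruction
    (``sample_visible=False``), the standard low-noise CD-1 recipe.
    """
    if velocity is None:
        velocity = _Velocity.zeros_like(layer)
    lr_w, lr_vb, lr_hb = lr
    dW, dc, db = cd_gradient(layer, batch, rng, k=k, sample_visible=sample_visible)
    velocity.W = momentum * velocity.W + lr_w * dW
    velocity.c = momentum * velocity.c + lr_vb * dc
    velocity.b = momentum * velocity.b + lr_hb * db
    layer.W = layer.W + velocity.W
    layer.c_visible = layer.c_visible + velocity.c
    layer.b_hidden = layer.b_hidden + velocity.b
    return layer, velocity


def _init_layer(
    nv: int, nh: int, kind: str, rng: np.random.Generator, init_range
) -> RBMLayer:
    lo, hi = init_range
    return RBMLayer(
        W=rng.uniform(lo, hi, size=(nv, nh)),
        b_hidden=rng.uniform(lo, hi, size=nh),
        c_visible=rng.uniform(lo, hi, size=nv),
        visible_kind=kind,
    )


def _check_finite(layer: RBMLayer) -> None:
    if not (
        np.all(np.isfinite(layer.W))
        and np.all(np.isfinite(layer.b_hidden))
        and np.all(np.isfinite(layer.c_visible))
    ):
        raise DivergenceError(
            "RBM weights diverged during pre-training; try a smaller learning rate"
        )


def pretrain(
    X: np.ndarray,
    config: TrainConfig,
    feature_stats: Standardizer | None = None,
    target_stats: Standardizer | None = None,
) -> DBNModel:
    """Greedy layer-wise CD pre-training on standardized inputs.

    Each layer is trained on the previous layer's hidden activation
    probabilities; the first layer has Gaussian visibles, the rest
    Bernoulli.  With ``epochs_pretrain=0`` the returned model is its
    random initialisation.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError("X must be a 2-d array")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    sizes = [X.shape[1], *config.hidden_sizes]
    layers: list[RBMLayer] = []
    inputs = X
    for li in range(len(config.hidden_sizes)):
        kind = "gaussian" if li == 0 else "bernoulli"
        layer = _init_layer(sizes[li], sizes[li + 1], kind, rng, config.init_range)
        velocity = _Velocity.zeros_like(layer)
        n = inputs.shape[0]
        for _ in range(config.epochs_pretrain):
            perm = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                batch = inputs[perm[start : start + config.batch_size]]
                layer, velocity = cd_update(
                    layer,
                    batch,
                    (config.lr_weights, config.lr_vbias, config.lr_hbias),
                    config.momentum,
                    velocity,
                    rng,
                    k=config.cd_steps,
                )
            _check_finite(layer)
        layers.append(layer)
        inputs = layer.hidden_probs(inputs)
    output_W = np.zeros((sizes[-1], 2))
    output_b = np.zeros(2)
    if feature_stats is None:
        feature_stats = Standardizer(
            np.zeros(X.shape[1]), np.ones(X.shape[1]),
            [f"feature_{j}" for j in range(X.shape[1])],
        )
    if target_stats is None:
        target_stats = Standardizer(np.zeros(2), np.ones(2), ["ref_sbp", "ref_dbp"])
    return DBNModel(
        layers=layers,
        output_W=output_W,
        output_b=output_b,
        feature_stats=feature_stats,
        target_stats=target_stats,
        config=config,
    )


# ---------------------------------------------------------------------------
# Fine-tuning (deterministic feed-forward net)


def mlp_loss_grads(
    model: DBNModel, Z: np.ndarray, T: np.ndarray
) -> tuple[float, list[tuple[np.ndarray, np.ndarray]], np.ndarray, np.ndarray]:
    """Batch MSE loss and its gradients by back-propagation.

    The loss is (1/B)·Σ_n Σ_d (ŷ_nd − t_nd)².  Returns
    (loss, [(dW, db) per hidden layer], dW_out, db_out).
    """
    B = Z.shape[0]
    acts = model.hidden_forward(Z)
    pred = acts[-1] @ model.output_W + model.output_b
    err = pred - T
    loss = float((err**2).sum() / B)
    delta_out = 2.0 * err / B
    dW_out = acts[-1].T @ delta_out
    db_out = delta_out.sum(axis=0)
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(model.layers)  # type: ignore[list-item]
    delta = delta_out @ model.output_W.T
    for li in range(len(model.layers) - 1, -1, -1):
        a = acts[li]
        delta = delta * a * (1.0 - a)  # sigmoid derivative
        prev = Z if li == 0 else acts[li - 1]
        grads[li] = (prev.T @ delta, delta.sum(axis=0))
        if li > 0:
            delta = delta @ model.layers[li].W.T
    return loss, grads, dW_out, db_out


def fine_tune(model: DBNModel, X: np.ndarray, Y: np.ndarray, config: TrainConfig) -> DBNModel:
    """Momentum-SGD fine-tuning of the unrolled network.

    ``X`` and ``Y`` must already be standardized.  Velocities follow
    v ← η·v − ϵ·∇Ω, θ ← θ + v, with a single learning rate
    (``lr_weights``) for all parameters.  A non-finite loss raises
    :class:`DivergenceError`.  With ``lr_weights=0`` parameters are
    unchanged.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ShapeError("Y must have 2 columns (standardized SBP, DBP)")
    if X.shape[0] != Y.shape[0]:
        raise ShapeError("X and Y row counts differ")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    lr = config.lr_weights
    eta = config.momentum
    vel_layers = [
        (np.zeros_like(l.W), np.zeros_like(l.b_hidden)) for l in model.layers
    ]
    vel_out_W = np.zeros_like(model.output_W)
    vel_out_b = np.zeros_like(model.output_b)
    n = X.shape[0]
    for _ in range(config.epochs_finetune):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            loss, grads, dW_out, db_out = mlp_loss_grads(model, X[idx], Y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    "fine-tuning loss diverged; try a smaller learning rate"
                )
            for li, (dW, db) in enumerate(grads):
                vW, vb = vel_layers[li]
                vW[:] = eta * vW - lr * dW
                vb[:] = eta * vb - lr * db
                model.layers[li].W = model.layers[li].W + vW
                model.layers[li].b_hidden = model.layers[li].b_hidden + vb
            vel_out_W = eta * vel_out_W - lr * dW_out
            vel_out_b = eta * vel_out_b - lr * db_out
            model.output_W = model.output_W + vel_out_W
            model.output_b = model.output_b + vel_out_b
    return model


def predict(model: DBNModel, features: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; returns (n, 2) of (SBP, DBP) in mmHg."""
    X = np.asarray(features, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ShapeError(
            f"feature width {X.shape[1]} does not match model ({model.n_features})"
        )
    Z = model.feature_stats.transform(X)
    out = model.forward_standardized(Z)
    Y = model.target_stats.inverse(out)
    return Y[0] if squeeze else Y


# ---------------------------------------------------------------------------
# Ensemble


def train_member(
    train_records: Sequence[MeasurementRecord], config: TrainConfig
) -> DBNModel:
    """Pre-train and fine-tune one DBN on (already augmented) records."""
    Z, T, fstats, tstats = standardize(train_records)
    model = pretrain(Z, config, feature_stats=fstats, target_stats=tstats)
    return fine_tune(model, Z, T, config)


def ensemble_train_predict(
    train_records: Sequence[MeasurementRecord],
    test_records: Sequence[MeasurementRecord],
    config: TrainConfig,
    augment_N: int = 0,
    bagging: bool = False,
) -> tuple[list[DBNModel], "pd.DataFrame"]:
    """Train an ensemble and predict the test measurements.

    Members differ only in their random seed (weight initialisation, CD
    sampling, batch order); with ``bagging=True`` each member additionally
    trains on its own parametric-bootstrap augmentation of the training
    set (``augment_N`` pseudo-measurements per subject; ``augment_N>0``
    with ``bagging=False`` uses one shared augmented set).  The ensemble
    prediction is the mean of the member predictions.
    """
    import pandas as pd

    from .bootstrap import augment_records

    config.validate()
    shared_train = list(train_records)
    if augment_N > 0 and not bagging:
        shared_train = augment_records(train_records, N=augment_N, seed=config.seed)
    X_test = np.array([r.features for r in test_records], dtype=float)
    models: list[DBNModel] = []
    preds = np.zeros((len(test_records), 2))
    for m in range(config.ensemble_size):
        member_cfg = TrainConfig(**{**config.__dict__, "seed": _member_seed(config.seed, m)})
        member_train = shared_train
        if augment_N > 0 and bagging:
            member_train = augment_records(
                train_records, N=augment_N, seed=member_cfg.seed
            )
        model = train_member(member_train, member_cfg)
        models.append(model)
        preds += predict(model, X_test)
    preds /= config.ensemble_size
    frame = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in test_records],
            "meas_idx": [r.meas_idx for r in test_records],
            "sbp_est": preds[:, 0],
            "dbp_est": preds[:, 1],
            "ref_sbp": [r.ref_sbp for r in test_records],
            "ref_dbp": [r.ref_dbp for r in test_records],
        }
    )
    return models, frame


def _member_seed(seed: int, member: int) -> int:
    return int(
        np.random.SeedSequence([int(seed), 2, int(member)]).generate_state(1)[0]
        % (2**31)
    )


# ---------------------------------------------------------------------------
# Serialization (single portable JSON file, versioned)


def save_model(models: DBNModel | Sequence[DBNModel], path: str | Path) -> None:
    """Serialize one model or an ensemble to a versioned JSON file."""
    members = [models] if isinstance(models, DBNModel) else list(models)
    doc = {
        "format_version": _MODEL_FORMAT_VERSION,
        "members": [
            {
                "layers": [
                    {
                        "W": l.W.tolist(),
                        "b_hidden": l.b_hidden.tolist(),
                        "c_visible": l.c_visible.tolist(),
                        "visible_kind": l.visible_kind,
                    }
                    for l in m.layers
                ],
                "output_W": m.output_W.tolist(),
                "output_b": m.output_b.tolist(),
                "feature_stats": {
                    "mean": m.feature_stats.mean.tolist(),
                    "sd": m.feature_stats.sd.tolist(),
                    "names": m.feature_stats.names,
                },
                "target_stats": {
                    "mean": m.target_stats.mean.tolist(),
                    "sd": m.target_stats.sd.tolist(),
                    "names": m.target_stats.names,
                },
            }
            for m in members
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> list[DBNModel]:
    """Load an ensemble saved by :func:`save_model`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model format version {doc.get('format_version')!r}"
        )
    members = []
    for md in doc["members"]:
        layers = [
            RBMLayer(
                W=np.asarray(ld["W"], dtype=float),
                b_hidden=np.asarray(ld["b_hidden"], dtype=float),
                c_visible=np.asarray(ld["c_visible"], dtype=float),
                visible_kind=ld["visible_kind"],
            )
            for ld in md["layers"]
        ]
        members.append(
            DBNModel(
                layers=layers,
                output_W=np.asarray(md["output_W"], dtype=float),
                output_b=np.asarray(md["output_b"], dtype=float),
                feature_stats=Standardizer(
                    np.asarray(md["feature_stats"]["mean"], dtype=float),
                    np.asarray(md["feature_stats"]["sd"], dtype=float),
                    md["feature_stats"]["names"],
                ),
                target_stats=Standardizer(
                    np.asarray(md["target_stats"]["mean"], dtype=float),
                    np.asarray(md["target_stats"]["sd"], dtype=float),
                    md["target_stats"]["names"],
                ),
            )
        )
    return members


def ensemble_predict(models: Sequence[DBNModel], features: np.ndarray) -> np.ndarray:
    """Mean prediction of an ensemble, (n, 2) mmHg."""
    X = np.asarray(features, dtype=float)
    preds = np.zeros((X.shape[0], 2))
    for m in models:
        preds += predict(m, X)
    return preds / len(models)
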