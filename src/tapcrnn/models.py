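"""Murmur classifiers: CNN, CRNN, and TAP-CRNN.

The three architectures share a frequency-scanning convolutional front
end over log-power spectrogram frames and differ in how they summarize
time before the dense head:

* **CNN** — global average of the per-frame conv features;
* **CRNN** — the last output h(N) of a stacked LSTM;
* **TAP-CRNN** — temporal attentive pooling: a global attention over all
  frames conditioned on the conv features and h(N), refined by a local
  attention, whose weighted average of conv features is concatenated
  with W_g h(N). The per-frame product alpha_global(n) * beta_local(n)
  is the event presence likelihood (EPL) used for explanation.

Everything is exposed twice: as scikit-learn style estimators
(:class:`CnnClassifier`, :class:`CrnnClassifier`,
:class:`TapCrnnClassifier`) and as module-level functional operations
(:func:`global_attention` etc.) convenient for verification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn.layers import (
    Adam,
    Conv2DTanh,
    Dense,
    LSTM,
    TapAttention,
    softmax,
    softmax_xent,
)

ARCHITECTURES = ("cnn", "crnn", "tap_crnn")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``conv_spec`` is a list of (n_filters, kernel_time, kernel_freq);
    kernels are oriented time x frequency, so (1, 4) scans 4 adjacent
    frequency bins within one frame. Convolutions use same padding and
    stride 1 with no pooling, so the per-frame conv feature dimension is
    ``n_bins * conv_spec[-1][0]`` after flattening frequency x channel.
    """

    architecture: str = "tap_crnn"
    conv_spec: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(16, 1, 4), (16, 1, 4)]
    )
    rnn_spec: list[int] = field(default_factory=lambda: [256, 256])
    dense_spec: list[int] = field(default_factory=lambda: [256, 256])
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.architecture == "cnn" and self.rnn_spec:
            raise ValueError("cnn architecture takes no recurrent layers")
        if self.architecture in ("crnn", "tap_crnn") and not self.rnn_spec:
            raise ValueError(f"{self.architecture} requires recurrent layers")

    @classmethod
    def cnn_default(cls) -> "ModelConfig":
        """Three conv layers (32 filters; 1x4, 1x4, 4x4) + two 512-wide dense."""
        return cls(
            architecture="cnn",
            conv_spec=[(32, 1, 4), (32, 1, 4), (32, 4, 4)],
            rnn_spec=[],
            dense_spec=[512, 512],
        )

    @classmethod
    def crnn_default(cls) -> "ModelConfig":
        """Two 16-filter 1x4 conv layers, two 256-unit LSTMs, two 256 dense."""
        return cls(architecture="crnn")

    @classmethod
    def tap_crnn_default(cls) -> "ModelConfig":
        """CRNN defaults plus the temporal attentive pooling layer."""
        return cls(architecture="tap_crnn")


@dataclass
class TapParams:
    """The temporal-attentive-pooling weight tensors.

    Shapes are asserted at construction: W_c is cnn_dim x cnn_dim, W_r and
    W_g are rnn_dim x rnn_dim, u and b_global have length cnn_dim +
    rnn_dim, and W_l / b_l / v act on cnn_dim.
    """

    W_c: np.ndarray
    W_r: np.ndarray
    u: np.ndarray
    b_global: np.ndarray
    W_l: np.ndarray
    b_l: np.ndarray
    v: np.ndarray
    W_g: np.ndarray

    def __post_init__(self) -> None:
        cnn_dim = self.W_c.shape[0]
        rnn_dim = self.W_r.shape[0]
        expected = {
            "W_c": (cnn_dim, cnn_dim),
            "W_r": (rnn_dim, rnn_dim),
            "u": (cnn_dim + rnn_dim,),
            "b_global": (cnn_dim + rnn_dim,),
            "W_l": (cnn_dim, cnn_dim),
            "b_l": (cnn_dim,),
            "v": (cnn_dim,),
            "W_g": (rnn_dim, rnn_dim),
        }
        for name, shape in expected.items():
            got = getattr(self, name).shape
            if got != shape:
                raise ValueError(f"TapParams.{name} has shape {got}, expected {shape}")

    @property
    def cnn_dim(self) -> int:
        return self.W_c.shape[0]

    @property
    def rnn_dim(self) -> int:
        return self.W_r.shape[0]


@dataclass
class AttentionTrace:
    """Per-frame attention weights of one forward pass.

    ``alpha_global`` and ``beta_local`` each sum to 1 across frames;
    ``epl`` is their element-wise product (the event presence
    likelihood), so every entry lies in [0, 1].
    """

    alpha_global: np.ndarray
    beta_local: np.ndarray
    epl: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.alpha_global)
        if len(self.beta_local) != n or len(self.epl) != n:
            raise ValueError("attention vectors must share one length")
        for name in ("alpha_global", "beta_local"):
            w = getattr(self, name)
            if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a distribution over frames")


# ---------------------------------------------------------------------------
# Functional operations (straightforward transcriptions, used for oracles)


def global_attention(Y: np.ndarray, hN: np.ndarray, params: TapParams) -> np.ndarray:
    """alpha_global(n) = softmax_n(u^T tanh([W_c y(n); W_r h(N)] + b_global))."""
    _check_dims(Y, hN, params)
    scores = np.empty(Y.shape[0])
    for n in range(Y.shape[0]):
        c = np.concatenate([params.W_c @ Y[n], params.W_r @ hN])
        scores[n] = params.u @ np.tanh(c + params.b_global)
    return softmax(scores)


def local_attention(Y: np.ndarray, alpha_global: np.ndarray, params: TapParams) -> np.ndarray:
    """beta_local(n) = softmax_n(v^T tanh(W_l alpha(n) y(n) + b_l))."""
    if Y.shape[0] != len(alpha_global):
        raise ValueError("alpha_global length must match the frame count")
    scores = np.empty(Y.shape[0])
    for n in range(Y.shape[0]):
        z = alpha_global[n] * Y[n]
        scores[n] = params.v @ np.tanh(params.W_l @ z + params.b_l)
    return softmax(scores)


def attentive_context(
    Y: np.ndarray, alpha_global: np.ndarray, beta_local: np.ndarray
) -> np.ndarray:
    """f_hat = (1/N) sum_n alpha(n) beta(n) y(n)."""
    n = Y.shape[0]
    if len(alpha_global) != n or len(beta_local) != n:
        raise ValueError("attention weights must match the frame count")
    return (alpha_global * beta_local) @ Y / n


def classify(
    f_hat: np.ndarray,
    hN: np.ndarray,
    params: TapParams,
    dense_layers: list[Dense],
) -> np.ndarray:
    """Dense head on s = [f_hat; W_g h(N)]: tanh hidden layers, softmax out."""
    a = np.concatenate([f_hat, params.W_g @ hN])
    for layer in dense_layers:
        a = layer.forward(a)
    return softmax(a)


def _check_dims(Y: np.ndarray, hN: np.ndarray, params: TapParams) -> None:
    if Y.shape[1] != params.cnn_dim:
        raise ValueError(
            f"W_c expects cnn_dim={params.cnn_dim}, got features of dim {Y.shape[1]}"
        )
    if hN.shape[0] != params.rnn_dim:
        raise ValueError(
            f"W_r expects rnn_dim={params.rnn_dim}, got recurrent state of dim {hN.shape[0]}"
        )


# ---------------------------------------------------------------------------
# Networks


class _Net:
    """Common plumbing: prefixed flat parameter/gradient dicts."""

    def __init__(self) -> None:
        self._layers: dict[str, object] = {}

    def _register(self, name: str, layer) -> None:
        self._layers[name] = layer

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{ln}.{pn}": arr
            for ln, layer in self._layers.items()
            for pn, arr in layer.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{ln}.{pn}": arr
            for ln, layer in self._layers.items()
            for pn, arr in layer.grads.items()
        }

    def zero_grads(self) -> None:
        for layer in self._layers.values():
            layer.zero_grads()

    def _conv_stack(self, config: ModelConfig, rng: np.random.Generator) -> None:
        c_in = 1
        self.convs = []
        for i, (filters, kt, kf) in enumerate(config.conv_spec):
            conv = Conv2DTanh(c_in, filters, (kt, kf), rng)
            self._register(f"conv{i}", conv)
            self.convs.append(conv)
            c_in = filters

    def conv_encode(self, frames: np.ndarray) -> np.ndarray:
        """Frames (N, n_bins) -> per-frame conv features Y (N, cnn_dim)."""
        if frames.shape[0] < 1:
            raise ValueError("empty spectrogram")
        a = frames[:, :, None]
        for conv in self.convs:
            a = conv.forward(a)
        self._conv_out_shape = a.shape
        return a.reshape(a.shape[0], -1)

    def _conv_backward(self, dY: np.ndarray) -> None:
        da = dY.reshape(self._conv_out_shape)
        for conv in reversed(self.convs):
            da = conv.backward(da)

    def _dense_stack(
        self, d_in: int, config: ModelConfig, rng: np.random.Generator
    ) -> None:
        self.denses = []
        for i, width in enumerate(config.dense_spec):
            layer = Dense(d_in, width, rng, activation="tanh")
            self._register(f"dense{i}", layer)
            self.denses.append(layer)
            d_in = width
        out = Dense(d_in, config.n_classes, rng, activation="linear")
        self._register("out", out)
        self.denses.append(out)

    def _dense_forward(self, a: np.ndarray) -> np.ndarray:
        for layer in self.denses:
            a = layer.forward(a)
        return a

    def _dense_backward(self, dlogits: np.ndarray) -> np.ndarray:
        da = dlogits
        for layer in reversed(self.denses):
            da = layer.backward(da)
        return da


class CnnNet(_Net):
    """Conv stack, global average pooling over frames, dense head."""

    def __init__(self, n_bins: int, config: ModelConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.config = config
        self._conv_stack(config, rng)
        cnn_dim = n_bins * config.conv_spec[-1][0]
        self._dense_stack(cnn_dim, config, rng)

    def forward(self, frames: np.ndarray) -> tuple[np.ndarray, None]:
        Y = self.conv_encode(frames)
        self._n = Y.shape[0]
        pooled = Y.mean(axis=0)
        logits = self._dense_forward(pooled)
        return softmax(logits), None

    def loss_grad(self, frames: np.ndarray, target: int) -> float:
        Y = self.conv_encode(frames)
        pooled = Y.mean(axis=0)
        logits = self._dense_forward(pooled)
        loss, _, dlogits = softmax_xent(logits, target)
        dpooled = self._dense_backward(dlogits)
        dY = np.repeat(dpooled[None, :] / Y.shape[0], Y.shape[0], axis=0)
        self._conv_backward(dY)
        return loss


class CrnnNet(_Net):
    """Conv stack, stacked LSTM, dense head on the last recurrent output."""

    def __init__(self, n_bins: int, config: ModelConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.config = config
        self._conv_stack(config, rng)
        d = n_bins * config.conv_spec[-1][0]
        self.cnn_dim = d
        self.lstms = []
        for i, width in enumerate(config.rnn_spec):
            lstm = LSTM(d, width, rng)
            self._register(f"lstm{i}", lstm)
            self.lstms.append(lstm)
            d = width
        self.rnn_dim = d
        self._dense_stack(d, config, rng)

    def recurrent_encode(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        H = Y
        for lstm in self.lstms:
            H = lstm.forward(H)
        return H, H[-1]

    def _recurrent_backward(self, dH_top: np.ndarray) -> np.ndarray:
        d = dH_top
        for lstm in reversed(self.lstms):
            d = lstm.backward(d)
        return d

    def forward(self, frames: np.ndarray) -> tuple[np.ndarray, None]:
        Y = self.conv_encode(frames)
        _, hN = self.recurrent_encode(Y)
        logits = self._dense_forward(hN)
        return softmax(logits), None

    def loss_grad(self, frames: np.ndarray, target: int) -> float:
        Y = self.conv_encode(frames)
        H, hN = self.recurrent_encode(Y)
        logits = self._dense_forward(hN)
        loss, _, dlogits = softmax_xent(logits, target)
        dhN = self._dense_backward(dlogits)
        dH = np.zeros_like(H)
        dH[-1] = dhN
        dY = self._recurrent_backward(dH)
        self._conv_backward(dY)
        return loss


class TapCrnnNet(CrnnNet):
    """CRNN encoder plus temporal attentive pooling before the dense head."""

    def __init__(self, n_bins: int, config: ModelConfig, rng: np.random.Generator) -> None:
        _Net.__init__(self)
        self.config = config
        self._conv_stack(config, rng)
        d = n_bins * config.conv_spec[-1][0]
        self.cnn_dim = d
        self.lstms = []
        for i, width in enumerate(config.rnn_spec):
            lstm = LSTM(d, width, rng)
            self._register(f"lstm{i}", lstm)
            self.lstms.append(lstm)
            d = width
        self.rnn_dim = d
        self.tap = TapAttention(self.cnn_dim, self.rnn_dim, rng)
        self._register("tap", self.tap)
        self._dense_stack(self.cnn_dim + self.rnn_dim, config, rng)

    def tap_params(self) -> TapParams:
        p = self.tap.params
        return TapParams(
            W_c=p["W_c"], W_r=p["W_r"], u=p["u"], b_global=p["b_global"],
            W_l=p["W_l"], b_l=p["b_l"], v=p["v"], W_g=p["W_g"],
        )

    def forward(self, frames: np.ndarray) -> tuple[np.ndarray, AttentionTrace]:
        Y = self.conv_encode(frames)
        _, hN = self.recurrent_encode(Y)
        s, alpha, beta = self.tap.forward(Y, hN)
        logits = self._dense_forward(s)
        trace = AttentionTrace(alpha_global=alpha, beta_local=beta, epl=alpha * beta)
        return softmax(logits), trace

    def loss_grad(self, frames: np.ndarray, target: int) -> float:
        Y = self.conv_encode(frames)
        H, hN = self.recurrent_encode(Y)
        s, _, _ = self.tap.forward(Y, hN)
        logits = self._dense_forward(s)
        loss, _, dlogits = softmax_xent(logits, target)
        ds = self._dense_backward(dlogits)
        dY_att, dhN = self.tap.backward(ds)
        dH = np.zeros_like(H)
        dH[-1] = dhN
        dY = dY_att + self._recurrent_backward(dH)
        self._conv_backward(dY)
        return loss


_NET_CLASSES = {"cnn": CnnNet, "crnn": CrnnNet, "tap_crnn": TapCrnnNet}


def build_net(n_bins: int, config: ModelConfig, rng: np.random.Generator):
    return _NET_CLASSES[config.architecture](n_bins, config, rng)


def forward(
    frames: np.ndarray, net: _Net
) -> tuple[np.ndarray, AttentionTrace | None]:
    """Posterior over classes (and, for TAP-CRNN, the attention trace)."""
    return net.forward(np.asarray(frames, dtype=np.float64))


# ---------------------------------------------------------------------------
# Estimators


def _validate_sequences(X) -> list[np.ndarray]:
    seqs = []
    n_bins = None
    for i, x in enumerate(X):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] < 1:
            raise ValueError(f"X[{i}] must be a nonempty 2-D (frames x bins) array")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"X[{i}] contains non-finite values")
        if n_bins is None:
            n_bins = x.shape[1]
        elif x.shape[1] != n_bins:
            raise ValueError(
                f"X[{i}] has {x.shape[1]} bins, expected {n_bins} like the others"
            )
        seqs.append(x)
    if not seqs:
        raise ValueError("X must contain at least one sequence")
    return seqs


class _SequenceClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery over variable-length spectrogram lists.

    ``X`` is a list/sequence of 2-D arrays (frames x frequency bins); each
    clip is processed at natural length and minibatches are formed by
    gradient accumulation, so no padding or masking is ever involved.
    """

    architecture: str = ""

    def __init__(
        self,
        conv_spec=None,
        rnn_spec=None,
        dense_spec=None,
        learning_rate: float = 1e-3,
        batch_size: int = 8,
        n_epochs: int = 50,
        validation_fraction: float = 0.1,
        early_stopping: bool = True,
        patience: int = 8,
        random_state: int | None = None,
    ) -> None:
        self.conv_spec = conv_spec
        self.rnn_spec = rnn_spec
        self.dense_spec = dense_spec
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.validation_fraction = validation_fraction
        self.early_stopping = early_stopping
        self.patience = patience
        self.random_state = random_state

    def _model_config(self) -> ModelConfig:
        default = {
            "cnn": ModelConfig.cnn_default,
            "crnn": ModelConfig.crnn_default,
            "tap_crnn": ModelConfig.tap_crnn_default,
        }[self.architecture]()
        if self.conv_spec is not None:
            default.conv_spec = [tuple(c) for c in self.conv_spec]
        if self.rnn_spec is not None:
            default.rnn_spec = list(self.rnn_spec)
        if self.dense_spec is not None:
            default.dense_spec = list(self.dense_spec)
        return default

    def fit(self, X, y, groups=None):
        """Train with softmax cross-entropy and Adam.

        ``groups`` (optional, one id per clip) makes the early-stopping
        validation carve-out group-exclusive, e.g. by subject.
        """
        seqs = _validate_sequences(X)
        y = np.asarray(y)
        if len(y) != len(seqs):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training set must contain at least two classes")
        rng = np.random.default_rng(self.random_state)
        config = self._model_config()
        config.n_classes = len(self.classes_)
        self.n_features_in_ = seqs[0].shape[1]
        self.config_ = config
        self.net_ = build_net(self.n_features_in_, config, rng)

        train_idx = np.arange(len(seqs))
        val_idx = np.array([], dtype=int)
        if self.early_stopping and self.validation_fraction > 0:
            train_idx, val_idx = self._carve_out(y_idx, groups, rng)
            if len(val_idx) == 0 or len(np.unique(y_idx[train_idx])) < 2:
                train_idx = np.arange(len(seqs))
                val_idx = np.array([], dtype=int)

        opt = Adam(self.net_.parameters(), lr=self.learning_rate)
        self.loss_curve_ = []
        best_val, best_state, stale = np.inf, None, 0
        for _epoch in range(self.n_epochs):
            order = rng.permutation(train_idx)
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                self.net_.zero_grads()
                for i in batch:
                    epoch_loss += self.net_.loss_grad(seqs[i], int(y_idx[i]))
                grads = self.net_.gradients()
                for g in grads.values():
                    g /= len(batch)
                opt.step(grads)
            self.loss_curve_.append(epoch_loss / len(order))
            if len(val_idx):
                val_loss = np.mean(
                    [self._clip_loss(seqs[i], int(y_idx[i])) for i in val_idx]
                )
                if val_loss < best_val - 1e-6:
                    best_val, stale = val_loss, 0
                    best_state = {
                        k: v.copy() for k, v in self.net_.parameters().items()
                    }
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if best_state is not None:
            for k, v in self.net_.parameters().items():
                v[...] = best_state[k]
        return self

    def _carve_out(self, y_idx, groups, rng):
        n = len(y_idx)
        if groups is not None:
            uniq = np.unique(groups)
            k = max(1, int(round(self.validation_fraction * len(uniq))))
            val_groups = set(rng.choice(uniq, size=k, replace=False))
            val = np.array([i for i in range(n) if groups[i] in val_groups])
        else:
            k = max(1, int(round(self.validation_fraction * n)))
            val = rng.choice(n, size=k, replace=False)
        train = np.setdiff1d(np.arange(n), val)
        return train, val

    def _clip_loss(self, frames: np.ndarray, target: int) -> float:
        probs, _ = self.net_.forward(frames)
        return -float(np.log(max(probs[target], 1e-300)))

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        seqs = _validate_sequences(X)
        return np.vstack([self.net_.forward(x)[0] for x in seqs])

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def murmur_score(self, X) -> np.ndarray:
        """Posterior probability of the murmur class (the ROC score)."""
        proba = self.predict_proba(X)
        idx = int(np.flatnonzero(self.classes_ == "murmur")[0])
        return proba[:, idx]

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted")

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> Path:
        """Write all weight tensors (npz) plus a JSON config sidecar."""
        self._check_fitted()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **self.net_.parameters())
        sidecar = {
            "architecture": self.architecture,
            "params": {
                k: v for k, v in self.get_params().items() if not callable(v)
            },
            "classes": [str(c) for c in self.classes_],
            "n_features_in": int(self.n_features_in_),
            "conv_spec": [list(c) for c in self.config_.conv_spec],
            "rnn_spec": list(self.config_.rnn_spec),
            "dense_spec": list(self.config_.dense_spec),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def load(cls, path) -> "_SequenceClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        est = _CLASSIFIERS[meta["architecture"]](
            conv_spec=[tuple(c) for c in meta["conv_spec"]],
            rnn_spec=meta["rnn_spec"],
            dense_spec=meta["dense_spec"],
        )
        est.classes_ = np.array(meta["classes"])
        est.n_features_in_ = meta["n_features_in"]
        config = est._model_config()
        config.n_classes = len(est.classes_)
        est.config_ = config
        est.net_ = build_net(est.n_features_in_, config, np.random.default_rng(0))
        with np.load(path if path.suffix else path.with_suffix(".npz")) as archive:
            for k, v in est.net_.parameters().items():
                v[...] = archive[k]
        return est


class CnnClassifier(_SequenceClassifier):
    """Purely convolutional baseline with average pooling over frames."""

    architecture = "cnn"


class CrnnClassifier(_SequenceClassifier):
    """Convolutional-recurrent baseline classifying from h(N)."""

    architecture = "crnn"


class TapCrnnClassifier(_SequenceClassifier):
    """Convolutional-recurrent classifier with temporal attentive pooling."""

    architecture = "tap_crnn"

    def attention_trace(self, x: np.ndarray) -> AttentionTrace:
        """Attention weights and EPL of one clip's forward pass."""
        self._check_fitted()
        _, trace = self.net_.forward(np.asarray(x, dtype=np.float64))
        return trace


_CLASSIFIERS = {
    "cnn": CnnClassifier,
    "crnn": CrnnClassifier,
    "tap_crnn": TapCrnnClassifier,
}


def make_classifier(architecture: str, **kwargs) -> _SequenceClassifier:
    if architecture not in _CLASSIFIERS:
        raise ValueError(f"architecture must be one of {ARCHITECTURES}")
    return _CLASSIFIERS[architecture](**kwargs)
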