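"""Attention-fused deep feature extractors for NIR spectra.

Three architectures share one implementation skeleton:

* ``cnn_mha`` — three parallel same-padded 1-D convolution branches with
  small / medium / large kernels (multi-scale local absorption morphology),
  channel-concatenated;
* ``lstm_mha`` — an LSTM over the wavelength sequence (long-range spectral
  trends);
* ``cnn_lstm_mha`` — the concatenated convolution feature maps fed as a
  wavelength-ordered sequence into the LSTM.

The resulting sequence is projected into a dual-head, 20-dimensional scaled
dot-product self-attention block (residual connection around the attention
output), flattened, and mapped by a fully connected layer of width
``feature_dimension`` — the *feature layer*, whose activations are the deep
features handed to downstream chemometric models.  On top of the feature
layer sit one linear head per regression task and a 3-class softmax head.

Training strategies: STL trains one head; MTL trains all three against the
simplex-weighted loss  w_alc*MSE + w_wort*MSE + w_cls*CE  on a shared trunk.
Regression targets are min-max scaled to [0, 1] on the calibration set;
scalers are stored and inverted for reporting.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import (Adam, Tensor, concat, conv1d_same, lstm, mse_loss,
                        scaled_dot_attention, softmax_cross_entropy)

ARCHS = ("cnn_mha", "lstm_mha", "cnn_lstm_mha")
TASKS = ("alcohol", "wort", "classify")
CLASS_ORDER = ("craft", "industrial", "non_fermented")

ATTENTION_HEADS = 2
ATTENTION_DIM = 20      # total model width; 10 per head


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of one extractor; the search space of the optimizer."""

    arch: str
    f_small: int = 3
    f_mid: int = 8
    f_large: int = 20
    num_filters: int = 16
    lstm_hidden_units: int = 64
    feature_dimension: int = 64
    initial_learn_rate: float = 3e-3
    learn_rate_drop_factor: float = 0.5
    l2_regularization: float = 1e-6
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"unknown architecture {self.arch!r}")
        if self.has_conv and not (self.f_small < self.f_mid < self.f_large):
            raise ValueError("kernel sizes not increasing")
        if self.feature_dimension < 1:
            raise ValueError("feature_dimension must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.has_lstm and not 0 < self.learn_rate_drop_factor <= 1:
            raise ValueError("learn_rate_drop_factor must be in (0, 1]")

    @property
    def has_conv(self) -> bool:
        return self.arch in ("cnn_mha", "cnn_lstm_mha")

    @property
    def has_lstm(self) -> bool:
        return self.arch in ("lstm_mha", "cnn_lstm_mha")


@dataclass
class TrainConfig:
    """Optimization settings shared by both strategies."""

    epochs: int = 150
    batch_size: int = 32
    lr_drop_period: int = 50
    seed: int = 0


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int
            ) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Network:
    """An (un)trained extractor network with named parameter tensors."""

    def __init__(self, config: NetworkConfig, n_wavelengths: int,
                 heads, init_seed: int = 0):
        heads = tuple(heads)
        if not heads:
            raise ValueError("network needs at least one task head")
        if any(h not in TASKS for h in heads):
            raise ValueError(f"unknown head in {heads}")
        if config.has_conv and config.f_large > n_wavelengths:
            raise ValueError("kernel larger than input")
        self.config = config
        self.n_wavelengths = n_wavelengths
        self.heads = heads
        self.params: dict[str, Tensor] = {}
        self._init(init_seed)

    # each module draws from its own seeded stream so the trunk
    # initialization is identical whichever heads exist
    def _rng(self, seed: int, name: str) -> np.random.Generator:
        return np.random.default_rng([seed & 0x7FFFFFFF,
                                      zlib.crc32(name.encode())])

    def _add(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, name=name)
        self.params[name] = t
        return t

    def _init(self, seed: int) -> None:
        cfg = self.config
        L = self.n_wavelengths
        seq_dim = 1
        if cfg.has_conv:
            for label, k in (("small", cfg.f_small), ("mid", cfg.f_mid),
                             ("large", cfg.f_large)):
                rng = self._rng(seed, f"conv_{label}")
                self._add(f"conv_{label}_W",
                          _glorot(rng, (k, 1, cfg.num_filters), k,
                                  k * cfg.num_filters))
                self._add(f"conv_{label}_b", np.zeros(cfg.num_filters))
            seq_dim = 3 * cfg.num_filters
        if cfg.has_lstm:
            H = cfg.lstm_hidden_units
            rng = self._rng(seed, "lstm")
            self._add("lstm_W", _glorot(rng, (seq_dim, 4 * H), seq_dim,
                                        4 * H))
            self._add("lstm_U", _glorot(rng, (H, 4 * H), H, 4 * H))
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0       # forget-gate bias
            self._add("lstm_b", b)
            seq_dim = H
        rng = self._rng(seed, "attention")
        D = ATTENTION_DIM
        self._add("proj_W", _glorot(rng, (seq_dim, D), seq_dim, D))
        self._add("proj_b", np.zeros(D))
        for name in ("q", "k", "v", "o"):
            self._add(f"att_{name}_W", _glorot(rng, (D, D), D, D))
        self._add("att_o_b", np.zeros(D))
        rng = self._rng(seed, "feature")
        self._add("fc_W", _glorot(rng, (L * D, cfg.feature_dimension),
                                  L * D, cfg.feature_dimension))
        self._add("fc_b", np.zeros(cfg.feature_dimension))
        for task in self.heads:
            width = len(CLASS_ORDER) if task == "classify" else 1
            rng = self._rng(seed, f"head_{task}")
            self._add(f"head_{task}_W",
                      _glorot(rng, (cfg.feature_dimension, width),
                              cfg.feature_dimension, width))
            self._add(f"head_{task}_b", np.zeros(width))

    def head_params(self, task: str):
        return [self.params[f"head_{task}_W"], self.params[f"head_{task}_b"]]

    def trainable(self, tasks):
        names = [n for n in self.params if not n.startswith("head_")]
        names += [n for n in self.params
                  if any(n.startswith(f"head_{t}_") for t in tasks)]
        return [self.params[n] for n in names]

    def forward(self, X: np.ndarray, tasks=None,
                rng: np.random.Generator | None = None
                ) -> tuple[Tensor, dict]:
        """Feature-layer activations and head outputs for a batch.

        ``rng`` enables dropout (training); ``rng=None`` is deterministic
        inference.
        """
        cfg = self.config
        if X.shape[1] != self.n_wavelengths:
            raise ValueError("input not on the training wavelength grid")
        tasks = self.heads if tasks is None else tuple(tasks)
        B = X.shape[0]
        seq = Tensor(X[:, :, None])
        if cfg.has_conv:
            branches = [
                conv1d_same(seq, self.params[f"conv_{lab}_W"],
                            self.params[f"conv_{lab}_b"]).relu()
                for lab in ("small", "mid", "large")]
            seq = concat(branches, axis=-1)
        if cfg.has_lstm:
            seq = lstm(seq, self.params["lstm_W"], self.params["lstm_U"],
                       self.params["lstm_b"])
            seq = seq.dropout(cfg.dropout_rate, rng)
        proj = seq @ self.params["proj_W"] + self.params["proj_b"]
        att = self._attention(proj, B)
        flat = (proj + att).reshape(B, self.n_wavelengths * ATTENTION_DIM)
        feature = (flat @ self.params["fc_W"] + self.params["fc_b"]).relu()
        outputs = {t: feature @ self.params[f"head_{t}_W"]
                   + self.params[f"head_{t}_b"] for t in tasks}
        return feature, outputs

    def _attention(self, proj: Tensor, B: int) -> Tensor:
        L, D, nH = self.n_wavelengths, ATTENTION_DIM, ATTENTION_HEADS
        dh = D // nH

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, nH, dh).transpose(0, 2, 1, 3)

        q = split_heads(proj @ self.params["att_q_W"])
        k = split_heads(proj @ self.params["att_k_W"])
        v = split_heads(proj @ self.params["att_v_W"])
        mixed = scaled_dot_attention(q, k, v)
        merged = mixed.transpose(0, 2, 1, 3).reshape(B, L, D)
        return merged @ self.params["att_o_W"] + self.params["att_o_b"]


def build_network(config: NetworkConfig, n_wavelengths: int, heads,
                  init_seed: int = 0) -> Network:
    """Construct an initialized, untrained extractor network."""
    return Network(config, n_wavelengths, heads, init_seed)


def count_parameters(net: Network) -> int:
    """Total trainable scalar parameters."""
    return int(sum(p.data.size for p in net.params.values()))


@dataclass
class TargetScaler:
    """Min-max scaling of a regression target onto [0, 1]."""

    lo: float
    hi: float

    @classmethod
    def fit(cls, y: np.ndarray) -> "TargetScaler":
        lo, hi = float(np.min(y)), float(np.max(y))
        if hi == lo:
            raise ValueError("constant target cannot be scaled")
        return cls(lo, hi)

    def transform(self, y):
        return (np.asarray(y, float) - self.lo) / (self.hi - self.lo)

    def inverse(self, y):
        return np.asarray(y, float) * (self.hi - self.lo) + self.lo


@dataclass
class TrainedExtractor:
    """A trained network plus the input/target scalers captured at fit time.

    Spectra are standardized per wavelength on calibration statistics before
    entering the network; the informative absorption-band variation is small
    against the broad water background, and the net trains poorly without
    this.
    """

    network: Network
    strategy: str                 # "stl" | "mtl"
    tasks: tuple
    scalers: dict = field(default_factory=dict)
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    loss_history: np.ndarray | None = None

    @property
    def config(self) -> NetworkConfig:
        return self.network.config

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if self.x_mean is None:
            return X
        if X.shape[1] != self.x_mean.size:
            raise ValueError("input not on the training wavelength grid")
        return (X - self.x_mean) / self.x_sd

    def predict(self, X: np.ndarray, task: str):
        """Head predictions in original units (or class labels)."""
        _, outputs = self.network.forward(self._scale_x(X), (task,))
        out = outputs[task].data
        if task == "classify":
            return np.asarray([CLASS_ORDER[i] for i in out.argmax(axis=1)],
                              dtype=object)
        return self.scalers[task].inverse(out[:, 0])

    def predict_scaled(self, X: np.ndarray, task: str) -> np.ndarray:
        _, outputs = self.network.forward(self._scale_x(X), (task,))
        return outputs[task].data[:, 0]


def _one_hot_classes(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    bad = set(labels) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"unknown class labels {sorted(bad)}")
    return np.stack([(labels == c).astype(float) for c in CLASS_ORDER],
                    axis=1)


def _train(net: Network, X: np.ndarray, targets: dict, weights: dict,
           cfg: TrainConfig, strategy: str) -> TrainedExtractor:
    if cfg.epochs < 1:
        raise ValueError("epochs must be >= 1")
    X = np.asarray(X, float)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    X = (X - x_mean) / x_sd
    active = tuple(t for t in TASKS if weights.get(t, 0.0) > 0.0)
    for t in active:
        if t not in targets or targets[t] is None:
            raise ValueError(f"missing target for task {t!r}")
        if t not in net.heads:
            raise ValueError(f"network has no head for task {t!r}")
    scalers: dict[str, TargetScaler] = {}
    prepared: dict[str, np.ndarray] = {}
    for t in active:
        if t == "classify":
            prepared[t] = _one_hot_classes(targets[t])
        else:
            scalers[t] = TargetScaler.fit(targets[t])
            prepared[t] = scalers[t].transform(targets[t])[:, None]

    rng = np.random.default_rng(cfg.seed)
    params = net.trainable(active)
    opt = Adam(params, lr=net.config.initial_learn_rate,
               l2=net.config.l2_regularization)
    # the piecewise schedule applies to lstm-bearing architectures only;
    # the plain convolutional extractor trains at a constant rate
    use_schedule = net.config.has_lstm
    n = len(X)
    losses = []
    for epoch in range(cfg.epochs):
        if use_schedule:
            opt.lr = (net.config.initial_learn_rate
                      * net.config.learn_rate_drop_factor
                      ** (epoch // cfg.lr_drop_period))
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            drop_rng = rng if net.config.has_lstm else None
            _, outputs = net.forward(X[idx], active, rng=drop_rng)
            loss = None
            for t in active:
                if t == "classify":
                    lt = softmax_cross_entropy(outputs[t], prepared[t][idx])
                else:
                    lt = mse_loss(outputs[t], prepared[t][idx])
                lt = weights[t] * lt
                loss = lt if loss is None else loss + lt
            if not np.isfinite(loss.data):
                raise RuntimeError("training diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
    return TrainedExtractor(net, strategy, active, scalers, x_mean, x_sd,
                            np.asarray(losses))


def train_stl(net: Network, X_cal: np.ndarray, y, task: str,
              train_cfg: TrainConfig | None = None) -> TrainedExtractor:
    """Single-task training: one head, MSE (scaled target) or cross-entropy."""
    cfg = train_cfg or TrainConfig()
    return _train(net, X_cal, {task: y}, {task: 1.0}, cfg, "stl")


def train_mtl(net: Network, X_cal: np.ndarray, y_alc, y_wort, y_cls,
              task_weights, train_cfg: TrainConfig | None = None
              ) -> TrainedExtractor:
    """Multi-task training of the shared trunk under simplex task weights.

    ``task_weights`` is (w_alc, w_wort, w_cls); tasks with weight exactly 0
    drop out of the loss, so a simplex vertex reproduces the corresponding
    single-task run exactly (same seed, same network).
    """
    w = np.asarray(task_weights, float)
    if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    cfg = train_cfg or TrainConfig()
    targets = {"alcohol": y_alc, "wort": y_wort, "classify": y_cls}
    weights = dict(zip(TASKS, w))
    return _train(net, X_cal, targets, weights, cfg, "mtl")


@dataclass
class FeatureMatrix:
    """Deep features handed from an extractor to chemometric models."""

    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")


def extract_features(ex: TrainedExtractor, X: np.ndarray,
                     batch_size: int = 32) -> FeatureMatrix:
    """Feature-layer activations (dropout disabled, deterministic)."""
    X = ex._scale_x(X)
    chunks = []
    for start in range(0, len(X), batch_size):
        feature, _ = ex.network.forward(X[start:start + batch_size],
                                        tasks=())
        chunks.append(feature.data)
    values = np.vstack(chunks)
    return FeatureMatrix(values, f"{ex.config.arch}/{ex.strategy}")
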