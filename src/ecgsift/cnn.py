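"""A compact convolutional image classifier, implemented in numpy.

Architecture (the default spec): three blocks of (3x3 valid convolution with
32 filters + ReLU + 2x2 max pooling, stride 2), then flatten, dropout 0.5, a
64-unit ReLU dense layer and a softmax output over the 3 classes.  With
200 x 200 x 3 inputs the spatial trace is 200 -> 198 -> 99 -> 97 -> 48 ->
46 -> 23, giving a flatten width of 23 * 23 * 32 = 16,928.

Training uses Adam on categorical cross-entropy with per-epoch shuffling.
The whole stack is plain numpy (float32, im2col/BLAS convolutions), so a
fixed seed reproduces parameters and history bit-for-bit — there are no
nondeterministic kernels to switch off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DTYPE = np.float32


@dataclass
class CnnSpec:
    """Layer stack and training hyperparameters."""

    input_shape: tuple[int, int, int] = (200, 200, 3)
    n_blocks: int = 3
    filters: int = 32
    kernel: int = 3
    pool: int = 2
    dropout: float = 0.5
    dense_units: int = 64
    n_classes: int = 3
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_blocks < 1 or self.filters < 1 or self.n_classes < 2:
            raise ValueError("invalid architecture spec")

    def spatial_trace(self) -> list[tuple[int, int]]:
        """(H, W) after each conv/pool, starting from the input."""
        h, w, _ = self.input_shape
        trace = [(h, w)]
        for _ in range(self.n_blocks):
            h, w = h - self.kernel + 1, w - self.kernel + 1  # valid conv
            trace.append((h, w))
            h, w = h // self.pool, w // self.pool  # floor pooling
            trace.append((h, w))
            if h < 1 or w < 1:
                raise ValueError("input too small for the conv/pool chain")
        return trace

    def flatten_width(self) -> int:
        h, w = self.spatial_trace()[-1]
        return h * w * self.filters


def _conv(x: np.ndarray, w: np.ndarray, bias=None, return_cols: bool = False):
    """Valid cross-correlation of (N,H,W,C) with (kh,kw,C,F) via im2col."""
    kh, kw, cin, f = w.shape
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    n, oh, ow = windows.shape[:3]
    cols = np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * oh * ow, kh * kw * cin
    )
    out = cols @ w.reshape(kh * kw * cin, f)
    if bias is not None:
        out += bias
    out = out.reshape(n, oh, ow, f)
    return (out, cols) if return_cols else out


class Conv2D:
    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = kernel * kernel * c_in
        self.w = (rng.standard_normal((kernel, kernel, c_in, c_out)) *
                  np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self._cols = None
        self._xshape = None

    @property
    def params(self):
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out, cols = _conv(x, self.w, self.b, return_cols=True)
        if train:
            self._cols, self._xshape = cols, x.shape
        return out

    def backward(self, dout: np.ndarray):
        n, oh, ow, f = dout.shape
        dflat = dout.reshape(n * oh * ow, f)
        dw = (self._cols.T @ dflat).reshape(self.w.shape)
        db = dflat.sum(axis=0)
        kh, kw = self.w.shape[:2]
        padded = np.pad(dout, ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1), (0, 0)))
        w_rot = self.w[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh,kw,F,C)
        dx = _conv(padded, np.ascontiguousarray(w_rot))
        self._cols = None
        return dx, [dw, db]


class ReLU:
    params: list = []

    def n_params(self) -> int:
        return 0

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask, []


class MaxPool2:
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    params: list = []

    def n_params(self) -> int:
        return 0

    def forward(self, x, train):
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        xc = x[:, : oh * 2, : ow * 2]
        win = xc.reshape(n, oh, 2, ow, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, oh, ow, c, 4
        )
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._xshape = idx, x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._xshape
        oh, ow = h // 2, w // 2
        scat = (np.eye(4, dtype=dout.dtype)[self._idx]) * dout[..., None]
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        dx[:, : oh * 2, : ow * 2] = (
            scat.reshape(n, oh, ow, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, oh * 2, ow * 2, c)
        )
        return dx, []


class Flatten:
    params: list = []

    def n_params(self) -> int:
        return 0

    def forward(self, x, train):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape), []


class Dropout:
    """Inverted dropout; identity at inference."""

    params: list = []

    def __init__(self, rate: float):
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def n_params(self) -> int:
        return 0

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask, []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)

    @property
    def params(self):
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        dw = self._x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx, [dw, db]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CnnNetwork:
    """The layer chain; see :func:`build_model`."""

    def __init__(self, spec: CnnSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        c_in = spec.input_shape[2]
        self.layers: list = []
        for _ in range(spec.n_blocks):
            self.layers.append(Conv2D(spec.kernel, c_in, spec.filters, rng))
            self.layers.append(ReLU())
            self.layers.append(MaxPool2())
            c_in = spec.filters
        self.layers.append(Flatten())
        self.layers.append(Dropout(spec.dropout))
        self.layers.append(Dense(spec.flatten_width(), spec.dense_units, rng))
        self.layers.append(ReLU())
        self.layers.append(Dense(spec.dense_units, spec.n_classes, rng))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of (N, H, W, C) float inputs."""
        out = np.asarray(x, dtype=DTYPE)
        expected = self.spec.input_shape
        if out.shape[1:] != expected:
            raise ValueError(f"input shape {out.shape[1:]} != spec {expected}")
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        chunks = [
            softmax(self.forward(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks) if chunks else np.zeros((0, self.spec.n_classes))

    def summary(self) -> list[dict]:
        """Structural echo of the layer stack (for architecture checks)."""
        rows = []
        for layer in self.layers:
            row = {"type": type(layer).__name__, "n_params": layer.n_params()}
            if isinstance(layer, Conv2D):
                kh, kw, _, f = layer.w.shape
                row.update(filters=f, kernel=(kh, kw), padding="valid")
            elif isinstance(layer, MaxPool2):
                row.update(pool=(2, 2), stride=2)
            elif isinstance(layer, Dropout):
                row.update(rate=layer.rate)
            elif isinstance(layer, Dense):
                row.update(units=layer.w.shape[1])
            rows.append(row)
        return rows


@dataclass
class TrainedModel:
    """A fitted network with its training history and config snapshot."""

    network: CnnNetwork
    history: dict = field(default_factory=lambda: {"loss": [], "accuracy": []})
    spec: CnnSpec | None = None
    seed: int | None = None


def build_model(spec: CnnSpec, seed: int = 0) -> CnnNetwork:
    """Instantiate the (untrained) network with seeded He initialisation."""
    spec.spatial_trace()  # raises if the input can't feed the chain
    return CnnNetwork(spec, seed)


class _Adam:
    def __init__(self, spec: CnnSpec, params: list[np.ndarray]):
        self.lr, self.b1, self.b2, self.eps = (
            spec.learning_rate, spec.beta1, spec.beta2, spec.adam_eps,
        )
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def train(
    model: CnnNetwork,
    images: np.ndarray,
    onehot: np.ndarray,
    spec: CnnSpec | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit with Adam on categorical cross-entropy.

    ``images`` is (N, H, W, C) float in [0, 1]; ``onehot`` is (N, K).  Runs
    ``epochs * ceil(N / batch_size)`` updates with per-epoch shuffling driven
    by ``seed``; records mean loss and training accuracy per epoch.  Raises
    on empty data or a non-finite loss.
    """
    spec = spec or model.spec
    x = np.asarray(images, dtype=DTYPE)
    y = np.asarray(onehot, dtype=DTYPE)
    if x.shape[0] == 0:
        raise ValueError("empty training data")
    if y.ndim != 2 or y.shape[0] != x.shape[0] or y.shape[1] != spec.n_classes:
        raise ValueError("labels must be one-hot over the spec's classes")

    rng = np.random.default_rng(seed)
    for layer in model.layers:
        if isinstance(layer, Dropout):
            layer.rng = np.random.default_rng(rng.integers(0, 2**31))

    params = [p for layer in model.layers for p in layer.params]
    adam = _Adam(spec, params)
    history = {"loss": [], "accuracy": []}
    n = x.shape[0]

    for _ in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True)
            probs = softmax(logits)
            loss = float(-np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1)))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss ({loss}); aborting")
            epoch_loss += loss * len(idx)
            epoch_correct += int(np.sum(probs.argmax(1) == yb.argmax(1)))

            dout = (probs - yb) / len(idx)
            grads: list[np.ndarray] = []
            for layer in reversed(model.layers):
                dout, layer_grads = layer.backward(dout)
                grads = layer_grads + grads
            adam.step(params, grads)
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(epoch_correct / n)

    return TrainedModel(model, history, spec, seed)


def predict(model: TrainedModel | CnnNetwork, images: np.ndarray):
    """Probability matrix (rows sum to 1) and argmax class indices.

    Ties in the probability row resolve to the lowest class index.
    """
    network = model.network if isinstance(model, TrainedModel) else model
    probs = network.predict_proba(images)
    return probs, probs.argmax(axis=1)
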