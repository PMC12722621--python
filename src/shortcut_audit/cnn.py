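"""Compact 3D CNN classifier, implemented directly on NumPy.

Architecture: four building blocks, each a 3x3x3 convolution (8 channels)
followed by a 3x3x3 down-convolution with stride 2, all ReLU-activated; then
two dense layers (16 and 2 units) with softmax output. There is no pooling,
no normalization and no dropout; every spatial halving is a strided
convolution. All biases are constrained to be non-positive by projection
after each optimizer step, which sparsifies activations and keeps the
relevance propagation in :mod:`.lrp` well-behaved.

Layers are written with explicit forward caches and hand-rolled backward
passes so the alpha-beta relevance rule can reuse the same im2col machinery;
convolution is im2col + BLAS matmul, the gradient scatter loops over the 27
kernel taps with strided slice adds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "NetworkSpec",
    "TrainingSpec",
    "RunResult",
    "MetricSummary",
    "PerformanceRecord",
    "Network",
    "build_network",
    "count_parameters",
    "train_session",
    "is_converged",
    "evaluate",
    "rank_auc",
]

KERNEL = 3


@dataclass(frozen=True)
class NetworkSpec:
    input_shape: tuple[int, int, int] = (32, 32, 32)
    n_blocks: int = 4
    channels: int = 8
    fc_units: tuple[int, int] = (16, 2)

    def __post_init__(self) -> None:
        div = 2 ** self.n_blocks
        for n in self.input_shape:
            if n % div != 0:
                raise ValueError(
                    f"input shape {self.input_shape} not divisible by "
                    f"{div} (= stride 2 ** {self.n_blocks} blocks)"
                )
        if self.fc_units[-1] != 2:
            raise ValueError("output layer must have exactly 2 units")

    @property
    def flat_features(self) -> int:
        return self.channels * int(
            np.prod([n // 2 ** self.n_blocks for n in self.input_shape])
        )


@dataclass(frozen=True)
class TrainingSpec:
    epochs: int = 30
    batch_size: int = 20
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class RunResult:
    """Outcome of one training session on one configuration."""

    config_id: str
    sampling_index: int
    init_index: int
    sampling_seed: int
    init_seed: int
    converged: bool
    validation_accuracy: float
    final_loss: float
    image_ids: list[str]
    true_labels: np.ndarray  # 1 = patient, 0 = control
    predicted_labels: np.ndarray
    scores: np.ndarray  # positive-class (patient) probability


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PerformanceRecord:
    accuracy: MetricSummary
    sensitivity: MetricSummary
    specificity: MetricSummary
    auc: MetricSummary
    n_sessions: int


# ---------------------------------------------------------------------------
# layers


def _pad_widths(stride: int) -> tuple[int, int]:
    # stride 1: symmetric 'same'; stride 2: pad right only so even sizes halve
    return (1, 1) if stride == 1 else (0, 1)


_DTYPE = np.float32  # network compute dtype; LRP tolerances account for it


class Conv3D:
    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        fan_in = in_ch * KERNEL**3
        self.weight = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in)
        ).astype(_DTYPE)
        self.bias = np.zeros(out_ch, dtype=_DTYPE)
        self.stride = stride
        self.in_ch = in_ch
        self.out_ch = out_ch
        self._cache: Optional[tuple] = None

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple]:
        p = _pad_widths(self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), p, p, p))
        win = sliding_window_view(xp, (KERNEL, KERNEL, KERNEL), axis=(2, 3, 4))
        s = self.stride
        win = win[:, :, ::s, ::s, ::s]
        b, c, do, ho, wo = win.shape[:5]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(b, do * ho * wo, c * KERNEL**3)
        return cols, xp, (do, ho, wo)

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        cols, xp, (do, ho, wo) = self._im2col(x)
        out = cols @ self.weight.T + self.bias
        out = out.transpose(0, 2, 1).reshape(x.shape[0], self.out_ch, do, ho, wo)
        if cache:
            self._cache = (x.shape, xp.shape, cols, (do, ho, wo))
        return out

    def _scatter(self, dcols: np.ndarray, x_shape: tuple, xp_shape: tuple,
                 out_sp: tuple) -> np.ndarray:
        """Fold (B, P, C*27) columns back onto the unpadded input grid."""
        b = x_shape[0]
        do, ho, wo = out_sp
        d = dcols.reshape(b, do, ho, wo, self.in_ch, KERNEL, KERNEL, KERNEL)
        dpad = np.zeros((b, self.in_ch) + xp_shape[2:], dtype=dcols.dtype)
        s = self.stride
        for i in range(KERNEL):
            for j in range(KERNEL):
                for k in range(KERNEL):
                    dpad[:, :,
                         i:i + s * do:s,
                         j:j + s * ho:s,
                         k:k + s * wo:s] += d[:, :, :, :, :, i, j, k].transpose(0, 4, 1, 2, 3)
        p0, _ = _pad_widths(s)
        sl = slice(p0, p0 + x_shape[2]), slice(p0, p0 + x_shape[3]), slice(p0, p0 + x_shape[4])
        return dpad[:, :, sl[0], sl[1], sl[2]]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, cols, out_sp = self._cache
        b = dout.shape[0]
        dflat = dout.reshape(b, self.out_ch, -1).transpose(0, 2, 1)  # (B, P, out)
        f = cols.shape[-1]
        self.dweight = dflat.reshape(-1, self.out_ch).T @ cols.reshape(-1, f)
        self.dbias = dflat.sum(axis=(0, 1))
        dcols = dflat @ self.weight
        return self._scatter(dcols, x_shape, xp_shape, out_sp)

    def lrp(self, r_out: np.ndarray, alpha: float, beta: float, eps: float) -> np.ndarray:
        """Alpha-beta relevance through the convolution (inputs assumed
        non-negative, which holds after ReLU and for image intensities);
        bias relevance is absorbed."""
        x_shape, xp_shape, cols, out_sp = self._cache
        b = r_out.shape[0]
        rflat = r_out.reshape(b, self.out_ch, -1).transpose(0, 2, 1)
        r_in = np.zeros((b, self.in_ch) + x_shape[2:])
        for sign, coef, wpart in (
            (1.0, alpha, np.maximum(self.weight, 0.0)),
            (-1.0, beta, np.minimum(self.weight, 0.0)),
        ):
            if coef == 0.0:
                continue
            z = cols @ wpart.T  # (B, P, out); sign of z matches wpart
            s = np.where(np.abs(z) > 0, rflat / (z + sign * eps), 0.0)
            dcols = (s @ wpart) * cols
            r_in += sign * coef * self._scatter(dcols, x_shape, xp_shape, out_sp)
        return r_in


class ReLU:
    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if cache:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def lrp(self, r_out: np.ndarray, alpha: float, beta: float, eps: float) -> np.ndarray:
        return r_out


class Flatten:
    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        if cache:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def lrp(self, r_out: np.ndarray, alpha: float, beta: float, eps: float) -> np.ndarray:
        return r_out.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)).astype(_DTYPE)
        self.bias = np.zeros(n_out, dtype=_DTYPE)
        self._cache: Optional[np.ndarray] = None

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        if cache:
            self._cache = x
        return x @ self.weight.T + self.bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dweight = dout.T @ self._cache
        self.dbias = dout.sum(axis=0)
        return dout @ self.weight

    def lrp(self, r_out: np.ndarray, alpha: float, beta: float, eps: float) -> np.ndarray:
        x = self._cache
        r_in = np.zeros_like(x)
        for sign, coef, wpart in (
            (1.0, alpha, np.maximum(self.weight, 0.0)),
            (-1.0, beta, np.minimum(self.weight, 0.0)),
        ):
            if coef == 0.0:
                continue
            z = x @ wpart.T
            s = np.where(np.abs(z) > 0, r_out / (z + sign * eps), 0.0)
            r_in += sign * coef * (s @ wpart) * x
        return r_in


class Network:
    """The stacked conv / down-conv classifier with a softmax head."""

    def __init__(self, spec: NetworkSpec, layers: list):
        self.spec = spec
        self.layers = layers

    def parameters(self):
        for layer in self.layers:
            if hasattr(layer, "weight"):
                yield layer

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """Logits for a batch shaped (B, D, H, W) or (B, 1, D, H, W)."""
        if x.ndim == 4:
            x = x[:, None]
        out = x.astype(_DTYPE)
        for layer in self.layers:
            out = layer.forward(out, cache=cache)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size])
            probs.append(_softmax(logits))
        return np.concatenate(probs, axis=0)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def max_bias(self) -> float:
        return max(float(layer.bias.max()) for layer in self.parameters())


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_network(spec: NetworkSpec, rng: Optional[np.random.Generator] = None) -> Network:
    rng = rng or np.random.default_rng(0)
    layers: list = []
    in_ch = 1
    for _ in range(spec.n_blocks):
        layers += [Conv3D(in_ch, spec.channels, 1, rng), ReLU(),
                   Conv3D(spec.channels, spec.channels, 2, rng), ReLU()]
        in_ch = spec.channels
    layers.append(Flatten())
    n_in = spec.flat_features
    for i, units in enumerate(spec.fc_units):
        layers.append(Dense(n_in, units, rng))
        if i < len(spec.fc_units) - 1:
            layers.append(ReLU())
        n_in = units
    return Network(spec, layers)


def count_parameters(spec: NetworkSpec) -> int:
    """Closed-form trainable-parameter count for the architecture."""
    k3 = KERNEL**3
    total = k3 * 1 * spec.channels + spec.channels  # first conv
    total += (2 * spec.n_blocks - 1) * (k3 * spec.channels**2 + spec.channels)
    n_in = spec.flat_features
    for units in spec.fc_units:
        total += n_in * units + units
        n_in = units
    return total


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, layers, spec: TrainingSpec):
        self.spec = spec
        self.state = {}
        self.t = 0
        for layer in layers:
            self.state[id(layer)] = {
                "mW": np.zeros_like(layer.weight), "vW": np.zeros_like(layer.weight),
                "mb": np.zeros_like(layer.bias), "vb": np.zeros_like(layer.bias),
            }

    def step(self, layers) -> None:
        s = self.spec
        self.t += 1
        bc1 = 1 - s.beta1**self.t
        bc2 = 1 - s.beta2**self.t
        for layer in layers:
            st = self.state[id(layer)]
            for p, g, m, v in (("weight", layer.dweight, "mW", "vW"),
                               ("bias", layer.dbias, "mb", "vb")):
                st[m] = s.beta1 * st[m] + (1 - s.beta1) * g
                st[v] = s.beta2 * st[v] + (1 - s.beta2) * g * g
                update = s.learning_rate * (st[m] / bc1) / (np.sqrt(st[v] / bc2) + s.adam_eps)
                setattr(layer, p, getattr(layer, p) - update)
            # non-positive bias constraint, projected after every step
            layer.bias = np.minimum(layer.bias, 0.0)


def _cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = _softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), y] + eps)))
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    return loss, d / n


def train_session(
    network: Network,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    spec: TrainingSpec,
    test_x: Optional[np.ndarray] = None,
    test_y: Optional[np.ndarray] = None,
    test_ids: Optional[Sequence[str]] = None,
    config_id: str = "A2",
    sampling_index: int = 0,
    init_index: int = 0,
    sampling_seed: int = 0,
    convergence_threshold: float = 0.60,
) -> RunResult:
    """Train the network with Adam / cross-entropy, projecting biases to
    non-positive values after every step. A NaN/inf loss marks the session
    non-converged instead of raising. Test predictions (if a test set is
    given) are recorded in the returned :class:`RunResult`."""
    params = list(network.parameters())
    adam = _Adam(params, spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.init_seed, spawn_key=(0x7A17,)))
    loss = np.nan
    diverged = False
    for _ in range(spec.epochs):
        order = rng.permutation(len(train_x))
        for start in range(0, len(order), spec.batch_size):
            idx = order[start:start + spec.batch_size]
            logits = network.forward(train_x[idx], cache=True)
            loss, dlogits = _cross_entropy(logits, train_y[idx])
            if not np.isfinite(loss):
                diverged = True
                break
            network.backward(dlogits)
            adam.step(params)
        if diverged:
            break

    val_proba = network.predict_proba(val_x)
    val_acc = float(np.mean(val_proba.argmax(axis=1) == val_y))
    if test_x is not None:
        proba = network.predict_proba(test_x)
        pred = proba.argmax(axis=1)
        scores = proba[:, 1]
        ids = list(test_ids) if test_ids is not None else [str(i) for i in range(len(test_x))]
        true = np.asarray(test_y)
    else:
        pred = np.array([], dtype=int)
        scores = np.array([])
        ids = []
        true = np.array([], dtype=int)

    result = RunResult(
        config_id=config_id,
        sampling_index=sampling_index,
        init_index=init_index,
        sampling_seed=sampling_seed,
        init_seed=spec.init_seed,
        converged=False,
        validation_accuracy=val_acc,
        final_loss=float(loss) if np.isfinite(loss) else float("nan"),
        image_ids=ids,
        true_labels=true,
        predicted_labels=pred,
        scores=scores,
    )
    result.converged = is_converged(result, convergence_threshold)
    return result


def is_converged(result: RunResult, threshold: float = 0.60) -> bool:
    """A session is kept iff its final validation accuracy reaches the
    threshold and its loss stayed finite."""
    return bool(np.isfinite(result.final_loss) and result.validation_accuracy >= threshold)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (patient, control) pairs where the
    patient scores higher, ties counted half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def _summarize(values: np.ndarray) -> MetricSummary:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return MetricSummary(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd)


def evaluate(results: Sequence[RunResult]) -> PerformanceRecord:
    """Per-session accuracy / sensitivity / specificity / AUC over converged
    sessions, aggregated as mean, SD and normal-approximation 95% interval."""
    kept = [r for r in results if r.converged]
    if not kept:
        raise ValueError("no converged sessions to evaluate")
    acc, sens, spec_, auc = [], [], [], []
    for r in kept:
        correct = r.predicted_labels == r.true_labels
        acc.append(np.mean(correct))
        pos = r.true_labels == 1
        neg = ~pos
        sens.append(np.mean(correct[pos]) if pos.any() else np.nan)
        spec_.append(np.mean(correct[neg]) if neg.any() else np.nan)
        auc.append(rank_auc(r.scores, r.true_labels))
    return PerformanceRecord(
        accuracy=_summarize(np.asarray(acc)),
        sensitivity=_summarize(np.asarray(sens)),
        specificity=_summarize(np.asarray(spec_)),
        auc=_summarize(np.asarray(auc)),
        n_sessions=len(kept),
    )
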