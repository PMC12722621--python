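"""Layer-wise relevance propagation (alpha-beta rule) and heatmap windowing.

Relevance starts at the pre-softmax logit of the explained class and is
redistributed backward through the network: each neuron's incoming relevance
is split over its inputs in proportion to alpha times the positive
contribution share minus beta times the negative share (alpha - beta = 1).
With the default alpha=1, beta=0 only positive contributions propagate and
voxel relevance is non-negative. Bias relevance is absorbed, so with the
classifier's non-positive biases the input relevance sum is bounded by the
starting logit.

The windowing procedure reproduces the top-fraction display threshold: a
histogram of relevance values is accumulated from the hottest bin downward
until the chosen fraction of total relevance is covered; the lower edge of
the last included bin is the display/binarization threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cnn import Network
from .phantom import HeadVolume

__all__ = [
    "LRPParams",
    "RelevanceMap",
    "WindowingSpec",
    "lrp_alpha_beta",
    "mean_heatmap",
    "window_threshold",
    "binarize_top_fraction",
]


@dataclass(frozen=True)
class LRPParams:
    alpha: float = 1.0
    beta: float = 0.0
    epsilon: float = 1e-9
    target_class: Optional[int] = None  # None -> the predicted class

    def __post_init__(self) -> None:
        if abs(self.alpha - self.beta - 1.0) > 1e-12:
            raise ValueError("alpha - beta must equal 1")


@dataclass
class RelevanceMap:
    R: np.ndarray
    image_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.float64)
        if self.R.ndim != 3:
            raise ValueError("relevance field must be 3D")
        if not np.all(np.isfinite(self.R)):
            raise ValueError("relevance must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.R.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class WindowingSpec:
    relevance_fraction: float = 0.40
    n_bins: int = 196

    def __post_init__(self) -> None:
        if not (0.0 < self.relevance_fraction <= 1.0):
            raise ValueError("relevance_fraction must lie in (0, 1]")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def lrp_alpha_beta(
    network: Network,
    volume: HeadVolume | np.ndarray,
    params: LRPParams = LRPParams(),
    image_id: str = "",
    session_id: str = "",
) -> RelevanceMap:
    """Voxel relevance for one input volume under the alpha-beta rule."""
    x = volume.intensities if isinstance(volume, HeadVolume) else np.asarray(volume)
    if x.shape != network.spec.input_shape:
        raise ValueError(
            f"input shape {x.shape} does not match network input "
            f"{network.spec.input_shape}"
        )
    logits = network.forward(x[None], cache=True)[0]
    target = int(np.argmax(logits)) if params.target_class is None else params.target_class
    r = np.zeros((1, logits.shape[0]))
    r[0, target] = logits[target]
    for layer in reversed(network.layers):
        r = layer.lrp(r, params.alpha, params.beta, params.epsilon)
    return RelevanceMap(r[0, 0], image_id=image_id, session_id=session_id)


def mean_heatmap(maps: Sequence[RelevanceMap]) -> RelevanceMap:
    """Voxel-wise arithmetic mean of relevance maps on a common grid."""
    if not maps:
        raise ValueError("need at least one relevance map")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("relevance maps are on different grids")
    mean = np.mean([m.R for m in maps], axis=0)
    return RelevanceMap(mean, image_id="mean", session_id=maps[0].session_id)


def window_threshold(map_: RelevanceMap, spec: WindowingSpec = WindowingSpec()) -> float:
    """Lower display threshold covering ``relevance_fraction`` of total
    relevance, accumulated from the hottest histogram bin downward."""
    values = map_.R.ravel()
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise ValueError("constant relevance map has no window threshold")
    total = float(values.sum())
    if total <= 0:
        raise ValueError("total relevance must be positive")
    sums, edges = np.histogram(values, bins=spec.n_bins, range=(lo, hi), weights=values)
    acc = 0.0
    for b in range(spec.n_bins - 1, -1, -1):
        acc += sums[b]
        if acc >= spec.relevance_fraction * total:
            return float(edges[b])
    return float(edges[0])


def binarize_top_fraction(
    map_: RelevanceMap, spec: WindowingSpec = WindowingSpec()
) -> np.ndarray:
    """Boolean field marking voxels at or above the windowing threshold."""
    thr = window_threshold(map_, spec)
    return map_.R >= thr
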