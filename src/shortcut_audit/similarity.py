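"""Heatmap similarity metrics between a reference model and alternatives.

Maps are min-max normalized and compared with: RMSE (reported x100 on the
normalized scale), Pearson correlation, mean structural similarity (MSSIM,
uniform 7x7x7 windows, dynamic range 1), Earth Mover's Distance (mean over
the three axes of the 1-D Wasserstein-1 distance between axis-marginal mass
distributions, in voxel units), and intersection-over-union of the top-40%
and top-10% relevance masks. An exact full 3-D transport is deliberately
not attempted; the axis-marginal EMD is exact in 1-D, fast, and shares the
translation-sensitivity that makes the metric informative here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from skimage.metrics import structural_similarity

from .lrp import RelevanceMap, WindowingSpec, binarize_top_fraction

__all__ = [
    "SimilarityRow",
    "MetricAggregate",
    "minmax_normalize",
    "compare_maps",
    "emd_distance",
    "aggregate_similarity",
]

METRICS = ("rmse", "pearson", "mssim", "emd", "iou_top40", "iou_top10")


@dataclass(frozen=True)
class SimilarityRow:
    rmse: float
    pearson: float
    mssim: float
    emd: float
    iou_top40: float
    iou_top10: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


@dataclass(frozen=True)
class MetricAggregate:
    mean: float
    sd: float
    ci_low: float
    ci_high: float


def minmax_normalize(map_: RelevanceMap) -> RelevanceMap:
    """Rescale relevance to span exactly [0, 1]."""
    lo, hi = float(map_.R.min()), float(map_.R.max())
    if hi <= lo:
        raise ValueError("constant map cannot be min-max normalized")
    return RelevanceMap((map_.R - lo) / (hi - lo), map_.image_id, map_.session_id)


def emd_distance(ref: RelevanceMap, alt: RelevanceMap) -> float:
    """Axis-marginal Wasserstein-1 distance between the two maps treated as
    unit-mass distributions; mean over the three axes, in voxel units."""
    if ref.shape != alt.shape:
        raise ValueError("maps are on different grids")
    a, b = ref.R, alt.R
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("EMD requires non-negative maps")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("EMD requires positive total mass")
    dists = []
    for axis in range(3):
        other = tuple(i for i in range(3) if i != axis)
        wa = a.sum(axis=other)
        wb = b.sum(axis=other)
        pos = np.arange(len(wa), dtype=float)
        dists.append(sps.wasserstein_distance(pos, pos, wa, wb))
    return float(np.mean(dists))


def compare_maps(
    ref: RelevanceMap,
    alt: RelevanceMap,
    windowing: tuple[WindowingSpec, WindowingSpec] = (
        WindowingSpec(relevance_fraction=0.40),
        WindowingSpec(relevance_fraction=0.10),
    ),
) -> SimilarityRow:
    """One metric row comparing two relevance maps (min-max normalized
    internally). RMSE is reported x100."""
    if ref.shape != alt.shape:
        raise ValueError("maps are on different grids")
    rn = minmax_normalize(ref)
    an = minmax_normalize(alt)
    rmse = float(np.sqrt(np.mean((rn.R - an.R) ** 2))) * 100.0
    pearson = float(np.corrcoef(rn.R.ravel(), an.R.ravel())[0, 1])
    win = min(7, min(ref.shape) - (1 - min(ref.shape) % 2))
    mssim = float(
        structural_similarity(
            rn.R, an.R, win_size=win, data_range=1.0, gaussian_weights=False
        )
    )
    emd = emd_distance(rn, an)
    ious = []
    for spec in windowing:
        m_ref = binarize_top_fraction(rn, spec)
        m_alt = binarize_top_fraction(an, spec)
        union = np.logical_or(m_ref, m_alt).sum()
        inter = np.logical_and(m_ref, m_alt).sum()
        ious.append(float(inter / union) if union else 1.0)
    return SimilarityRow(rmse, pearson, mssim, emd, ious[0], ious[1])


def aggregate_similarity(rows: Sequence[SimilarityRow]) -> dict[str, MetricAggregate]:
    """Mean, sample SD and normal 95% interval per metric across session
    pairs."""
    if not rows:
        raise ValueError("no similarity rows to aggregate")
    out = {}
    for m in METRICS:
        vals = np.array([getattr(r, m) for r in rows], dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[m] = MetricAggregate(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd)
    return out
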