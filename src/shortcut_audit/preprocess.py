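"""The eight preprocessing configurations.

Input volumes are intensity-normalized to the white-matter peak of the
within-mask intensity histogram (196 bins). From the normalized aligned
image, three binarized variants are derived at fixed fractions of the WM
peak (13.75%, 27.50%, 41.25%), and each of the four is additionally
skull-stripped by zeroing everything outside the brain mask — eight
configurations in total:

====  =============  ===========
id    skull-stripped  binarizer
====  =============  ===========
A1    no             none
B1    no             13.75%
C1    no             27.50%
D1    no             41.25%
A2    yes            none
B2    yes            13.75%
C2    yes            27.50%
D2    yes            41.25%
====  =============  ===========

WM-peak detection restricts candidate bins to intensities above the midpoint
of the in-mask range, so the gray-matter mode is never selected; the peak is
the center of the highest-count remaining bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import BrainMask, HeadVolume

__all__ = [
    "HistogramSpec",
    "BinarizationSpec",
    "ConfigurationId",
    "CONFIGURATIONS",
    "compute_wm_peak",
    "normalize_to_wm_peak",
    "apply_skull_strip",
    "binarize",
    "build_configurations",
]


@dataclass(frozen=True)
class HistogramSpec:
    n_bins: int = 196
    domain: str = "within_mask"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.domain != "within_mask":
            raise ValueError("only within_mask histograms are supported")


@dataclass(frozen=True)
class BinarizationSpec:
    threshold_fractions: tuple[float, ...] = (0.1375, 0.2750, 0.4125)

    def __post_init__(self) -> None:
        fr = self.threshold_fractions
        if any(not (0.0 < f < 1.0) for f in fr):
            raise ValueError("threshold fractions must lie in (0, 1)")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("threshold fractions must be strictly increasing")


@dataclass(frozen=True)
class ConfigurationId:
    id: str
    skull_stripped: bool
    binarizer: float | None  # fraction of the WM peak, or None

    def __str__(self) -> str:
        return self.id


def _make_configurations() -> dict[str, ConfigurationId]:
    fractions = BinarizationSpec().threshold_fractions
    configs = {}
    for col, stripped in (("1", False), ("2", True)):
        for row, frac in zip("ABCD", (None, *fractions)):
            cid = f"{row}{col}"
            configs[cid] = ConfigurationId(cid, stripped, frac)
    return configs


#: the bijection id <-> (skull_stripped, binarizer)
CONFIGURATIONS: dict[str, ConfigurationId] = _make_configurations()


def compute_wm_peak(
    volume: HeadVolume, mask: BrainMask, spec: HistogramSpec = HistogramSpec()
) -> float:
    """White-matter peak: center of the highest-count histogram bin among
    bins above the midpoint of the within-mask intensity range."""
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    values = volume.intensities[mask.mask]
    if values.size == 0:
        raise ValueError("empty mask")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise ValueError("constant within-mask intensities: no histogram peak")
    counts, edges = np.histogram(values, bins=spec.n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    candidates = centers >= lo + 0.5 * (hi - lo)
    best = np.flatnonzero(candidates)[np.argmax(counts[candidates])]
    peak = float(centers[best])
    if peak <= 0:
        raise ValueError("non-positive white-matter peak")
    return peak


def normalize_to_wm_peak(
    volume: HeadVolume, mask: BrainMask, spec: HistogramSpec = HistogramSpec()
) -> HeadVolume:
    peak = compute_wm_peak(volume, mask, spec)
    return volume.copy_with(volume.intensities / peak)


def apply_skull_strip(volume: HeadVolume, mask: BrainMask) -> HeadVolume:
    """Zero all intensities outside the brain mask."""
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match mask shape {mask.shape}"
        )
    return volume.copy_with(np.where(mask.mask, volume.intensities, 0.0))


def binarize(volume: HeadVolume, wm_peak: float, fraction: float) -> HeadVolume:
    """Threshold at ``fraction * wm_peak``; ties go to foreground."""
    if wm_peak <= 0:
        raise ValueError("wm_peak must be positive")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    out = (volume.intensities >= fraction * wm_peak).astype(np.float64)
    return volume.copy_with(out)


def build_configurations(
    volume: HeadVolume,
    mask: BrainMask,
    hist_spec: HistogramSpec = HistogramSpec(),
    bin_spec: BinarizationSpec = BinarizationSpec(),
) -> dict[str, HeadVolume]:
    """All eight preprocessing configurations of one aligned volume.

    Binarization is computed on the normalized aligned image; the
    skull-stripped variants apply the mask afterwards, so e.g. D2 equals
    ``apply_skull_strip(D1, mask)`` voxel for voxel.
    """
    normalized = normalize_to_wm_peak(volume, mask, hist_spec)
    peak = compute_wm_peak(normalized, mask, hist_spec)  # ~1 after normalization
    out: dict[str, HeadVolume] = {"A1": normalized}
    for row, frac in zip("BCD", bin_spec.threshold_fractions):
        out[f"{row}1"] = binarize(normalized, peak, frac)
    for row in "ABCD":
        out[f"{row}2"] = apply_skull_strip(out[f"{row}1"], mask)
    return out
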