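"""Background-ROI statistics, signal thresholding and whole-lung SNR.

The lung is segmented with the field's simple operational rule: pick a
10 x 10 voxel region of pure background, and keep every voxel whose value is
at least the ROI mean plus three ROI standard deviations. The same ROI's SD
serves as the noise estimate in the whole-lung SNR.

The threshold comparison is inclusive (>=) for deterministic boundary
behaviour, the ROI statistics use the population SD, and no Rician bias
correction is applied to the background SD — the noise estimate is the raw
SD of magnitude background, as in routine practice; these are documented
conventions, not fitted choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy import ndimage

from .recon import MagnitudeImage

ArrayLike = Union[np.ndarray, MagnitudeImage]


def _values(image: ArrayLike) -> np.ndarray:
    return image.values if isinstance(image, MagnitudeImage) else np.asarray(image, float)


@dataclass
class BackgroundROI:
    """Rectangular background region with its first two moments."""

    origin: tuple  # (row, col) of the ROI's top-left voxel
    size: tuple
    mean: float
    sd: float

    @classmethod
    def from_image(cls, image: ArrayLike, origin: Tuple[int, int], size: Tuple[int, int] = (10, 10)) -> "BackgroundROI":
        arr = _values(image)
        r, c = origin
        h, w = size
        if r < 0 or c < 0 or r + h > arr.shape[0] or c + w > arr.shape[1]:
            raise ValueError(f"ROI {origin}+{size} exceeds image bounds {arr.shape}")
        patch = arr[r : r + h, c : c + w]
        return cls(origin=(int(r), int(c)), size=(int(h), int(w)),
                   mean=float(patch.mean()), sd=float(patch.std()))


@dataclass
class LungMask:
    """Boolean lung segmentation with the threshold that produced it."""

    mask: np.ndarray
    threshold_value: float
    n_voxels: int


def _otsu_threshold(arr: np.ndarray, nbins: int = 256) -> float:
    """Otsu's between-class-variance maximizing cut on a value histogram."""
    counts, edges = np.histogram(arr.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    cum = np.cumsum(counts * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cum / w0
        mu1 = (cum[-1] - cum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    return float(centers[np.argmax(between)])


def select_background_roi(
    image: ArrayLike,
    seed: Optional[int] = None,
    size: Tuple[int, int] = (10, 10),
    margin_voxels: int = 6,
) -> BackgroundROI:
    """Seeded random placement of a background ROI far-removed from the lung.

    Provisional foreground is estimated with an Otsu cut; it is dilated by
    ``margin_voxels`` (so the ROI also clears the apodization halo around
    the lung, emulating an operator picking a region well away from signal)
    and one ROI is drawn uniformly among all placements that avoid the
    dilated foreground. Raises if the image is too small or no candidate
    exists (image saturated with signal).
    """
    arr = _values(image)
    h, w = size
    if arr.shape[0] < h or arr.shape[1] < w:
        raise ValueError(f"image {arr.shape} smaller than ROI {size}")
    if arr.max() > arr.min():
        fg = arr > _otsu_threshold(arr)
        if margin_voxels > 0 and fg.any():
            fg = ndimage.binary_dilation(fg, iterations=margin_voxels)
        bad = np.lib.stride_tricks.sliding_window_view(fg, size).any(axis=(2, 3))
    else:  # constant image: every placement is background
        bad = np.zeros((arr.shape[0] - h + 1, arr.shape[1] - w + 1), dtype=bool)
    candidates = np.argwhere(~bad)
    if len(candidates) == 0:
        raise ValueError("no all-background ROI position found (image saturated with signal)")
    rng = np.random.default_rng(seed)
    r, c = candidates[rng.integers(len(candidates))]
    return BackgroundROI.from_image(arr, (int(r), int(c)), size)


def threshold_and_mask(image: ArrayLike, roi: BackgroundROI) -> LungMask:
    """Mask voxels at or above the ROI mean plus three ROI SDs."""
    arr = _values(image)
    threshold = roi.mean + 3.0 * roi.sd
    mask = arr >= threshold
    return LungMask(mask=mask, threshold_value=float(threshold), n_voxels=int(mask.sum()))


def whole_lung_snr(image: ArrayLike, mask: Union[LungMask, np.ndarray], roi: BackgroundROI) -> float:
    """Mean in-mask signal divided by the background-ROI SD."""
    arr = _values(image)
    m = mask.mask if isinstance(mask, LungMask) else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty lung mask")
    if roi.sd <= 0:
        raise ValueError("background ROI has zero noise SD")
    return float(arr[m].mean() / roi.sd)
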