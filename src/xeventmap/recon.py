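"""K-space to magnitude-image reconstruction.

Raw frames are apodized with a separable sine-bell squared window and passed
through a centered unitary 2D inverse FFT; the magnitude is kept (signal
intensity and SNR are defined on magnitude data). K-space is stored
DC-centered, so the transform is wrapped in fftshift/ifftshift pairs to
avoid quadrant swaps. No zero-filling is applied; images keep the acquired
matrix size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .phantom import KSpaceFrame
from .series import ChallengeSeries


@dataclass
class MagnitudeImage:
    """Nonnegative 2D voxel array with geometry and protocol labels."""

    values: np.ndarray
    voxel_mm: tuple
    slice_thickness_mm: Optional[float] = None
    label: str = ""
    cumulative_dose_ug: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("MagnitudeImage requires a 2D array")
        if np.any(self.values < 0):
            raise ValueError("magnitude values must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def sine_bell_squared_window(n: int) -> np.ndarray:
    """1D sample-centered sine-bell squared weights w[j] = sin^2(pi (j+1/2)/n).

    The half-sample offset keeps both edge samples nonzero and the window
    exactly symmetric (w[j] == w[n-1-j]), peaking at the matrix center.
    """
    j = np.arange(n)
    return np.sin(np.pi * (j + 0.5) / n) ** 2


def sine_bell_squared(kspace: KSpaceFrame) -> KSpaceFrame:
    """Apodize a k-space frame with the separable sine-bell squared window.

    Pure: returns a new frame, the input is untouched.
    """
    if kspace.data.size == 0:
        raise ValueError("empty k-space")
    wr = sine_bell_squared_window(kspace.data.shape[0])
    wp = sine_bell_squared_window(kspace.data.shape[1])
    return replace(kspace, data=kspace.data * np.outer(wr, wp))


def reconstruct(kspace: KSpaceFrame, apodize: bool = True) -> MagnitudeImage:
    """Magnitude image from DC-centered k-space.

    Applies the sine-bell squared window (unless ``apodize`` is off), then a
    centered unitary 2D inverse FFT. With apodization off the transform is
    unitary, so Parseval energy conservation holds between k-space and the
    complex image.
    """
    if kspace.data.shape != tuple(kspace.config.matrix):
        raise ValueError("k-space shape does not match the acquisition matrix")
    frame = sine_bell_squared(kspace) if apodize else kspace
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(frame.data), norm="ortho"))
    return MagnitudeImage(
        values=np.abs(img),
        voxel_mm=kspace.config.voxel_mm,
        slice_thickness_mm=kspace.config.slice_thickness_mm,
        label=kspace.label,
        cumulative_dose_ug=kspace.cumulative_dose_ug,
    )


def reconstruct_series(series: ChallengeSeries, apodize: bool = True) -> ChallengeSeries:
    """Reconstruct every k-space frame of a series into magnitude images."""
    images = [reconstruct(f, apodize=apodize) for f in series.frames]
    return ChallengeSeries(
        frames=images,
        roles=list(series.roles),
        dose_increments_ug=list(series.dose_increments_ug),
        cumulative_dose_ug=list(series.cumulative_dose_ug),
        phantom=series.phantom,
        meta=dict(series.meta, apodize=apodize),
    )
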