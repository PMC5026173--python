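"""Challenge-series statistics: global signal, difference maps, heterogeneity.

For a challenge image M and baseline B, voxel index i, k voxels in the
analysis domain:

* normalized global signal intensity  GS = sum_i M_i / sum_i B_i
* absolute intensity difference map   dA_i = M_i - B_i
* relative intensity difference map
      dR_i = (M_i / mean(M) - B_i / mean(B)) * 100% / GS
  which captures redistribution of inhaled gas independent of the global
  loss: dR sums to zero over the full domain by construction and is scaled
  by 1/GS so late-challenge redistribution is not dwarfed by global signal
  loss. dR can fall below -100%.
* sigma_RID — the SD of dR over the analysis mask — is the scalar
  heterogeneity index of regional ventilation change; mean difference is the
  mean of dA over the same mask.

Reversal frames are compared against the maximum-dose frame (not baseline),
matching the convention that reversal maps show recovery from the fully
constricted state. NaN voxels in either frame are excluded from sums,
means and masks; their count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .recon import MagnitudeImage
from .segment import BackgroundROI
from .series import ChallengeSeries, cumulative_doses  # noqa: F401 (re-export)

ArrayLike = Union[np.ndarray, MagnitudeImage]


def _values(x: ArrayLike) -> np.ndarray:
    return x.values if isinstance(x, MagnitudeImage) else np.asarray(x, dtype=float)


def _domain_mask(arr: np.ndarray, domain: Optional[np.ndarray]) -> np.ndarray:
    if domain is None:
        return np.ones(arr.shape, dtype=bool)
    domain = np.asarray(domain, dtype=bool)
    if domain.shape != arr.shape:
        raise ValueError("domain mask shape mismatch")
    return domain


def global_signal(M: ArrayLike, B: ArrayLike, domain: Optional[np.ndarray] = None) -> float:
    """GS = sum(M) / sum(B) over the domain (default: all k voxels)."""
    m, b = _values(M), _values(B)
    if m.shape != b.shape:
        raise ValueError("image shape mismatch")
    d = _domain_mask(m, domain) & ~np.isnan(m) & ~np.isnan(b)
    denom = b[d].sum()
    if denom <= 0:
        raise ValueError("baseline voxel sum is not positive")
    return float(m[d].sum() / denom)


@dataclass
class GlobalSignalCurve:
    """Per-frame GS values against a fixed reference."""

    gs: np.ndarray
    reference_mode: str  # first_baseline | averaged_reference
    reference_indices: list
    cumulative_dose_ug: list
    roles: list
    labels: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "role": self.roles,
                "cumulative_dose_ug": self.cumulative_dose_ug,
                "GS": self.gs,
            }
        )


def default_reference_indices(series: ChallengeSeries) -> list:
    """Averaged-reference convention: all baselines, the fluid frame, and the
    first dose frame (compensates slow polarization drift)."""
    idx = series.indices("baseline") + series.indices("fluid")
    dose_idx = series.indices("dose")
    if dose_idx:
        idx.append(dose_idx[0])
    return sorted(idx)


def global_signal_curve(
    series: ChallengeSeries,
    reference_mode: str = "first_baseline",
    reference_indices: Optional[Sequence[int]] = None,
    domain: Optional[np.ndarray] = None,
) -> GlobalSignalCurve:
    """GS for every frame of a series against a shared reference.

    ``first_baseline`` divides each frame's voxel sum by the first baseline
    frame's; ``averaged_reference`` divides by the mean voxel sum of the
    designated reference frames (defaults to baselines + fluid + first dose).
    """
    sums = []
    for f in series.frames:
        arr = _values(f)
        d = _domain_mask(arr, domain) & ~np.isnan(arr)
        sums.append(arr[d].sum())
    sums = np.asarray(sums)

    if reference_mode == "first_baseline":
        ref_idx = [series.indices("baseline")[0]]
    elif reference_mode == "averaged_reference":
        ref_idx = list(reference_indices) if reference_indices is not None else default_reference_indices(series)
        if not ref_idx or any(i >= len(series) for i in ref_idx):
            raise ValueError("designated reference frames missing from series")
    else:
        raise ValueError(f"unknown reference mode {reference_mode!r}")
    ref = sums[ref_idx].mean()
    if ref <= 0:
        raise ValueError("reference voxel sum is not positive")
    return GlobalSignalCurve(
        gs=sums / ref,
        reference_mode=reference_mode,
        reference_indices=ref_idx,
        cumulative_dose_ug=list(series.cumulative_dose_ug),
        roles=list(series.roles),
        labels=series.labels,
    )


def absolute_difference_map(M: ArrayLike, B: ArrayLike) -> np.ndarray:
    """Voxel-wise dA = M - B (for reversal frames, B is the max-dose frame)."""
    m, b = _values(M), _values(B)
    if m.shape != b.shape:
        raise ValueError("image shape mismatch")
    return m - b


def relative_difference_map(
    M: ArrayLike,
    B: ArrayLike,
    gs: Optional[float] = None,
    domain: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Voxel-wise dR = (M/mean(M) - B/mean(B)) * 100% / GS.

    Means and GS are taken over the chosen domain (default: whole image,
    k = total voxel count). If ``gs`` is omitted it is computed from the
    same two frames on the same domain. Voxels outside the domain or NaN in
    either frame are NaN in the output.
    """
    m, b = _values(M), _values(B)
    if m.shape != b.shape:
        raise ValueError("image shape mismatch")
    d = _domain_mask(m, domain) & ~np.isnan(m) & ~np.isnan(b)
    mean_m, mean_b = m[d].mean(), b[d].mean()
    if mean_m <= 0 or mean_b <= 0:
        raise ValueError("frame means must be positive")
    if gs is None:
        gs = mean_m / mean_b
    if gs <= 0:
        raise ValueError("GS must be positive")
    out = np.full(m.shape, np.nan)
    out[d] = (m[d] / mean_m - b[d] / mean_b) * 100.0 / gs
    return out


@dataclass
class DifferenceResult:
    """Paired dA / dR maps with their scalar summaries over an analysis mask."""

    delta_A: np.ndarray
    delta_R: np.ndarray
    analysis_mask: np.ndarray
    mean_difference: float  # mean of dA over the mask, signal units
    sigma_RID: float  # population SD of dR over the mask, percent
    n_voxels: int
    n_excluded_nan: int = 0
    label: str = ""
    cumulative_dose_ug: Optional[float] = None


def summarize_difference(
    delta_A: np.ndarray,
    delta_R: np.ndarray,
    analysis_mask: Optional[np.ndarray] = None,
    label: str = "",
    cumulative_dose_ug: Optional[float] = None,
) -> DifferenceResult:
    """Mean difference (mean dA) and sigma_RID (population SD of dR) over a mask."""
    delta_A = np.asarray(delta_A, float)
    delta_R = np.asarray(delta_R, float)
    if delta_A.shape != delta_R.shape:
        raise ValueError("map shape mismatch")
    mask = _domain_mask(delta_A, analysis_mask)
    valid = mask & ~np.isnan(delta_A) & ~np.isnan(delta_R)
    if not valid.any():
        raise ValueError("empty analysis mask")
    return DifferenceResult(
        delta_A=delta_A,
        delta_R=delta_R,
        analysis_mask=valid,
        mean_difference=float(delta_A[valid].mean()),
        sigma_RID=float(delta_R[valid].std()),  # population SD (n divisor)
        n_voxels=int(valid.sum()),
        n_excluded_nan=int(mask.sum() - valid.sum()),
        label=label,
        cumulative_dose_ug=cumulative_dose_ug,
    )


@dataclass
class NoiseReport:
    """Background-noise consistency across a challenge sequence."""

    means: np.ndarray
    fluctuation: float  # max |mean_f - mean_ref| / mean_ref, ref = first frame
    flagged: bool
    threshold: float = 0.20

    def to_frame(self) -> pd.DataFrame:
        ref = self.means[0]
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.means)),
                "noise_mean": self.means,
                "rel_deviation": np.abs(self.means - ref) / ref,
            }
        )


def noise_consistency(rois: Sequence[BackgroundROI], threshold: float = 0.20) -> NoiseReport:
    """Check that per-frame background noise means stay within a fractional
    band of the first frame's (default 20%); flag the series otherwise."""
    means = np.asarray([r.mean for r in rois], dtype=float)
    if means[0] <= 0:
        raise ValueError("reference noise mean must be positive")
    fluct = float(np.abs(means - means[0]).max() / means[0])
    return NoiseReport(means=means, fluctuation=fluct, flagged=fluct >= threshold, threshold=threshold)


def regional_summary(result: DifferenceResult, roi_boxes: Sequence[tuple]) -> pd.DataFrame:
    """Per-box mean/SD of dA and dR for rectangular regions of interest.

    Boxes are (row, col, height, width) in voxel units; supports e.g.
    apical-vs-basal comparisons. SDs are population SDs, consistent with
    sigma_RID.
    """
    rows = []
    shape = result.delta_A.shape
    for i, (r, c, h, w) in enumerate(roi_boxes):
        if h <= 0 or w <= 0 or r < 0 or c < 0 or r + h > shape[0] or c + w > shape[1]:
            raise ValueError(f"box {(r, c, h, w)} empty or outside grid {shape}")
        da = result.delta_A[r : r + h, c : c + w]
        dr = result.delta_R[r : r + h, c : c + w]
        rows.append(
            {
                "box": i,
                "row": r,
                "col": c,
                "height": h,
                "width": w,
                "mean_dA": float(np.nanmean(da)),
                "sd_dA": float(np.nanstd(da)),
                "mean_dR": float(np.nanmean(dr)),
                "sd_dR": float(np.nanstd(dr)),
            }
        )
    return pd.DataFrame(rows)


def defect_mask(delta: np.ndarray, cut: float) -> np.ndarray:
    """Voxels whose signal dropped by at least ``cut`` (delta <= -cut).

    Operationalizes ventilation-defect detection on dA (signal units) or dR
    (percent) maps; NaN voxels are never flagged.
    """
    delta = np.asarray(delta, float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(delta), False, delta <= -cut)
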