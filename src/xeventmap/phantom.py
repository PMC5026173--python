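"""Digital lung phantom and hyperpolarized-gas acquisition simulator.

Every downstream stage of the package (reconstruction, segmentation,
challenge metrics, statistics) is exercised against synthetic data produced
here, so the forward model mirrors the measurement chain of an ex vivo
hp-gas ventilation experiment:

* a two-lobed coronal lung mask on a 128 (read) x 64 (phase) grid with a
  field of view of 47.3 x 31.5 mm;
* contiguous ventilation regions, each carrying its own Hill-type
  dose-response to cumulative methacholine (MCh): the OVA (allergic-asthma)
  preset responds at a lower effective dose and with markedly larger
  inter-region heterogeneity than the control preset;
* a variable-flip-angle (VFA) FLASH readout that spends the nonrenewable
  hyperpolarized magnetization evenly across phase-encode lines;
* additive complex Gaussian noise in k-space, so magnitude backgrounds are
  Rician as on a real scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .series import ChallengeSeries, cumulative_doses

# Inter-region spread scales (dimensionless); multiplied by the phantom's
# heterogeneity parameter eta.
LOG_EC50_SD0 = 0.5
EMAX_SD0 = 0.15


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic ventilation phantom.

    ``heterogeneity`` (eta) scales the inter-region spread of the regional
    dose-response parameters: log-EC50 SD = eta * 0.5, Emax SD = eta * 0.15
    (Emax clipped to [0, 1]). eta = 0 gives perfectly homogeneous response.
    """

    grid_shape: tuple = (128, 64)
    fov: tuple = (47.3, 31.5)
    n_regions: int = 12
    baseline_amplitude: float = 100.0
    heterogeneity: float = 0.3
    ec50_mean: float = 500.0
    hill_coefficient: float = 1.5
    emax_mean: float = 0.3
    noise_sd: float = 0.65
    seed: int = 0
    phenotype_label: str = "control"

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 8:
            raise ValueError("grid_shape entries must be >= 8")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")
        if not 0.0 <= self.emax_mean <= 1.0:
            raise ValueError("emax_mean must lie in [0, 1]")
        if self.ec50_mean <= 0:
            raise ValueError("ec50_mean must be > 0")
        if self.hill_coefficient <= 0:
            raise ValueError("hill_coefficient must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")


def control_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Control-phenotype preset: high EC50, mild heterogeneity, shallow Emax.

    Baseline amplitude and noise are calibrated so the default windowed
    reconstruction yields whole-lung SNR ~ 70, the value reported for
    nonslice-selective imaging of healthy lungs.
    """
    return PhantomSpec(seed=seed, phenotype_label="control", **overrides)


def ova_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """OVA (allergic asthma) preset: ~4x lower EC50, ~3x larger heterogeneity,
    deeper maximal constriction, and lower baseline signal (SNR ~ 50)."""
    defaults = dict(
        ec50_mean=120.0,
        heterogeneity=1.0,
        emax_mean=0.7,
        baseline_amplitude=72.0,
        phenotype_label="OVA",
    )
    defaults.update(overrides)
    return PhantomSpec(seed=seed, **defaults)


@dataclass
class VentilationPhantom:
    """Ground-truth regional gas distribution with dose-response parameters."""

    amplitude_map: np.ndarray
    region_labels: np.ndarray
    region_params: pd.DataFrame  # columns: region, ec50, emax, hill
    lung_mask_true: np.ndarray
    spec: Optional[PhantomSpec] = None


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and timing of the gradient-echo readout.

    ``flip_schedule`` holds per-phase-encode flip angles in radians; ``None``
    means an idealized unit transverse factor on every line (useful for
    round-trip tests). ``mode`` labels slice-selective vs nonslice-selective
    acquisitions; slice physics is not modelled beyond the label and the
    recorded slice thickness.
    """

    matrix: tuple = (128, 64)
    fov_mm: tuple = (47.3, 31.5)
    slice_thickness_mm: Optional[float] = None
    te_ms: float = 1.27
    tr_ms: float = 67.5
    flip_schedule: Optional[tuple] = None
    mode: str = "nonslice"

    def __post_init__(self) -> None:
        if min(self.matrix) <= 0:
            raise ValueError("matrix entries must be > 0")
        if self.mode not in ("slice", "nonslice"):
            raise ValueError("mode must be 'slice' or 'nonslice'")

    @property
    def voxel_mm(self) -> tuple:
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])


def default_config(matrix: tuple = (128, 64), vfa: bool = True, **kw) -> AcquisitionConfig:
    """Standard config with the constant-signal VFA schedule on the phase axis."""
    sched = tuple(constant_signal_flip_schedule(matrix[1])) if vfa else None
    return AcquisitionConfig(matrix=matrix, flip_schedule=sched, **kw)


@dataclass
class KSpaceFrame:
    """Raw complex 2D k-space matrix with acquisition geometry, DC-centered."""

    data: np.ndarray
    config: AcquisitionConfig
    label: str = ""
    cumulative_dose_ug: Optional[float] = None

    def __post_init__(self) -> None:
        if self.data.shape != tuple(self.config.matrix):
            raise ValueError(
                f"k-space shape {self.data.shape} != matrix {self.config.matrix}"
            )


def _lung_mask_template(shape: tuple) -> np.ndarray:
    """Two elliptical lobes joined by a tracheal bridge, scaled to the grid."""
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError(f"grid {shape} too small for the two-lobe lung template")
    r = np.arange(h)[:, None]
    c = np.arange(w)[None, :]
    mask = np.zeros(shape, dtype=bool)
    for cc in (0.30 * w, 0.70 * w):
        mask |= ((r - 0.52 * h) / (0.34 * h)) ** 2 + ((c - cc) / (0.155 * w)) ** 2 <= 1.0
    bridge = (r >= 0.16 * h) & (r <= 0.28 * h) & (c >= 0.40 * w) & (c <= 0.60 * w)
    mask |= bridge
    n_comp = ndimage.label(mask)[1]
    if n_comp != 1:  # tiny grids can disconnect after rasterization
        raise ValueError(f"grid {shape} too small for a connected lung template")
    return mask


def make_phantom(spec: PhantomSpec) -> VentilationPhantom:
    """Build the ground-truth phantom: lung mask, region partition,
    per-region Hill parameters.

    Regions are a Voronoi partition of the lung mask seeded from random
    in-mask points; region parameters are drawn with spread proportional to
    the heterogeneity eta. Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _lung_mask_template(spec.grid_shape)
    coords = np.argwhere(mask)
    if spec.n_regions > len(coords):
        raise ValueError("n_regions exceeds number of lung voxels")

    seed_idx = rng.choice(len(coords), size=spec.n_regions, replace=False)
    tree = cKDTree(coords[seed_idx])
    nearest = tree.query(coords)[1]
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    labels[mask] = nearest + 1

    eta = spec.heterogeneity
    ec50 = np.exp(rng.normal(np.log(spec.ec50_mean), eta * LOG_EC50_SD0, spec.n_regions))
    emax = np.clip(rng.normal(spec.emax_mean, eta * EMAX_SD0, spec.n_regions), 0.0, 1.0)
    params = pd.DataFrame(
        {
            "region": np.arange(1, spec.n_regions + 1),
            "ec50": ec50,
            "emax": emax,
            "hill": np.full(spec.n_regions, spec.hill_coefficient),
        }
    )

    amplitude = np.where(mask, spec.baseline_amplitude, 0.0)
    return VentilationPhantom(amplitude, labels, params, mask, spec)


def _response_fraction(phantom: VentilationPhantom, dose: float) -> np.ndarray:
    """Per-voxel multiplicative ventilation fraction v(D) in [0, 1]."""
    v = np.ones(phantom.amplitude_map.shape, dtype=float)
    if dose == 0:
        return v
    p = phantom.region_params
    for region, ec50, emax, hill in zip(p["region"], p["ec50"], p["emax"], p["hill"]):
        frac = dose**hill / (dose**hill + ec50**hill)
        v[phantom.region_labels == region] = 1.0 - emax * frac
    return v


def apply_dose(phantom: VentilationPhantom, cumulative_dose: float) -> np.ndarray:
    """Ground-truth amplitude after a cumulative MCh dose (µg).

    Each region r is scaled by the Hill sigmoid
    ``v_r(D) = 1 - emax_r * D^h / (D^h + ec50_r^h)``; the map is
    monotonically non-increasing in D and equals the baseline exactly at
    D = 0.
    """
    if cumulative_dose < 0:
        raise ValueError("cumulative dose must be >= 0")
    return phantom.amplitude_map * _response_fraction(phantom, cumulative_dose)


def reversal_amplitude(
    phantom: VentilationPhantom, max_cumulative_dose: float, restore_fraction: float = 0.5
) -> np.ndarray:
    """Amplitude after partial bronchodilator reversal.

    Models reversal as fractional restoration of the constriction reached at
    the maximum cumulative dose: v_rev = v(D_max) + f * (1 - v(D_max)).
    """
    if not 0.0 <= restore_fraction <= 1.0:
        raise ValueError("restore_fraction must lie in [0, 1]")
    v = _response_fraction(phantom, max_cumulative_dose)
    return phantom.amplitude_map * (v + restore_fraction * (1.0 - v))


def constant_signal_flip_schedule(n_lines: int) -> np.ndarray:
    """VFA flip angles theta_j = arctan(1/sqrt(n - j)), j = 1..n (radians).

    With nonrenewable longitudinal magnetization, this schedule yields the
    same transverse signal on every phase-encode line (the final pulse is
    90 degrees), so all of the hyperpolarization is spent evenly.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    j = np.arange(1, n_lines + 1)
    return np.arctan2(1.0, np.sqrt(n_lines - j))


def flip_factors(flip_schedule: Sequence[float]) -> np.ndarray:
    """Per-line transverse-signal factors for nonrenewable magnetization.

    Line j produces ``sin(theta_j) * prod_{i<j} cos(theta_i)`` of the
    initial longitudinal magnetization.
    """
    theta = np.asarray(flip_schedule, dtype=float)
    cos_prior = np.concatenate(([1.0], np.cumprod(np.cos(theta))[:-1]))
    return np.sin(theta) * cos_prior


def simulate_acquisition(
    amplitude: np.ndarray,
    config: AcquisitionConfig,
    noise_sd: float,
    seed: Optional[int] = None,
    label: str = "",
    cumulative_dose_ug: Optional[float] = None,
) -> KSpaceFrame:
    """Forward-model a magnitude ground truth into noisy DC-centered k-space.

    The unitary 2D DFT of the amplitude map is weighted line-by-line along
    the phase axis with the flip-schedule transverse factors, then
    independent complex Gaussian noise (SD ``noise_sd`` per real/imaginary
    channel) is added.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if amplitude.shape != tuple(config.matrix):
        raise ValueError(
            f"amplitude shape {amplitude.shape} != matrix {config.matrix}"
        )
    k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(amplitude), norm="ortho"))
    if config.flip_schedule is not None:
        f = flip_factors(config.flip_schedule)
        if len(f) != config.matrix[1]:
            raise ValueError("flip_schedule length must equal the phase matrix size")
        k = k * f[None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        k = k + rng.normal(0.0, noise_sd, k.shape) + 1j * rng.normal(0.0, noise_sd, k.shape)
    else:
        k = k.astype(complex)
    return KSpaceFrame(k, config, label=label, cumulative_dose_ug=cumulative_dose_ug)


def generate_challenge_series(
    spec: PhantomSpec,
    dose_schedule: Sequence[float],
    n_baseline: int = 2,
    config: Optional[AcquisitionConfig] = None,
    seed: Optional[int] = None,
    include_fluid: bool = True,
    include_reversal: bool = True,
    reversal_restore: float = 0.5,
) -> ChallengeSeries:
    """Simulate a full MCh challenge protocol into a k-space series.

    Emits ``n_baseline`` baseline frames, an optional vehicle/fluid frame,
    one frame per dose increment (labelled with per-step and cumulative
    dose), and an optional partial-reversal frame. Every frame is noised
    independently; the whole series is reproducible from ``seed`` (defaults
    to the spec's seed).
    """
    if len(dose_schedule) == 0:
        raise ValueError("dose schedule must contain at least one increment")
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    phantom = make_phantom(spec)
    if config is None:
        config = default_config(matrix=tuple(spec.grid_shape))
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    def frame_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    cum = cumulative_doses(dose_schedule)
    frames, roles, cum_per_frame = [], [], []
    for b in range(n_baseline):
        frames.append(
            simulate_acquisition(
                phantom.amplitude_map, config, spec.noise_sd, frame_seed(),
                label=f"baseline{b + 1}", cumulative_dose_ug=0.0,
            )
        )
        roles.append("baseline")
        cum_per_frame.append(0.0)
    if include_fluid:
        frames.append(
            simulate_acquisition(
                phantom.amplitude_map, config, spec.noise_sd, frame_seed(),
                label="fluid", cumulative_dose_ug=0.0,
            )
        )
        roles.append("fluid")
        cum_per_frame.append(0.0)
    for inc, total in zip(dose_schedule, cum):
        frames.append(
            simulate_acquisition(
                apply_dose(phantom, total), config, spec.noise_sd, frame_seed(),
                label=f"mch{inc:g}ug", cumulative_dose_ug=float(total),
            )
        )
        roles.append("dose")
        cum_per_frame.append(float(total))
    if include_reversal:
        amp = reversal_amplitude(phantom, cum[-1], reversal_restore)
        frames.append(
            simulate_acquisition(
                amp, config, spec.noise_sd, frame_seed(),
                label="reversal", cumulative_dose_ug=float(cum[-1]),
            )
        )
        roles.append("reversal")
        cum_per_frame.append(float(cum[-1]))

    return ChallengeSeries(
        frames=frames,
        roles=roles,
        dose_increments_ug=[float(d) for d in dose_schedule],
        cumulative_dose_ug=cum_per_frame,
        phantom=phantom,
        meta={"seed": spec.seed if seed is None else seed, "spec": spec},
    )


# The printed MCh increment protocol (µg per step).
DEFAULT_DOSE_SCHEDULE = (10.0, 25.0, 50.0, 75.0, 100.0, 200.0, 400.0)
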