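# Methods

## The measurement problem

Hyperpolarized ¹²⁹Xe gives a lung gas-space MRI signal that is large but
nonrenewable: the polarization is consumed by excitation pulses and cannot be
averaged back. In a bronchoprovocation experiment a lung is imaged on one
inhalation per protocol step — baseline (≥2 frames), a vehicle/fluid step,
then increasing methacholine (MCh) doses tracked as a cumulative dose, and
optionally a bronchodilator reversal. Airway narrowing reduces how much gas
enters the lung (a global effect) and redirects it between regions (a
regional effect). The package quantifies both, and ships a simulator of the
whole chain so each stage has a testable ground truth.

## Forward model (phantom + acquisition)

**Geometry.** Images are 128 (read) × 64 (phase) over a 47.3 × 31.5 mm FOV,
i.e. 0.37 × 0.49 mm voxels; a slice-selective mode is a label plus recorded
slice thickness only (no RF-profile physics).

**Lung template.** Two ellipses (per-lobe semi-axes 0.34·H × 0.155·W,
centers at 30%/70% of the width) joined by a tracheal bridge; occupancy is
verified to land in 20–50% of the grid and the mask to be one connected
component. Ventilation amplitude is uniform inside the mask at
`baseline_amplitude` (arbitrary units); intra-lung texture is deliberately
not modelled (see Limitations).

**Regions and dose response.** The mask is split into `n_regions` contiguous
cells by a seeded Voronoi partition (nearest of `n_regions` random in-mask
points). Each region r responds to cumulative dose D with a Hill sigmoid

    v_r(D) = 1 − emax_r · D^h / (D^h + ec50_r^h),

the standard pharmacological dose-response form with minimal parameters.
Heterogeneity is a single dial η: `log ec50_r ~ N(log ec50_mean, (0.5·η)²)`
and `emax_r ~ N(emax_mean, (0.15·η)²)` clipped to [0, 1]; η = 0 makes all
regions identical. Reversal is fractional restoration of the constriction
reached at the maximum dose, `v_rev = v(D_max) + f·(1 − v(D_max))` with
f = 0.5 by default (partial reversal is what is observed experimentally).

**Presets.** `control`: ec50 500 µg, η 0.3, emax 0.3. `ova` (allergic
phenotype): ec50 120 µg, η 1.0, emax 0.7, lower baseline amplitude. These
are calibration defaults chosen so the simulated GS curves bracket the
qualitative behaviour of the two phenotypes (near-flat control vs >50% GS
loss in OVA at 860 µg, with ~3× heterogeneity); they are not fitted to any
dataset.

**Acquisition.** k-space is the unitary 2D DFT of the amplitude map, stored
DC-centered. Each phase-encode line j is weighted by the transverse factor
of the variable-flip-angle FLASH schedule θ_j = arctan(1/√(n−j)), which
spends nonrenewable magnetization to give a constant per-line signal (the
last pulse is 90°); an idealized unit-factor mode exists for round-trip
tests. Independent N(0, noise_sd²) noise is added to the real and imaginary
channels of every sample, so magnitude backgrounds after reconstruction are
Rician (Rayleigh where signal is zero, mean/SD ratio √(π/2)/√(2−π/2) ≈ 1.91).

**Noise calibration.** `noise_sd = 0.65` (control preset, amplitude 100) was
set once so that the default windowed reconstruction yields whole-lung
baseline SNR ≈ 70, the reported nonslice-selective value for healthy lungs;
the OVA preset's amplitude 72 gives SNR ≈ 50. Doubling amplitude at fixed
noise doubles measured SNR (verified by Monte-Carlo test).

## Reconstruction

A separable sine-bell-squared window, `w[j] = sin²(π(j+½)/N)` per axis, is
applied to raw k-space before a centered unitary 2D inverse FFT; the
magnitude is kept. The half-sample phase convention keeps both edge samples
nonzero and the window exactly symmetric about the matrix center. fftshift /
ifftshift pairs around the transform keep images un-swapped for DC-centered
data. No zero-filling is applied. Apodization trades resolution for noise:
the point-spread function's second moment strictly grows (tested), and
image-domain noise SD shrinks by ≈ mean(w²) = 3/8 relative to unwindowed —
which is why the noise calibration above is done through the windowed path.

## Segmentation and SNR

A 10×10 background ROI supplies the noise statistics. Placement is
automated: provisional foreground by an Otsu cut, dilated by a 6-voxel
margin, and a seeded uniform draw among all ROI positions clear of it. The
margin exists because a percentile-cut rule without it let ROIs sit in the
apodization halo around the lung (or in dim, heavily constricted lung),
which made noise means and SNR erratic; the margin emulates an operator
choosing a region "far removed" from signal. The lung mask keeps voxels
≥ ROI mean + 3·ROI SD (inclusive comparison, population SD). Whole-lung SNR
is mean in-mask signal / ROI SD — a mean-based, whole-lung definition rather
than peak SNR. No Rician bias correction is applied to the background SD;
this matches common practice and slightly inflates the noise estimate.

On pure Gaussian noise the mean+3SD rule masks ≈0.13% of voxels (one-sided
3σ tail); with a 100-voxel ROI the estimated threshold itself fluctuates, so
the expected masked fraction is slightly above the nominal tail — the test
suite checks the rule against a direct simulation of that estimator, not
against the nominal value alone.

## Challenge metrics

Equations and conventions as in the README. Domain choices: GS and the ΔR
normalization default to the whole image (all k voxels); σ_RID and the mean
difference default to the union of the two frames' lung masks, since
background voxels would dilute a lung-focused heterogeneity statistic. Both
domains are exposed because the lung-only alternative is equally defensible.
σ_RID uses the population SD (n divisor): it is a descriptive map statistic,
not an inferential estimate. Reversal frames are differenced against the
maximum-cumulative-dose frame. Voxels NaN in either frame are excluded from
sums, means and masks, and the exclusion count is reported. No inter-frame
registration is performed (single-inhalation ex vivo frames are acquired in
a fixed holder); the pipeline logs this, and misregistration-like edge
artifacts remain a known failure mode on real data.

Noise monitoring compares each frame's background-ROI mean to the first
frame's; fluctuation ≥20% flags the series. Note the 10×10 ROI mean has ~5%
sampling error, so an 11-frame series can flag at ~20% even with perfectly
stationary noise — the flag is a data-quality warning (an error only under
`--strict`), not a hard gate.

## Statistics

Bland-Altman: differences on the percent-of-pair-mean scale by default
(raw scale available); bias ± 1.96·sample SD gives the 95% limits of
agreement (1.96 is the conventional multiplier). Dose-response comparison:
two-way ANOVA (group × cumulative dose, type-II sums of squares — robust to
the mildly unbalanced group sizes typical of these experiments) via
statsmodels, with per-dose Student t contrasts Bonferroni-corrected by the
number of dose levels. On balanced designs the sums of squares partition the
total exactly, and the family-wise type-I error of the contrasts stays ≤0.05
under a simulated null (both tested). t-tests default to Student's flavor
(Welch by flag); the degenerate all-equal case returns p = 1 by convention.

## What a green test establishes — and what it does not

The synthetic world emulates: the acquisition geometry, Rician noise and
realistic baseline SNR, a monotone regional dose response with controllable
heterogeneity, polarization-drift-free baselines, and the full protocol
bookkeeping. It does not emulate: intra-lung ventilation texture, airway
structures, B₀/B₁ inhomogeneity, diffusive blurring from long readouts, T₁
decay of the hyperpolarized gas, inter-frame motion, or pressure-to-volume
mechanics (airway pressure is not modelled at all). Green tests therefore
establish the correctness and calibration of the analysis chain on its
stated model — not the physiological accuracy of the phantom, and not any
published in vivo/ex vivo effect size.

## Numerical conventions

Unitary (ortho-normalized) FFTs throughout; seeds propagate from a single
integer through `numpy.random.default_rng` (child seeds < 2³¹); threshold
comparisons are inclusive; population vs sample SD is population for map
statistics (σ_RID, ROI stats) and sample for inferential quantities
(Bland-Altman SD, t-tests); Hill curves evaluate exactly to baseline at
D = 0 and are monotone non-increasing in dose per voxel.
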