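# Methods

## The phantom and its design space

All analysis is anchored in a single design-space description of the
phantom: a right-handed millimeter frame with the origin at the center of
the plate stack (+x left→right, +y posterior→anterior, +z
inferior→superior). The encoded features are

- a 170 mm spherical shell filled with 2.9 mM CuSO₄ solution;
- 15 solid, signal-free fiducial spheres (10 mm diameter), a cross of five
  per plate (plate offsets −50/0/+50 mm; arms ±50 mm along the in-plane
  axes), 50 mm center-to-center. Over the three scan planes their in-plane
  radii take exactly the values {0, 50, 70.7} mm, which define the radial
  distortion groups;
- three quantitative arrays of 14 mimic spheres (18 mm inner diameter):
  NiCl₂ (0.29–65.3 mM), MnCl₂ (0.0113–1.5996 mM), PVP (0–50 % w/w, ADC
  2.00→0.27 ×10⁻³ mm²/s);
- a ten-element liquid-crystal thermometer with phase transitions at whole
  degrees 15–24 °C and a 24.5 °C maximum reading.

The phantom's specification fixes the counts, diameters, spacings, and the
concentration/ADC range endpoints, but not the per-mimic concentrations or
the angular placement of mimics on each plate. Those are implementation
constants frozen here: doped-array concentrations are geometrically spaced
between the printed extremes (matching their log-spaced appearance on a
logarithmic concentration axis), and each plate carries six mimics on an
inner ring (r = 28 mm) and eight on an outer ring (r = 55 mm), angularly
offset from the fiducial cross so every sphere clears the fiducials and
stays inside the shell on the ±50 mm plates. The thermometer is a row of
3 mm-radius elements at y = −72 mm on the central plate, spaced 6 mm along
x so that anisotropic axial scans resolve them in-plane. All downstream
mathematics depends only on self-consistency between this template and the
simulator, not on the particular placement.

Per-mimic reference relaxation times follow the linear rate model
R = R₀ + r·C with default relaxivities r₁/r₂ of 0.624/0.549 mM⁻¹s⁻¹
(NiCl₂) and 21.9/34.6 mM⁻¹s⁻¹ (MnCl₂) and zero-concentration rates
R₁,₀ = 0.3 s⁻¹ and R₂,₀ = 0.5 s⁻¹ (NiCl₂) / 3.0 s⁻¹ (MnCl₂) — values of
the right magnitude for doped aqueous solutions at 64 mT, chosen once so
that MnCl₂ has T₂ < T₁ everywhere (tissue-like) while NiCl₂ stays near
T₂/T₁ ≈ 1. The fill solution is assigned T₁ = 0.25 s, T₂ = 0.20 s.

## Synthetic scans

The simulator renders a session from explicit ground truth — rigid
misplacement (three Euler angles + translation), a smooth distortion field,
a noise level, the phantom temperature, and a site baseline Larmor
frequency — so every metric downstream has an exact oracle.

Signal formation uses the standard weightings (times in seconds): T2w fast
spin echo S = PD(1−e^(−TR/T1))e^(−TE/T2) with the nominal effective TE
(echo-train magnetization-transfer and diffusion effects are not modelled);
signed inversion recovery S = M0(1−2e^(−TI/T1)+e^(−TR/T1)) for T1 mapping
(phase-corrected real-valued convention — the same expression the fitter
uses, deliberately, since the mapping data are simulated and fitted by one
model family); mono-exponential decay for multi-echo T2 mapping; the
short-TE thermometer scan reuses the spin-echo weighting with TE = 5 ms.
Default protocols: T2w TR 2.2 s / TE 180 ms at 1.5×1.5×5 mm (fine in-plane,
coarse slices, matching the anisotropy of low-field acquisitions; the slice
axis follows the scan plane); T1 mapping with 20 TIs log-spaced 25–4000 ms
at TR 5 s; T2 mapping with 16 echoes from 9 ms at 5.4 ms spacing.

Rendering details that matter for the oracles:

- Features are rasterized with 3×3×3 per-voxel supersampling, keeping the
  centroid bias of a rasterized sphere well below half a voxel.
- Misplacement and distortion displace *feature centers*: a feature at
  design position p appears at Rp + t + d(p). Spheres are not deformed —
  for smooth fields capped at 2.5 mm the within-sphere field variation is
  negligible — and in exchange the distortion oracle is exact: the detected
  centroid equals the applied field at the design position plus the rigid
  motion.
- Distortion fields provided: a radial polynomial d(p) = a(|p|/85)^k·p̂ and
  a capped linear (affine) field; both clip their magnitude at a
  configurable cap (default 2.5 mm, the scale of distortions seen on these
  systems).
- Noise is additive Gaussian on the final image with SD = noise_sigma ×
  mean fill intensity, clipped at zero. After vendor reconstruction the
  true noise distribution on real scanners is unknown (correlated,
  non-Rician); Gaussian is the simplest model that exercises a
  repeated-scan PSNR, whose contract is distribution-agnostic.
- The repeated axial scan shares the first axial scan's noiseless rendering
  and differs only in its noise realization. One session seed
  deterministically derives all per-scan seeds; identical seeds give
  bit-identical volumes.
- Thermometer elements at or past their transition temperature are rendered
  signal-free; cooler elements carry fill-like signal.

What the simulator does *not* emulate — k-space sampling, coil
sensitivities, EMI waveforms, vendor deep-learning reconstruction, B0
inhomogeneity as an image-domain warp, magnetization transfer — bounds what
green tests mean: they validate the analysis chain (segmentation accuracy,
metric formulas, exclusion rules, statistical recovery) under controlled
truth, not the scanner physics producing real artifacts.

## Segmentation

Mimics, the fill mask, and thermometer elements come from template label
transfer: a noiseless, undistorted 1 mm isotropic rendering with
rasterization-derived labels (the stand-in for a high-field template scan
with manual labels) is rigidly registered to the acquired volume and its
labels are resampled nearest-neighbor. Registration maximizes normalized
cross-correlation (robust to global intensity scaling between software
versions) over the six rigid parameters, from a center-of-mass (moments)
initialization, coarse-to-fine (shrink 4/2/1), via SimpleITK's
regular-step gradient descent with physical-shift parameter scaling and
dense sampling for determinism. The achieved NCC is reported; values below
0.6 flag a low-confidence result rather than aborting. For the thermometer
scan the template is re-rendered with the short-TE weighting, so the
similarity metric compares matching contrasts — with the T2w-weighted
template the mismatched mimic pattern can pull the optimizer into a tilted
local optimum.

Fiducials are deliberately *not* template-constrained (their positions
would then inherit the registration's global transform, hiding exactly the
distortions they measure). A classical detector replaces a trained
segmenter: the phantom mask (Otsu, largest component, holes filled) is
eroded to drop the partial-volume rim; voxels darker than half the fill
level (the interior median) are candidates — a global Otsu inside the mask
would instead split fill from bright mimics, the signal-free class being
far too small to drive the histogram; connected components are gated by
volume (200–1400 mm³ around the 524 mm³ design sphere) and bounding-box
extent (≤ 22 mm); centroids are intensity-weighted centers of gravity of
the inverted image in world millimeters. Ids are assigned by Hungarian
matching against the design positions after a centroid-shift pre-alignment,
refined once by a rigid fit on the current matches; ties resolve
deterministically. Fewer than four detections is an error (a rigid
alignment would be underdetermined).

Contrast extraction crops each mimic label to the single slice (along the
low-resolution axis) containing its warped design center, avoiding
partial-volume dilution at the sphere poles on 5 mm slices.

## QC metrics

**PSNR.** Both repeats are normalized by their own global maximum — the
simplest reading of "scale each image to unit maximum"; a masked-maximum
mode is configurable — and MSE is taken over the phantom mask. The noise law —
doubling the noise SD costs 20·log10 2 = 6.02 dB — holds in the regime
where the masked MSE is noise-dominated while the maximum stays
signal-dominated; the acceptance check runs at 0.2–0.4 % noise for that
reason. Identical inputs (MSE = 0) are an error, not an infinite value.

**Distortion.** Detected centroids are aligned onto the design positions by
the Kabsch algorithm (centroid removal, SVD of the cross covariance,
determinant-corrected rotation). The per-fiducial distortion is defined as
reference minus aligned-acquired position, i.e. the vector pointing from
where a fiducial landed back to where it belongs. Records with
3D |Δr̄| > 20 mm are marked excluded and never enter summaries; the rigid
fit is not repeated after exclusion. Radius groups use the *design*
position (stable under distortion); reporting focuses on the in-plane
magnitude, where anisotropic voxels resolve positions well.

**Temperature.** Each element's mean intensity is compared to half the
fill-solution mean (a threshold between fill and zero); the dark count n
maps to T = 14.5 + n °C, consistent with whole-degree transitions at
15–24 °C: one dark element reads 15.5 °C, all ten read 24.5 °C and set the
capped flag (the vendor's exact calibration table is not published; the
mapping is configurable). All-bright sets a capped-low flag at 14.5 °C.
The reading is quantized to the element ladder, so a true 20.0 °C phantom
reads 20.5 °C — within the half-degree resolution the hardware provides.

## Relaxometry

T1 fits use the signed IR model with multi-start T1 initialization
(six starts log-spaced over the TI range) and honest convergence flags; a
magnitude-polarity-restoration mode is intentionally absent by default
since the data convention is phase-corrected real values. T2 fits use
log-linear initialization on the positive echoes with nonlinear refinement,
flagging fits where most echoes are non-positive or T2 falls below the
first echo time (the protocol cannot resolve such fast decay — the reason
the highest-concentration mimics are filtered before relaxivity
regression). Per-mimic ROI summaries use the median for mapping
experiments and the mean for contrast intensities, both fixed. Relaxivity
regression is unweighted OLS of rate on concentration (a weighted variant
is available); the concentration filters and any explicit exclusions (such
as a manufacturer-reported drifted mimic) are applied first and recorded in
the result. Tissue matching selects, per tissue, the mimic minimizing
|T₂,mimic − T₂,ref| — T2-weighted protocols make T2 the contrast-dominant
time — with ties toward the lower id; T1 offsets are reported but do not
drive the choice. Reference tissue values are taken at nominal temperature;
no temperature correction is applied (no published coefficients at 64 mT).

## Study statistics

The Larmor-frequency/temperature relation is modelled with one shared slope
and a separate intercept per site. It is estimated as a fixed-effects
dummy-variable OLS rather than a REML mixed model: for this estimand the
slope matches the mixed-model description while remaining closed-form and
deterministic; the distinction is documented rather than hidden. Sessions
whose thermometer reading saturated (capped) are excluded — their true
temperature is unknown. The pooled single-line OLS is reported alongside:
between-site baseline differences mask the within-site slope there, which
is exactly why the per-site-intercept model exists. ANOVA across sites is
the classical one-way fixed-effects decomposition; modPSNR is the default
working variable for PSNR comparisons. Longitudinal summaries report
empirical 2.5–97.5 percentile interval widths and mark the first session
bearing each new software tag as a change-point. Dates are ISO-8601. No
multiple-testing correction is applied; p-values are reported as-is.

## Problem sizes and numerical choices

Default grids are 120×120×36 at 1.5×1.5×5 mm for QC scans and 184³ at 1 mm
for the template — large enough that sphere rasterization, detection, and
registration behave as on real data while a full session simulates in
under a second and a complete QC analysis (two registrations, three
detections, all metrics) runs in about half a minute on one CPU. Monte
Carlo checks use 100 replicates (relaxivity, T1 recovery) or 10 seeds
(PSNR law). Rotation matrices are validated orthonormal to 1e-6 and
re-orthonormalized via SVD beyond 1e-12; label transfer uses order-0
resampling so legends can never grow; contrast requires a strictly positive
reference intensity; Kabsch rejects collinear configurations via the
second singular value.

## Known limitations

- Mimic intensity means include label-edge partial volume, biasing mimic
  means toward the fill level by up to ~10–15 % on coarse grids; contrast
  remains internally consistent (and scale-invariant) but is not a pure
  signal-equation value.
- The distortion analysis measures the field only at 15 points; no field
  interpolation over the FOV is attempted (too few fiducials).
- The classical fiducial detector assumes negative-contrast spheres inside
  a bright fill; heavily corrupted real scans may need the gating
  parameters adjusted.
- DICOM support is read-only and minimal (pixel data, spacing, position,
  imaging frequency); NIfTI-1 with JSON sidecars is the primary format.
- ADC fitting, multi-component relaxometry, B1 correction, EMI
  quantification, and the resolution insert are out of scope.
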