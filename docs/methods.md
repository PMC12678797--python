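# Methods

## The phantom model

The digital phantom emulates a cylindrical PVP QA object, 170 mm tall and
150 mm in diameter, with four axial compartments: a homogeneous
gray-matter-mimicking control region (ADC 0.8·10⁻³ mm²/s, ≈31 % PVP, T2
taken as 730 ms), a lesion insert in which six circular lesions mimicking
cytotoxic edema (ADC 0.5·10⁻³ mm²/s, ≈42 % PVP, T2 544 ms) are embedded in
the same matrix at diameters 10/7/5/4/3/2 mm, a homogeneous
restricted-diffusion control region, and a resolution insert (geometry
only; it is not scored here).

All metrics of interest are computed on a single slice, so the simulation
is 2-D: `build_phantom` rasterizes one compartment cross-section onto a
square grid (per-pixel compartment label, true ADC, T2, proton density).
Slice thickness (3 mm) enters only as the divisor converting the standard
ROI volumes to in-plane areas.  A pixel belongs to a lesion when its
center falls inside the lesion circle; rasterization is deliberately
crisp — through-plane and in-plane partial-volume mixing is *not*
modelled, which keeps the ground truth exact for recovery tests (a
supersampled partial-volume rendering was evaluated and widens every
lesion edge by about one pixel, degrading the edge-profile diameter
estimator without adding validity to the metrics under test).

The in-plane lesion layout is not a property the analysis depends on and
is a free design choice: the six lesions sit on a horizontal line through
the insert, adjacent centers spaced 1.5× the larger of the two diameters,
the row centered on the cylinder axis.  `compact_phantom()` trims the
cylinder to 80 mm around the identical lesion row for fast runs; every
metric's ground truth is unchanged.

## Acquisition simulation

Per repeat and b-value the forward model is

    S_b = PD · exp(−TE/T2) · exp(−b · ADC)

followed, in order, by

1. Gaussian blur (`blur_fwhm`, mm) — a surrogate for T2*/PSF blurring;
2. a smooth sinusoidal displacement along the phase-encode (row) axis with
   amplitude `pe_shift` (mm) — a surrogate for susceptibility distortion;
   it deforms round objects without simulating field-map physics, which is
   all the distortion metric needs to respond to;
3. for blade-style acquisitions, a multiplicative amplitude loss inside
   lesions and a ~2 mm surrounding band — mimicking local off-resonance
   signal loss;
4. Rician noise: the magnitude of complex Gaussian noise with per-channel
   SD `noise_sigma` added to the clean signal (so a zero-signal region has
   mean σ·√(π/2));
5. for the high-b image, averaging of `n_averages_b1000` independent noise
   draws of the same distorted clean image — matching how repeated
   excitations are averaged on-scanner (noise before averaging, draws
   independent).

Noise is applied after the deterministic degradations; all randomness
flows from a single seed per scan, and series derive per-repeat seeds from
a master seed via `numpy` seed sequences, so identical inputs and seeds
give bit-identical pixels.

Temperature: the phantom warms during a session (default schedule 21 →
22.5 °C across the 10 repeats; the per-sequence presets use consecutive
windows 21→22, 22→22.5, 22.5→22.5).  Because diffusion in aqueous PVP
accelerates with temperature, the generator scales the true diffusivity by
exp(c·(T−20)) with the compartment-specific coefficient (c = 0.0315 /°C
for the edema mimic, 0.0297 /°C for the gray-matter mimic); the analysis
side divides it back out.  This coupling is what makes the 20 °C
correction testable end-to-end; it can be disabled for experiments that
want temperature as pure metadata.

The three sequence presets (`ssEPI`, `rsEPI`, `TGSE_BLADE`) order the
imperfection magnitudes by the sequences' known artifact behaviour —
ss-EPI the largest distortion and blur plus 12-fold high-b averaging to
match scan time, rs-EPI small distortion, TGSE-BLADE the smallest shift
but nonzero amplitude loss — with echo times from the protocol table and
noise scales chosen so repeat-series SNR lands in the tens.  They are
plausibility calibrations, explicitly **not** fitted to any particular
scanner's output, so preset-level metric values are illustrative while the
metric *definitions*, recovery properties and orderings are the tested
content.

## Analysis choices

- **Resampling**: native 1.1 mm images are bilinearly interpolated to the
  0.5 mm analysis grid.  Source and target grids share the physical origin
  at the FOV center (pixel-center convention), avoiding a systematic
  half-pixel diameter bias; edges clamp.
- **ADC**: ln(S_low/S_high)/Δb per pixel; pixels with non-positive signal
  are flagged invalid, excluded from ROI statistics and counted.  ROI
  means are corrected to 20 °C with that repeat's temperature and the
  coefficient selected by ROI compartment (not per-pixel tissue
  inference).  Reported in units of 10⁻³ mm²/s, 2 decimals in summaries;
  raw values kept in the CSVs.
- **Temporal SD**: sample SD (n−1) across repeats per voxel, averaged over
  the ROI.  n−1 is unbiased at n = 10; a noiseless series has zero
  temporal SD and the noise metrics report that degenerate case
  explicitly rather than a number.
- **Background pooling**: the four ≈170 mm³ matrix ROIs flanking the
  lesion row (placement a free choice, kept ≥ 2 mm clear of every lesion)
  are pooled at pixel level before means and SDs.
- **ReCon**: per-repeat value from the two ROI means; the series value is
  the mean over repeats, matching a mean ± SD over 10 scans presentation.
- **GDR**: 360 profiles at 1° offsets (the 180° redundancy is kept to
  match the stated procedure), bilinear sampling at a default step of half
  the pixel, averaged position-wise.  On each side of the center the
  minimum is searched excluding the innermost 20 % of the half-profile
  (noise dips inside the lesion are not matrix minima); the edge threshold
  is literally min × 1.10, with min + 10 % of (peak − min) available
  behind `threshold_rule` since the phrasing is ambiguous; crossings are
  refined by linear interpolation; a minimum at the profile end flags the
  estimate unreliable.  The flanking minima are treated as baseline
  anchors and the 10 % crossings as the edges.  Profile half-length
  defaults to 1.5× the expected diameter.  The estimator carries a small
  outward bias (the threshold crosses the edge ramp below its midpoint),
  bounded by about half a pixel; validation therefore runs on a phantom
  rasterized directly at the 0.5 mm analysis pixel, and the known-dilation
  check draws the lesion 5 % larger in the scene (an exact imposed
  distortion) rather than warping the sampled image, which would add
  resampling blur of its own.
- **2 mm lesion**: supported but excluded from default summaries — at
  0.5 × 0.5 × 3 mm voxels its ROI holds ~5 pixels and the measurements are
  not interpretable; `include_2mm=True` restores it.
- **Statistics**: Wilcoxon signed-rank pairs sequences by repeat index
  (the only pairing repeated phantom scans admit), drops zero differences,
  uses the exact null for n ≤ 25 and the tie-corrected normal
  approximation beyond; an all-zero difference vector is reported as
  degenerate with p = 1.  Kruskal–Wallis returns H = 0, p = 1 when every
  value is identical.  Spearman correlates per-repeat metric values pooled
  across lesion sizes by default (n = repeats × sizes), with a means-only
  mode; strength classes use strict thresholds (|ρ| > 0.3/0.5/0.7), so a
  boundary value falls in the lower class.  No multiple-testing
  adjustment is applied by default (Holm available), α = 0.05 two-sided.
- **Weighted kappa**: linear weights by default (the weighting behind the
  published values is undocumented, so quadratic is exposed too and κ
  values are not treated as reproduction targets); asymptotic
  (Fleiss–Cohen–Everitt) SE for the 95 % CI; Altman bands with gap values
  (e.g. 0.205) assigned to the lower band; both-raters-constant-and-equal
  is degenerate (chance agreement 1) and reported as undefined κ with
  100 % raw agreement.
- **Ratings reconstruction**: the bundled two-rater tables are a synthetic
  reconstruction of the published score distributions — exact per
  rater × sequence × criterion, arbitrary in within-sequence order (lower
  scores placed first), since per-image assignments were never published.
  Only distribution-level quantities computed from them (percent
  agreement, κ up to ordering effects) are meaningful.

## Problem sizes and determinism

Default runs use the full 150 mm phantom at 1.1 mm native / 0.5 mm
analysis pixels, 10 repeats, 3 sequences (seconds of runtime); the test
suite uses the compact 80 mm phantom and 2–6 repeats, and Monte-Carlo
properties (noise halving, √12 averaging) use a 40 mm homogeneous disk
with 100 seeds per arm.  Every pipeline output is a pure function of the
configuration and master seed; the JSON report embeds a config hash and
the seed, and re-running a configuration reproduces the report
byte-for-byte.

## Limitations

The simulator is 2-D and partial-volume-free; it has no k-space physics,
coil sensitivities, GRAPPA, eddy currents or Siemens-star rendering, and
its distortion/blur/amplitude-loss knobs are phenomenological.  Passing
tests therefore demonstrate correctness of the metric implementations and
their response to controlled degradations — not that the presets
quantitatively reproduce any scanner's Table of values, which depend on
hardware, reconstruction and the physical phantom.
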