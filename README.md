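# dwiphantom

Quality-assurance analysis of diffusion-weighted MRI (DWI) sequences on a
digital lesion phantom, built for comparing how well different sequences
(single-shot EPI, readout-segmented EPI, turbo gradient-spin-echo BLADE)
depict *small* diffusion-restricted lesions — the setting of retinal
ischemia imaging, where the structure of interest is millimetres across.

The package provides a synthetic stand-in for a physical PVP phantom: a
cylindrical gray-matter-mimicking matrix (ADC 0.8·10⁻³ mm²/s) holding six
circular lesions that mimic cytotoxic edema (ADC 0.5·10⁻³ mm²/s) at
diameters 10, 7, 5, 4, 3 and 2 mm, plus two homogeneous control
compartments.  An acquisition simulator produces repeated two-b-value
magnitude series (b = 0 / 1000 s/mm²) with per-sequence blur, phase-encode
distortion, blade-style amplitude loss, Rician noise, signal averaging and
temperature drift, and the analysis layer computes the quantitative metrics
used to score such phantoms.

## The metrics

With S₀ and S_b the b=0 and b=1000 magnitude signals,

- **ADC**, from the mono-exponential decay S_b = S₀·exp(−b·ADC), referred
  to 20 °C by ADC₂₀ = ADC / exp(c·(T − 20 °C)) with c = 0.0315 /°C for the
  edema mimic and 0.0297 /°C for the gray-matter mimic;
- **SNR_mult** = mean_i [ SI_ROI(i) / SD_ROI ], where SI_ROI(i) is the ROI
  mean in repeat i and SD_ROI is the voxel-wise *temporal* standard
  deviation across the repeated scans, averaged over the ROI — robust to
  the spatially non-uniform noise of multi-channel coils with parallel
  imaging;
- **CNR_mult** = mean_i [ (SI_ROI(i) − SI_GM(i)) / SD_GM ], against four
  pixel-pooled background ROIs in the surrounding matrix;
- **ReCon** = (SI_ROI − SI_GM) / (SI_ROI + SI_GM), a noise-free relative
  contrast;
- **GDR** = |D_DWI − D_t| / D_t · 100 %, where D_DWI is the lesion diameter
  measured on the mean of 360 radial signal profiles through the lesion
  center as the distance between the first points 10 % above the two
  flanking signal minima.

Sequence comparisons use Kruskal–Wallis and pairwise Wilcoxon signed-rank
tests (paired by repeat), lesion-size dependence uses Spearman's ρ with the
conventional strength classes, and two-rater 0–4 Likert scores are scored
with linear-weighted Cohen's κ (asymptotic 95 % CI, Altman bands) and raw
percent agreement.

## Worked example

```python
from dwiphantom import *
from dwiphantom.phantom import build_phantom, default_phantom
from dwiphantom.acquisition import sequence_preset, simulate_series
from dwiphantom.adc import adc_roi_summary, compute_adc_map, CorrectionConstants
from dwiphantom.roi import default_rois

grids = build_phantom(default_phantom(), "lesion_insert", pixel_size=0.5)
series = simulate_series(grids, sequence_preset("rsEPI", n_repeats=10), master_seed=7)
maps = [compute_adc_map(b0, b1000) for b0, b1000 in series.repeats]
roi = default_rois(grids)["lesions"][0]          # 74 mm³ ROI in the 10 mm lesion
s = adc_roi_summary(maps, roi, CorrectionConstants(), "lesion")
print(f"{roi.label}: ADC20 = {s.mean:.2f} ± {s.sd:.2f} ×1e-3 mm²/s")
```

prints

```
10mm: ADC20 = 0.50 ± 0.00 ×1e-3 mm²/s
```

i.e. the temperature-corrected ADC in the largest lesion recovers the
0.5·10⁻³ mm²/s ground truth, with repeat-to-repeat scatter below the
displayed precision at this noise level.

The numbered drivers under `analysis/` run the full study:
`01_simulate_phantom.py` (archive the raw series as NIfTI + JSON sidecars),
`02_quantitative_metrics.py` (ADC/SNR/CNR/ReCon/GDR tables and the
sequence statistics), `03_gdr_profiles.py` (radial profiles and diameter
estimates), `04_rater_agreement.py` (κ and agreement per rating
criterion); outputs land under `results/`.  The same stages are available
as CLI subcommands (`dwiphantom simulate | resample | adc | gdr | stats |
report | fixtures`).

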