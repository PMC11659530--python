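# rsikit

Multi-b-value diffusion MRI modelling for nodal-status prediction in rectal
cancer: per-voxel fitting of three diffusion signal models, whole-tumor ROI
quantification with two-observer agreement, and the full comparison
statistics — plus a synthetic phantom/cohort generator with known ground
truth standing in for patient data.

**Who it is for:** researchers comparing diffusion models (conventional
DWI, diffusion kurtosis imaging, restriction spectrum imaging) as imaging
biomarkers of lymph node metastasis (LNM), and anyone needing a fully
seeded, ground-truthed sandbox for multi-compartment diffusion pipelines.

## The models

Over an 11-shell acquisition (b = 0…2000 s/mm², per-shell NEX
1,1,1,1,1,2,2,2,4,4,4), each voxel's signal is fitted with:

* **DWI** — S_b/S₀ = exp(−b·ADC), inverted from b = 0 and 800 s/mm²;
* **DKI** — S_b = S₀·exp(−b·D_app + b²·D_app²·K_app/6), a log-domain
  linear fit with constraint projection (D_app > 0, 0 ≤ K_app ≤ 3);
* **RSI** — S(b) = S₀·(f₁e^(−b·D₁) + f₂e^(−b·D₂) + f₃e^(−b·D₃)) with fixed
  D₁,D₂,D₃ = 0.5, 1.3, 3.0 ×10⁻³ mm²/s (restricted / hindered / free
  water), solved by non-negative least squares; fractions are the
  normalized weights.

Whole-tumor ROI means (necrotic core excluded) per observer feed ICC(2,1)
agreement, group comparisons with an adaptive normality gate
(Shapiro–Wilk → t-test or Mann–Whitney U; chi-square for categoricals),
logistic regression with odds ratios per 1 SD, ROC with Youden cutoffs, and
DeLong paired-AUC tests of the composite scores DWI (ADC), RSI (f₁+f₃) and
DKI (D_app+K_app).

## Worked example

```python
from rsikit import (DwiSeries, aggregate_roi, fit_volume,
                    generate_lesion_phantom)

phantom = generate_lesion_phantom("positive", grid_shape=(16, 16, 8),
                                  seed=42, snr_at_b0=50.0)
maps = fit_volume(DwiSeries(phantom.dwi, phantom.scheme),
                  phantom.roi_observer1)
m = aggregate_roi(maps, phantom.roi_observer1,
                  exclusion=phantom.necrosis_mask)
```

Running `python examples/01_phantom_and_fitting.py` prints:

```
lesion voxels used: 330
whole-tumor mean ADC   : 1.334 x10^-3 mm^2/s
whole-tumor mean D_app : 1.552 x10^-3 mm^2/s
whole-tumor mean K_app : 0.834
whole-tumor mean f1    : 0.420 (ground truth 0.430)
```

The fitted whole-tumor restricted fraction (0.420) tracks the simulated
ground truth (0.430) to within a few hundredths at SNR 50 — the level of
accuracy the downstream group statistics rely on. The other examples cover
observer agreement (`02`), screening/eligibility and the cohort table
(`03`), and the full statistics stage (`04`); each prints the numbers it
computes with a note on what they mean.

A thin CLI wraps the same pipeline for shell use:

```bash
rsikit simulate --out run/sim --seed 1
rsikit fit      --inp run/sim --out run/maps
rsikit roi      --sim run/sim --maps run/maps --out run/roi
rsikit stats    --cohort run/cohort.csv --out run/stats
```

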