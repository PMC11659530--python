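"""Simulate one lesion phantom and fit the three diffusion models.

Builds a noisy multi-b phantom for an LNM-positive-style lesion, fits the
mono-exponential (ADC), kurtosis (D_app, K_app) and three-compartment
(f1, f2, f3) models over the tumor ROI, and compares the whole-tumor mean
restricted fraction against the simulation ground truth.
"""
import numpy as np

from rsikit import DwiSeries, aggregate_roi, fit_volume, generate_lesion_phantom

phantom = generate_lesion_phantom("positive", grid_shape=(16, 16, 8),
                                  seed=42, snr_at_b0=50.0)
dwi = DwiSeries(phantom.dwi, phantom.scheme)
maps = fit_volume(dwi, phantom.roi_observer1)
m = aggregate_roi(maps, phantom.roi_observer1,
                  exclusion=phantom.necrosis_mask, patient_id="demo",
                  observer_id="obs1")

truth_f1 = np.mean(phantom.truth["f1"][phantom.roi_observer1
                                       & ~phantom.necrosis_mask])
print(f"lesion voxels used: {m.n_voxels}")
print(f"whole-tumor mean ADC   : {m.values['adc'] * 1e3:.3f} x10^-3 mm^2/s")
print(f"whole-tumor mean D_app : {m.values['d_app'] * 1e3:.3f} x10^-3 mm^2/s")
print(f"whole-tumor mean K_app : {m.values['k_app']:.3f}")
print(f"whole-tumor mean f1    : {m.values['f1']:.3f} "
      f"(ground truth {truth_f1:.3f})")
# The fitted restricted fraction should track the simulated truth to within
# a few hundredths at this signal-to-noise ratio.
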