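"""Fit voxelwise T2* maps on a synthetic fetal phantom.

Renders one 64³ phantom (placenta, fetal brain, amniotic-fluid background)
at the emulated 5-echo acquisition, fits the mono-exponential decay in every
voxel, and compares the fitted maps with the known ground truth — first
noiselessly (recovery is exact to machine precision), then at first-echo
SNR 20 (per-voxel errors of a few percent; the ROI mean is far tighter
because it averages thousands of voxels).
"""

import dataclasses

import numpy as np

from fetalt2star import PhantomSpec, fit_t2star_map, make_phantom, mean_t2star

# --- noiseless: inverse of the forward model -------------------------------
bundle = make_phantom(dataclasses.replace(PhantomSpec(), snr_echo1=None))
t2map, s0map = fit_t2star_map(bundle.volume)
sel = t2map.validity.astype(bool)
rel = np.abs(t2map.data[sel] - bundle.t2star_truth.data[sel]) / bundle.t2star_truth.data[sel]
print("noiseless phantom: %d voxels fitted, max |rel error| = %.2e" % (sel.sum(), rel.max()))

# --- noisy: first-echo SNR 20 ----------------------------------------------
bundle = make_phantom(dataclasses.replace(PhantomSpec(), seed=42))
t2map, _ = fit_t2star_map(bundle.volume, roi=bundle.placenta_mask)
sel = bundle.placenta_mask.as_bool() & t2map.validity.astype(bool)
rel = np.abs(t2map.data[sel] - bundle.t2star_truth.data[sel]) / bundle.t2star_truth.data[sel]
truth_mean = float(np.nanmean(bundle.t2star_truth.data[bundle.placenta_mask.as_bool()]))
fitted_mean = mean_t2star(t2map, bundle.placenta_mask)  # < 500 msec threshold
print(
    "SNR-20 phantom:  median voxel |rel error| = %.1f%%;"
    " placental mean T2* truth %.1f vs fitted %.1f msec"
    % (100 * np.median(rel), truth_mean, fitted_mean)
)
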