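"""Continuous decomposition analysis of one recording.

Deconvolves skin conductance by the Bateman impulse response, splits the
driver into tonic and phasic parts, and checks the result against the
generator's ground truth.
"""

import numpy as np
from scipy.ndimage import gaussian_filter1d

from edadrive import (DEFAULT_PROFILES, SynthConfig, decompose, preprocess,
                      synthesize_recording)

cfg = SynthConfig(seed=7, noise_sd=0.0)
rec, truth = synthesize_recording(cfg, DEFAULT_PROFILES["text"])
clean = preprocess(rec)          # 10th-order Butterworth <20 Hz, 50 Hz rate
dec = decompose(clean)

# ground-truth impulse train on the working grid, smoothed like the driver
train = np.zeros(clean.samples.size)
idx = np.minimum(np.round(truth.impulse_times * clean.fs).astype(int),
                 train.size - 1)
np.add.at(train, idx, truth.impulse_amps * clean.fs)
smoothed = gaussian_filter1d(train, 0.2 * clean.fs)

tonic_truth = truth.tonic_truth[::4]
tonic_err = (np.sqrt(np.mean((dec.sc_tonic - tonic_truth) ** 2))
             / np.sqrt(np.mean(tonic_truth ** 2)))

print(f"recording: {truth.impulse_times.size} SCR impulses over "
      f"{clean.duration_s:.0f} s (text condition, noiseless)")
print(f"reconstruction error (sc_tonic + sc_phasic vs sc): "
      f"{dec.reconstruction_error():.4f} relative RMS")
print(f"phasic driver vs smoothed true impulse train:      "
      f"r = {np.corrcoef(dec.driver_phasic, smoothed)[0, 1]:.3f}")
print(f"tonic recovery error:                              "
      f"{100 * tonic_err:.2f}% relative RMS")
print(f"phasic driver 20th percentile (zero-baseline check): "
      f"{np.percentile(dec.driver_phasic, 20):+.4f} µS/s")
print("\nA correlation near 1 and a near-zero phasic baseline mean the "
      "deconvolution has untangled overlapping SCRs from the tonic drift.")
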