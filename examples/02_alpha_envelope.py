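"""Compute the single-trial alpha envelope and verify the 2A/pi rule.

The envelope procedure: baseline, 8-13 Hz zero-phase band-pass,
rectify, trim 200 ms per edge, average in 100 ms windows every 50 ms.
For a pure sinusoid of amplitude A the rectified mean is 2A/pi.
"""

import numpy as np

from alphalight import alphapower
from alphalight.containers import EpochSet

amp, fs = 10.0, 500.0
t = -0.7 + np.arange(950) / fs
wave = amp * np.sin(2 * np.pi * 10.0 * t)
epochs = EpochSet(voltages=np.tile(wave, (1, 1, 1)).astype(np.float32),
                  fs=fs, t_start_ms=-700.0, channel_labels=["O1"])

series = alphapower.alpha_envelope(alphapower.bandpass_alpha(epochs))
print(f"grid: {series.grid_times_ms[0]:g}..{series.grid_times_ms[-1]:g} ms "
      f"in {len(series.grid_times_ms)} windows")
print(f"envelope mean {series.values.mean():.3f} uV; "
      f"2A/pi = {2 * amp / np.pi:.3f} uV")

summary = alphapower.pretarget_alpha(series, {"left": ["O1"],
                                              "right": ["O1"]})
print(f"pre-target (-500..0 ms) summary: {summary.alpha_pooled[0]:.3f} uV, "
      f"log = {summary.log_alpha_pooled[0]:.3f}")
# The summary is the per-trial quantity every model downstream consumes.
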