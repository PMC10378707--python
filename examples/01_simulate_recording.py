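"""Generate a synthetic annotated flight recording and inspect its band powers.

The generator plants workload-dependent band-limited oscillations on a 1/f
background: the landing phase (high workload) carries the strongest frontal
slow-wave activity, while cruise (low workload) shows the occipital α rhythm.
"""

import numpy as np

from mwl_eeg import PHASES, SimConfig, generate_recording
from mwl_eeg.features import band_powers, fft_spectrum

# artifacts off so the whole-phase periodogram shows the planted band
# pattern undistorted (blink pulses would inflate δ); the cleaning chain in
# example 02 handles them the proper way, by epoch rejection
cfg = SimConfig(seed=7, artifact_rate=0.0)
rec = generate_recording(cfg)
print(f"recording: {rec.n_channels} channels x {rec.duration_s:.0f} s "
      f"at {rec.fs:.0f} Hz")

for ann in rec.annotations:
    i0, i1 = int(ann.start_s * rec.fs), int(ann.end_s * rec.fs)
    af3 = rec.samples[rec.channel_names.index("AF3"), i0:i1]
    pz = rec.samples[rec.channel_names.index("Pz"), i0:i1]
    bp_f = band_powers(fft_spectrum(af3, rec.fs))
    bp_o = band_powers(fft_spectrum(pz, rec.fs))
    print(f"\n{ann.phase:>9}:  AF3 δ = {bp_f['δ']:6.1f} μV²   "
          f"Pz α = {bp_o['α']:6.1f} μV²")

# Frontal δ power grows from cruise to landing (workload), while the
# occipital α is strongest in cruise — the contrast the classifier exploits.
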