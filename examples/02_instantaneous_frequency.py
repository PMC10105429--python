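"""Instantaneous frequency from the analytic signal.

Builds a linear chirp (5 -> 20 Hz over 8 s), forms the analytic signal
Z = x + iH[x], and shows that the derivative of its unwrapped phase tracks
the known instantaneous frequency sample by sample — the resolution that
distinguishes the Hilbert view from a windowed Fourier spectrum.
"""

import numpy as np
from scipy.signal import chirp

from hhteeg.hilbert_spectral import analytic_signal, instantaneous_freq_amp

rate = 128.0
t = np.arange(1024) / rate
x = chirp(t, f0=5.0, t1=8.0, f1=20.0)

z = analytic_signal(x)
trace = instantaneous_freq_amp(z, rate)

print("time (s)   true f (Hz)   estimated f (Hz)")
for sec in (1, 2, 3, 4, 5, 6, 7):
    i = int(sec * rate)
    true_f = 5.0 + 15.0 * sec / 8.0
    print(f"{sec:7.1f} {true_f:12.2f} {trace.frequency[i]:15.2f}")

err = np.abs(trace.frequency - (5.0 + 15.0 * t / 8.0))[trace.valid_mask]
print(f"\nmax |error| over valid samples: {err.max():.3f} Hz")
print(f"masked-out fraction (edges, negative-frequency glitches): "
      f"{1 - trace.valid_fraction:.2%}")
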