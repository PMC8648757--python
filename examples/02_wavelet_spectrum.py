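"""Morlet scalogram and time-averaged spectrum of a two-tone signal.

A 600-s series holding a VLF tone (0.02 Hz) and a cardiac tone (1.2 Hz)
is transformed over the 0.009-2 Hz grid; the time-averaged spectrum
should peak at both injected frequencies.
"""

import numpy as np

from fnirspect import MorletParams, cwt, time_avg_spectrum, validate_duration

fs = 10.0
t = np.arange(6000) / fs
x = 1.0 * np.sin(2 * np.pi * 0.02 * t) + 0.5 * np.sin(2 * np.pi * 1.2 * t)

params = MorletParams()  # f0 = 1, 0.009-2 Hz, 16 voices/octave
advisory = validate_duration(len(x) / fs, params.f_min)
print(f"duration check: {advisory.cycles:.1f} cycles of {params.f_min} Hz"
      + (f" -> {advisory.message}" if advisory.warn else " -> ok"))

sg = cwt(x, params, fs, check_duration=False)
print(f"scalogram: {sg.coeffs.shape[0]} frequencies x {sg.coeffs.shape[1]} samples")

spec = time_avg_spectrum(sg)  # cone-of-influence excluded by default
for f_true in (0.02, 1.2):
    lo, hi = f_true / 1.3, f_true * 1.3
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    f_peak = spec.freqs[sel][np.argmax(spec.amplitude[sel])]
    print(f"tone at {f_true:g} Hz -> spectral peak at {f_peak:.4f} Hz")
print("Each peak lands within one grid step of the injected frequency; the peak")
print("amplitudes differ because wavelet magnitude scales with sqrt(scale).")
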