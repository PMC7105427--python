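"""Quantifying disturbed flow by Reynolds decomposition.

A slow pulsatile velocity trend is contaminated with seeded high-frequency
perturbations of known amplitude; the decomposition splits the signal at a
cutoff of 10 cardiac harmonics and the cycle RMS of the perturbation
recovers the injected amplitude / sqrt(2).
"""

import numpy as np

from graftmetrics import (
    CycleWindow,
    FieldSeries,
    TrendSpec,
    disturbed_velocity_series,
    perturbation_rms,
    reynolds_decompose,
)

window = CycleWindow.uniform(1.0, 257)
t = window.sample_times
trend_signal = 0.6 + 0.25 * np.sin(2 * np.pi * t) + 0.1 * np.cos(4 * np.pi * t)
base = FieldSeries(
    kind="scalar",
    attachment="node",
    values=np.tile(trend_signal[:, None, None], (1, 100, 1)),
    units="m/s",
    window=window,
)

eps = 0.05  # injected perturbation amplitude, m/s
noisy = disturbed_velocity_series(base, eps, perturbation_frequency=40.0, seed=42)

trend, pert = reynolds_decompose(noisy, window, TrendSpec(cutoff_harmonics=10))
rms = perturbation_rms(pert, window)

print(f"injected amplitude        : {eps:.4f} m/s")
print(f"expected cycle RMS        : {eps / np.sqrt(2):.4f} m/s")
print(f"median recovered RMS      : {np.median(rms.values):.4f} m/s")
resid = np.max(np.abs(noisy.scalar_values() - trend.scalar_values() - pert.scalar_values()))
print(f"max additivity residual   : {resid:.2e} m/s")

# The recovered RMS matches eps/sqrt(2) because the perturbation harmonic
# (40/T) lies above the 10-harmonic trend cutoff; content at or below the
# cutoff would be absorbed into the trend instead.
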