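import numpy as np
import pytest

from graftmetrics import CycleWindow, FieldSeries, SurfaceMesh


@pytest.fixture
def unit_window():
    """One 1-second cycle at 1000 uniform samples."""
    return CycleWindow.uniform(1.0, 1000)


@pytest.fixture
def flat_patch():
    """Ten unit-ish right triangles in the z=0 plane, equal areas."""
    pts = []
    tris = []
    for i in range(10):
        x0 = float(i)
        base = len(pts)
        pts += [(x0, 0.0, 0.0), (x0 + 1.0, 0.0, 0.0), (x0, 2.0, 0.0)]
        tris.append((base, base + 1, base + 2))
    return SurfaceMesh(points=np.array(pts), triangles=np.array(tris))


def vector_series(components, window, n_elements=1):
    """Build an element-attached vector3 series from a (n_t, 3) signal."""
    sig = np.asarray(components, dtype=float)
    vals = np.repeat(sig[:, None, :], n_elements, axis=1)
    return FieldSeries(
        kind="vector3", attachment="element", values=vals, units="Pa", window=window
    )


def sin_x_series(window, n_elements=1, amplitude=1.0):
    """tau(t) = (A sin(2 pi t / T), 0, 0)."""
    t = window.sample_times
    sig = np.zeros((window.n_samples, 3))
    sig[:, 0] = amplitude * np.sin(2 * np.pi * (t - window.t_start) / window.period_T)
    return vector_series(sig, window, n_elements)
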