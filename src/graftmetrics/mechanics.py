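"""Wall-mechanics post-processing: von Mises stress, areal strain, pulsatility.

Stress series are symmetric Cauchy tensors stored with 6 components per
element (xx, yy, zz, xy, xz, yz).  The von Mises equivalent stress is
``sqrt(3/2 * tr(sigma_d . sigma_d))`` with ``sigma_d`` the deviatoric part —
the scalar stress an equivalent uniaxial load would produce.

Wall strain is the areal engineering strain ``sqrt((A_n - A_0)/A_0)`` of a
surface element relative to its zero-pressure reference area; it lumps
circumferential and longitudinal stretch into one metric.  For transiently
compressed elements (``A_n < A_0``, where the root is undefined) a signed
extension ``-sqrt((A_0 - A_n)/A_0)`` is used and those entries are flagged.

Pulsatility of any scalar series is the per-element cycle max minus min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CycleWindow, FieldSeries, MetricMap, RegionMask
from .wss import region_median, robust_max


@dataclass
class AreaSeries:
    """Reference areas ``A0`` (m², per element) and deformed areas ``An(t)``."""

    A0: np.ndarray
    An: np.ndarray  # (n_times, n_elements)
    window: CycleWindow

    def __post_init__(self):
        self.A0 = np.asarray(self.A0, dtype=float).ravel()
        self.An = np.asarray(self.An, dtype=float)
        if self.An.ndim != 2 or self.An.shape != (self.window.n_samples, self.A0.size):
            raise ValueError("An must be (n_times, n_elements) matching A0 and window")
        if np.any(self.A0 <= 0) or np.any(self.An <= 0):
            raise ValueError("areas must be positive")


def von_mises(stress: FieldSeries) -> FieldSeries:
    """Von Mises equivalent stress of a symmetric tensor series, in Pa."""
    if stress.kind != "sym_tensor3":
        raise ValueError(f"expected sym_tensor3 series, got {stress.kind}")
    v = stress.values
    if not np.all(np.isfinite(v)):
        t, e, _ = np.argwhere(~np.isfinite(v))[0]
        raise ValueError(f"non-finite stress at time index {t}, element {e}")
    sxx, syy, szz = v[..., 0], v[..., 1], v[..., 2]
    sxy, sxz, syz = v[..., 3], v[..., 4], v[..., 5]
    tr3 = (sxx + syy + szz) / 3.0
    dxx, dyy, dzz = sxx - tr3, syy - tr3, szz - tr3
    # tr(sigma_d . sigma_d) for a symmetric tensor counts off-diagonals twice
    dd = dxx**2 + dyy**2 + dzz**2 + 2.0 * (sxy**2 + sxz**2 + syz**2)
    vm = np.sqrt(1.5 * dd)
    return FieldSeries(
        kind="scalar",
        attachment=stress.attachment,
        values=vm[:, :, None],
        units="Pa",
        window=stress.window,
    )


def engineering_strain(areas: AreaSeries) -> FieldSeries:
    """Areal engineering strain series (dimensionless).

    ``sqrt((An - A0)/A0)`` where the element has grown; the signed extension
    ``-sqrt((A0 - An)/A0)`` where it has shrunk (flagged via a warning — the
    root-based definition only covers expansion).
    """
    rel = (areas.An - areas.A0[None, :]) / areas.A0[None, :]
    eps = np.sign(rel) * np.sqrt(np.abs(rel))
    n_neg = int(np.count_nonzero(rel < 0))
    if n_neg:
        warnings.warn(
            f"{n_neg} element-time samples have An < A0; "
            "signed strain extension applied"
        )
    return FieldSeries(
        kind="scalar",
        attachment="element",
        values=eps[:, :, None],
        units="",
        window=areas.window,
    )


def pulsatility(series: FieldSeries, window: CycleWindow) -> MetricMap:
    """Cycle max minus min per element of a scalar series (always >= 0)."""
    vals = series.scalar_values()
    out = vals.max(axis=0) - vals.min(axis=0)
    return MetricMap(
        values=out,
        units=series.units,
        metric_name=f"pulsatility",
        window=window,
    )


def time_average(series: FieldSeries, window: CycleWindow) -> MetricMap:
    """Trapezoidal cycle average per element of a scalar series."""
    w = window.trapezoid_weights()
    vals = (w @ series.scalar_values()) / window.period_T
    return MetricMap(
        values=vals, units=series.units, metric_name="time_average", window=window
    )


def mechanics_report(
    stress: FieldSeries | None,
    strain: FieldSeries | None,
    regions: dict[str, RegionMask],
    omit_area_fraction: float = 0.01,
    area_weighted: bool = True,
) -> pd.DataFrame:
    """Regional stress/strain summary table.

    For each region and each supplied quantity (von Mises stress in kPa,
    areal strain in %), reports the area-weighted median and robust maximum
    of the cycle-averaged map, and the median and robust maximum of the
    per-element pulsatility map.  The robust maximum discards the
    highest-valued elements holding the top ``omit_area_fraction`` of region
    area.

    Columns: region, quantity, median, median_pulsatility, robust_max,
    max_pulsatility, units.
    """
    quantities = []
    if stress is not None:
        vm = von_mises(stress) if stress.kind == "sym_tensor3" else stress
        quantities.append(("von_mises_stress", vm, 1e-3, "kPa"))
    if strain is not None:
        quantities.append(("strain", strain, 100.0, "%"))
    if not quantities:
        raise ValueError("at least one of stress/strain is required")

    rows = []
    for region_name, region in regions.items():
        if region.is_empty:
            raise ValueError(f"region {region_name!r} is empty")
        for qname, series, scale, units in quantities:
            window = series.window
            avg = time_average(series, window)
            puls = pulsatility(series, window)
            rows.append(
                {
                    "region": region_name,
                    "quantity": qname,
                    "median": scale * region_median(avg, region, area_weighted),
                    "median_pulsatility": scale
                    * region_median(puls, region, area_weighted),
                    "robust_max": scale * robust_max(avg, region, omit_area_fraction),
                    "max_pulsatility": scale
                    * robust_max(puls, region, omit_area_fraction),
                    "units": units,
                }
            )
    return pd.DataFrame(rows)
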