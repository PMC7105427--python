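"""Regions of interest and comparative reports across graft-material cases.

The anastomotic region of interest is the set of wall elements inside a
sphere around the junction (default radius 1.2 cm); graft and vein segments
are labelled by nearest-centreline-segment assignment relative to a
transition landmark.  Membership is decided by element centroid, which keeps
region areas consistent with the area-weighted statistics downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Centreline, FieldSeries, RegionMask, SurfaceMesh
from .mechanics import AreaSeries, engineering_strain, mechanics_report, von_mises
from .wss import (
    DEFAULT_THRESHOLDS,
    ThresholdSpec,
    area_fraction,
    compute_osi,
    compute_tawss,
    compute_wss_max,
)


@dataclass(frozen=True)
class SphereROI:
    """Spherical anastomotic region of interest (radius default 1.2 cm)."""

    center: tuple[float, float, float]
    radius: float = 0.012

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


def sphere_region(mesh: SurfaceMesh, roi: SphereROI) -> RegionMask:
    """Elements whose centroid lies strictly inside the sphere."""
    d = np.linalg.norm(mesh.element_centroid - np.asarray(roi.center, dtype=float), axis=1)
    ids = np.flatnonzero(d < roi.radius)
    if ids.size == 0:
        warnings.warn("sphere ROI contains no element centroids; empty mask returned")
    return RegionMask(element_ids=ids, label="anastomosis", mesh=mesh)


def label_segments(
    mesh: SurfaceMesh, centreline: Centreline, transition_landmark: str = "transition"
) -> dict[str, RegionMask]:
    """Partition wall elements into graft and vein by nearest centreline point.

    The centreline must carry a landmark marking the graft-vein transition
    arclength; each element is assigned to the side of the transition on
    which its nearest centreline point falls.  The two masks are disjoint and
    cover the mesh.
    """
    if transition_landmark not in centreline.landmarks:
        raise KeyError(
            f"centreline has no {transition_landmark!r} landmark; "
            f"available: {sorted(centreline.landmarks)}"
        )
    s_cut = centreline.landmarks[transition_landmark]

    p0 = centreline.points[:-1]
    seg = np.diff(centreline.points, axis=0)
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    c = mesh.element_centroid
    # distance from every centroid to every segment, clamped to endpoints
    w = c[:, None, :] - p0[None, :, :]
    t = np.clip(np.einsum("esj,sj->es", w, seg) / seg_len2[None, :], 0.0, 1.0)
    foot = p0[None, :, :] + t[..., None] * seg[None, :, :]
    dist2 = np.einsum("esj,esj->es", c[:, None, :] - foot, c[:, None, :] - foot)
    nearest_seg = np.argmin(dist2, axis=1)
    s_star = centreline.arclength[nearest_seg] + t[
        np.arange(len(c)), nearest_seg
    ] * np.sqrt(seg_len2[nearest_seg])

    graft_ids = np.flatnonzero(s_star < s_cut)
    vein_ids = np.flatnonzero(s_star >= s_cut)
    masks = {
        "graft": RegionMask(element_ids=graft_ids, label="graft", mesh=mesh),
        "vein": RegionMask(element_ids=vein_ids, label="vein", mesh=mesh),
    }
    assert masks["graft"].n_elements + masks["vein"].n_elements == mesh.n_elements
    return masks


@dataclass
class CaseInputs:
    """Per-case field bundle feeding a comparative report."""

    mesh: SurfaceMesh
    wss: FieldSeries  # vector3, element-attached
    stress: FieldSeries | None = None  # sym_tensor3 or scalar von Mises
    areas: AreaSeries | None = None


def build_report(
    cases: dict[str, CaseInputs],
    regions: dict[str, RegionMask],
    thresholds: tuple[ThresholdSpec, ...] = DEFAULT_THRESHOLDS,
    omit_area_fraction: float = 0.01,
) -> pd.DataFrame:
    """Exceedance and mechanics summary across cases and regions.

    For every case x region the report holds one row per WSS threshold
    (area-percent of the region beyond the bound) and, where stress/area
    series are supplied, the regional stress and strain statistics.  Rows are
    emitted in a fixed (case, region, metric) order so the serialised CSV is
    byte-identical across reruns.
    """
    ref_mesh = None
    rows = []
    for case_name in sorted(cases):
        case = cases[case_name]
        if ref_mesh is None:
            ref_mesh = case.mesh
        elif case.mesh.n_elements != ref_mesh.n_elements or not np.array_equal(
            case.mesh.triangles, ref_mesh.triangles
        ):
            raise ValueError(
                f"case {case_name!r} uses a different mesh than the other cases"
            )
        window = case.wss.window
        maps = {
            "TAWSS": compute_tawss(case.wss, window),
            "WSS_max": compute_wss_max(case.wss, window),
            "OSI": compute_osi(case.wss, window),
        }
        for region_name in sorted(regions):
            region = regions[region_name]
            for th in thresholds:
                rows.append(
                    {
                        "case": case_name,
                        "region": region_name,
                        "metric": th.label,
                        "value": area_fraction(maps[th.metric_name], th, region),
                        "units": "%",
                    }
                )
        if case.stress is not None or case.areas is not None:
            stress = case.stress
            strain = engineering_strain(case.areas) if case.areas is not None else None
            mech = mechanics_report(
                stress, strain, dict(sorted(regions.items())), omit_area_fraction
            )
            for _, r in mech.iterrows():
                for stat in ("median", "median_pulsatility", "robust_max", "max_pulsatility"):
                    rows.append(
                        {
                            "case": case_name,
                            "region": r["region"],
                            "metric": f"{stat} {r['quantity']}",
                            "value": r[stat],
                            "units": r["units"],
                        }
                    )
    report = pd.DataFrame(rows, columns=["case", "region", "metric", "value", "units"])
    dup = report.duplicated(subset=["case", "region", "metric"])
    if dup.any():
        raise ValueError("duplicate (case, region, metric) cells in report")
    return report
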