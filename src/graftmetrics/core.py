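"""Core spatial and temporal containers.

Every downstream metric operates on these types: triangulated wall surfaces
(:class:`SurfaceMesh`), tetrahedral flow domains (:class:`VolumeMesh`), the
analysed cardiac cycle (:class:`CycleWindow`), time-resolved fields attached
to mesh nodes or elements (:class:`FieldSeries`), vessel centrelines
(:class:`Centreline`) and element subsets (:class:`RegionMask`).

Units are strictly SI internally: metres, seconds, pascals.  Pressures in
mmHg are converted at the interface with 1 mmHg = 133.322 Pa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

MMHG_TO_PA = 133.322

_KIND_NCOMP = {"scalar": 1, "vector3": 3, "sym_tensor3": 6}


def mmhg(p: float) -> float:
    """Convert a pressure from mmHg to Pa."""
    return p * MMHG_TO_PA


@dataclass(frozen=True)
class CycleWindow:
    """The analysed cardiac cycle ``[t_start, t_start + period_T]``.

    ``sample_times`` are the (possibly non-uniform) instants at which fields
    are stored; they must start at ``t_start``, end at ``t_start + period_T``
    and be strictly increasing.  All time integrals downstream use the
    trapezoidal rule on these actual sample times.
    """

    t_start: float
    period_T: float
    sample_times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        object.__setattr__(self, "sample_times", t)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("a cycle window needs at least 3 sample times")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if abs(t[0] - self.t_start) > 1e-9:
            raise ValueError("sample_times[0] must equal t_start")
        if abs(t[-1] - (self.t_start + self.period_T)) > 1e-9:
            raise ValueError("sample_times[-1] must equal t_start + period_T")

    @property
    def n_samples(self) -> int:
        return self.sample_times.size

    @classmethod
    def uniform(cls, period_T: float, n_samples: int, t_start: float = 0.0) -> "CycleWindow":
        """A window with ``n_samples`` equispaced instants spanning one cycle."""
        t = np.linspace(t_start, t_start + period_T, n_samples)
        return cls(t_start=t_start, period_T=period_T, sample_times=t)

    def trapezoid_weights(self) -> np.ndarray:
        """Quadrature weights w such that sum(w * f(t_i)) = trapezoid(f)."""
        dt = np.diff(self.sample_times)
        w = np.zeros_like(self.sample_times)
        w[:-1] += 0.5 * dt
        w[1:] += 0.5 * dt
        return w


def _triangle_geometry(points: np.ndarray, triangles: np.ndarray):
    p0 = points[triangles[:, 0]]
    p1 = points[triangles[:, 1]]
    p2 = points[triangles[:, 2]]
    cross = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(cross, axis=1)
    area = 0.5 * norm
    with np.errstate(invalid="ignore", divide="ignore"):
        normal = cross / norm[:, None]
    centroid = (p0 + p1 + p2) / 3.0
    return area, centroid, normal


@dataclass
class SurfaceMesh:
    """Triangulated wall surface: the substrate for all WSS and stress maps.

    ``points`` is (n_nodes, 3) in metres, ``triangles`` (n_elem, 3) 0-based.
    Per-element areas, centroids and unit normals are computed on
    construction and cached.
    """

    points: np.ndarray
    triangles: np.ndarray
    element_area: np.ndarray = field(init=False, repr=False)
    element_centroid: np.ndarray = field(init=False, repr=False)
    element_normal: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if self.triangles.size and self.triangles.max() >= len(self.points):
            raise ValueError("triangle node index out of range")
        if self.triangles.size and self.triangles.min() < 0:
            raise ValueError("negative node index")
        area, centroid, normal = _triangle_geometry(self.points, self.triangles)
        if np.any(area <= 0):
            bad = int(np.argmin(area))
            raise ValueError(f"degenerate triangle (zero area) at element {bad}")
        self.element_area = area
        self.element_centroid = centroid
        self.element_normal = normal

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    @property
    def total_area(self) -> float:
        return float(self.element_area.sum())

    def all_elements_mask(self, label: str = "custom") -> "RegionMask":
        return RegionMask(element_ids=np.arange(self.n_elements), label=label, mesh=self)


@dataclass
class VolumeMesh:
    """Tetrahedral flow domain.  Tets are reoriented on load so volumes > 0."""

    points: np.ndarray
    tets: np.ndarray
    element_volume: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be (m, 4)")
        if self.tets.size and self.tets.max() >= len(self.points):
            raise ValueError("tet node index out of range")
        vol = self._signed_volumes()
        flip = vol < 0
        if np.any(flip):
            self.tets[flip] = self.tets[flip][:, [0, 2, 1, 3]]
            vol = np.abs(vol)
        if np.any(vol == 0):
            raise ValueError("degenerate tetrahedron (zero volume)")
        self.element_volume = vol

    def _signed_volumes(self) -> np.ndarray:
        p = self.points
        a, b, c, d = (p[self.tets[:, i]] for i in range(4))
        return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_elements(self) -> int:
        return len(self.tets)


@dataclass
class Centreline:
    """Ordered vessel centreline with cumulative arclength and named landmarks.

    ``landmarks`` maps names (e.g. ``"transition"``) to arclength positions in
    metres along the polyline.
    """

    points: np.ndarray
    landmarks: dict[str, float] = field(default_factory=dict)
    arclength: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("centreline needs >= 2 points of shape (n, 3)")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centreline has coincident consecutive points")
        self.arclength = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Linear interpolation of position at arclength ``s``."""
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.arclength, s, side="right")) - 1
        i = min(max(i, 0), len(self.points) - 2)
        ds = self.arclength[i + 1] - self.arclength[i]
        w = (s - self.arclength[i]) / ds
        return (1 - w) * self.points[i] + w * self.points[i + 1]

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent of the containing segment at arclength ``s``."""
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.arclength, s, side="right")) - 1
        i = min(max(i, 0), len(self.points) - 2)
        d = self.points[i + 1] - self.points[i]
        return d / np.linalg.norm(d)


@dataclass
class RegionMask:
    """Subset of surface elements (graft / vein / anastomosis / custom)."""

    element_ids: np.ndarray
    label: str
    mesh: SurfaceMesh

    def __post_init__(self):
        ids = np.asarray(self.element_ids, dtype=np.int64).ravel()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate element ids in region mask")
        if ids.size and (ids.min() < 0 or ids.max() >= self.mesh.n_elements):
            raise ValueError("element id out of range")
        self.element_ids = np.sort(ids)

    @property
    def n_elements(self) -> int:
        return self.element_ids.size

    @property
    def total_area(self) -> float:
        return float(self.mesh.element_area[self.element_ids].sum())

    @property
    def is_empty(self) -> bool:
        return self.element_ids.size == 0


@dataclass
class FieldSeries:
    """A time-sampled scalar / vector / symmetric-tensor field on a mesh.

    ``values`` has shape (n_times, n_entities, n_components) with component
    counts 1, 3 or 6 (tensor order: xx, yy, zz, xy, xz, yz).  ``attachment``
    says whether entities are mesh nodes or elements.
    """

    kind: Literal["scalar", "vector3", "sym_tensor3"]
    attachment: Literal["node", "element"]
    values: np.ndarray
    units: str
    window: CycleWindow

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if self.kind not in _KIND_NCOMP:
            raise ValueError(f"unknown field kind {self.kind!r}")
        ncomp = _KIND_NCOMP[self.kind]
        if v.ndim == 2 and ncomp == 1:
            v = v[:, :, None]
        if v.ndim != 3 or v.shape[2] != ncomp:
            raise ValueError(
                f"values must be (n_times, n_entities, {ncomp}) for kind {self.kind!r}"
            )
        if v.shape[0] != self.window.n_samples:
            raise ValueError(
                f"{v.shape[0]} value arrays for {self.window.n_samples} sample times"
            )
        self.values = v

    @property
    def n_entities(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def magnitude(self) -> np.ndarray:
        """Euclidean norm per time and entity; shape (n_times, n_entities)."""
        if self.kind == "scalar":
            return np.abs(self.values[:, :, 0])
        if self.kind == "vector3":
            return np.linalg.norm(self.values, axis=2)
        raise ValueError("magnitude of a tensor series is not defined; use von_mises")

    def scalar_values(self) -> np.ndarray:
        if self.kind != "scalar":
            raise ValueError(f"expected a scalar series, got {self.kind}")
        return self.values[:, :, 0]


@dataclass
class MetricMap:
    """Per-element (or per-node) scalar result with units and provenance."""

    values: np.ndarray
    units: str
    metric_name: str
    window: CycleWindow | None = None
    flagged: np.ndarray | None = None  # boolean mask of degenerate entries

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.flagged is not None:
            self.flagged = np.asarray(self.flagged, dtype=bool).ravel()
            if self.flagged.shape != self.values.shape:
                raise ValueError("flag mask shape mismatch")

    def __len__(self) -> int:
        return self.values.size


def node_to_element(series: FieldSeries, mesh: SurfaceMesh | VolumeMesh) -> FieldSeries:
    """Average a node-attached series onto elements (unweighted vertex mean).

    A series that is already element-attached is returned unchanged with a
    warning.
    """
    if series.attachment == "element":
        warnings.warn("series is already element-attached; returning as is")
        return series
    conn = mesh.triangles if isinstance(mesh, SurfaceMesh) else mesh.tets
    if series.n_entities != mesh.n_nodes:
        raise ValueError(
            f"series has {series.n_entities} nodes but mesh has {mesh.n_nodes}"
        )
    # (n_times, n_elem, n_vertices, n_comp) -> mean over vertices
    vals = series.values[:, conn, :].mean(axis=2)
    return FieldSeries(
        kind=series.kind,
        attachment="element",
        values=vals,
        units=series.units,
        window=series.window,
    )
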