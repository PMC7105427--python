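"""Synthetic meshes, waveforms and fields with analytically known metrics.

Patient-specific fluid–structure-interaction output is cluster-scale and
not redistributable, so every downstream stage is validated against
closed-form tube flows instead:

* quasi-steady Poiseuille wall shear on a cylinder,
  ``|tau|(t) = 4 mu Q(t) / (pi r^3)``, which gives exact TAWSS/OSI for any
  prescribed inflow waveform;
* a two-phase reversing shear signal whose oscillatory shear index is an
  exact function of the forward fraction of the cycle;
* Laplace-law wall stress of a pressurised thin-walled tube
  (``sigma_theta = p r / h``, ``sigma_z = p r / 2h``), with element areas
  scaled by the linear-elastic hoop strain ``p r / (E h)``;
* seeded high-frequency velocity perturbations with known cycle RMS;
* an idealized end-to-side graft–vein anastomosis surface with ground-truth
  region labels.

Default dimensions and fluid constants follow the arteriovenous-graft
setting: 6 mm zero-pressure graft diameter, 7.14 mm vein diameter, vein wall
thickness 10% of its radius, 0.63 mm graft wall, blood viscosity
4.5e-3 Pa s, density 1000 kg/m^3, venous pressure ~50 mmHg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Centreline, CycleWindow, FieldSeries, RegionMask, SurfaceMesh


@dataclass(frozen=True)
class TubeSpec:
    """Geometry of a straight circular tube at zero transmural pressure."""

    radius_zero_pressure: float
    length: float
    wall_thickness: float
    n_circ: int = 32
    n_axial: int = 40

    def __post_init__(self):
        if min(self.radius_zero_pressure, self.length, self.wall_thickness) <= 0:
            raise ValueError("radius, length and wall thickness must be positive")
        if self.n_circ < 8:
            raise ValueError("n_circ must be >= 8")
        if self.n_axial < 1:
            raise ValueError("n_axial must be >= 1")


@dataclass(frozen=True)
class FluidSpec:
    """Newtonian blood model (defaults: mu = 4.5e-3 Pa s, rho = 1000 kg/m^3)."""

    dynamic_viscosity: float = 4.5e-3
    density: float = 1000.0

    def __post_init__(self):
        if self.dynamic_viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")


@dataclass(frozen=True)
class WaveformSpec:
    """Pulsatile inflow ``Q(t) = mean + sum_k a_k sin(2 pi k t / T + phi_k)``.

    A parametric stand-in for a measured dialysis-graft inflow: strictly
    positive (no retrograde graft flow), with the default harmonics giving a
    systolic peak of roughly twice the cycle mean.
    """

    mean_flow: float = 1e-5  # 600 ml/min, typical functioning graft flow
    period_T: float = 1.0
    harmonics: Sequence[tuple[float, float]] = ((4e-6, 0.0), (1.5e-6, np.pi / 3))

    def __post_init__(self):
        if self.mean_flow <= 0 or self.period_T <= 0:
            raise ValueError("mean flow and period must be positive")
        t = np.linspace(0.0, self.period_T, 2048)
        if np.any(self.evaluate(t) <= 0):
            raise ValueError("waveform must be strictly positive (retrograde flow)")

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        q = np.full_like(t, self.mean_flow)
        for k, (amp, phase) in enumerate(self.harmonics, start=1):
            q = q + amp * np.sin(2.0 * np.pi * k * t / self.period_T + phase)
        return q


#: Constants of the modelled graft-vein system.
GRAFT_D0 = 6.0e-3
VEIN_D0 = 7.14e-3
GRAFT_WALL = 0.63e-3
VEIN_WALL = 0.1 * VEIN_D0 / 2  # 10% of the pre-operative vein radius
VENOUS_PRESSURE_MMHG = 50.0


def default_graft_tube(**kw) -> TubeSpec:
    return TubeSpec(GRAFT_D0 / 2, 0.03, GRAFT_WALL, **kw)


def default_vein_tube(**kw) -> TubeSpec:
    return TubeSpec(VEIN_D0 / 2, 0.075, VEIN_WALL, **kw)


def make_tube_surface(
    spec: TubeSpec,
    origin=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
) -> tuple[SurfaceMesh, Centreline]:
    """Structured triangulated cylinder wall plus its axial centreline.

    The mesh has ``n_circ * n_axial`` quads split into triangles; its total
    area converges to ``2 pi r L`` with circumferential refinement.
    """
    origin = np.asarray(origin, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    nc, na, r = spec.n_circ, spec.n_axial, spec.radius_zero_pressure
    theta = 2.0 * np.pi * np.arange(nc) / nc
    ring = r * (np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2))
    z = spec.length * np.arange(na + 1) / na
    points = (origin[None, :] + z[:, None, None] * axis[None, None, :] + ring[None, :, :]).reshape(
        -1, 3
    )

    tris = []
    for ia in range(na):
        base0 = ia * nc
        base1 = (ia + 1) * nc
        for ic in range(nc):
            icn = (ic + 1) % nc
            a, b = base0 + ic, base0 + icn
            c, d = base1 + ic, base1 + icn
            tris.append((a, b, c))
            tris.append((b, d, c))
    mesh = SurfaceMesh(points=points, triangles=np.array(tris, dtype=np.int64))
    cl_pts = origin[None, :] + np.linspace(0, spec.length, na + 1)[:, None] * axis[None, :]
    return mesh, Centreline(points=cl_pts)


def poiseuille_wss_series(
    spec: TubeSpec,
    waveform: WaveformSpec,
    fluid: FluidSpec = FluidSpec(),
    n_samples: int = 65,
    axis=(0.0, 0.0, 1.0),
) -> tuple[SurfaceMesh, FieldSeries]:
    """Quasi-steady Poiseuille wall shear on a tube, element-attached.

    At every instant the WSS vector points along the tube axis with uniform
    magnitude ``4 mu Q(t) / (pi r^3)`` — the exact steady-flow value for the
    instantaneous flow rate, which makes every WSS metric downstream a closed
    form of the waveform.
    """
    mesh, _ = make_tube_surface(spec, axis=axis)
    window = CycleWindow.uniform(waveform.period_T, n_samples)
    q = waveform.evaluate(window.sample_times)
    mag = 4.0 * fluid.dynamic_viscosity * q / (np.pi * spec.radius_zero_pressure**3)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    vals = mag[:, None, None] * axis[None, None, :] * np.ones((1, mesh.n_elements, 1))
    series = FieldSeries(
        kind="vector3", attachment="element", values=vals, units="Pa", window=window
    )
    return mesh, series


def prescribed_osi_wss_series(
    target_osi: float,
    magnitude: float,
    window: CycleWindow,
    n_elements: int = 1,
    axis=(1.0, 0.0, 0.0),
) -> FieldSeries:
    """Axial WSS signal whose OSI (trapezoid-integrated) equals the target.

    The signal is forward at ``+magnitude`` for a fraction f of the cycle and
    reversed at ``-magnitude`` for the rest, with ``f`` solved from the index
    identity OSI = (1 - |2f - 1|)/2.  The reversal is realised as a short
    linear ramp (half-width T * 1e-9) whose knots are inserted into the
    sample times, so the trapezoidal rule integrates the piecewise-linear
    signal exactly and the returned series reproduces the target to
    round-off.
    """
    if not 0.0 <= target_osi <= 0.5:
        raise ValueError("target OSI must lie in [0, 0.5]")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    T, t0 = window.period_T, window.t_start
    delta = T * 1e-9

    if target_osi < 2.0 * delta / T:  # steady forward flow
        vals = magnitude * np.ones((window.n_samples, n_elements, 1)) * axis[None, None, :]
        return FieldSeries(
            kind="vector3", attachment="element", values=vals, units="Pa", window=window
        )

    # forward fraction from the exact quadrature identity of the ramped signal
    f = 0.5 * (1.0 + (1.0 - 2.0 * target_osi) * (T - delta) / T)
    t_break = t0 + f * T
    knots = np.array([t_break - delta, t_break, t_break + delta])
    times = np.unique(np.concatenate([window.sample_times, knots]))
    times = times[np.concatenate([[True], np.diff(times) > delta / 100])]
    for k in knots:  # the knots themselves must survive the merge
        if not np.any(np.abs(times - k) < delta / 100):
            times = np.sort(np.append(times, k))
    new_window = CycleWindow(t_start=t0, period_T=T, sample_times=times)

    scalar = np.where(
        times <= t_break - delta,
        magnitude,
        np.where(
            times >= t_break + delta,
            -magnitude,
            magnitude * (t_break - times) / delta,
        ),
    )
    vals = scalar[:, None, None] * axis[None, None, :] * np.ones((1, n_elements, 1))
    return FieldSeries(
        kind="vector3", attachment="element", values=vals, units="Pa", window=new_window
    )


def pressurised_tube_stress_series(
    spec: TubeSpec,
    pressure_values: np.ndarray,
    window: CycleWindow,
    youngs_modulus: float | None = None,
    axis=(0.0, 0.0, 1.0),
):
    """Laplace-law wall stress of a thin pressurised tube.

    Per element the stress state is hoop ``sigma_theta = p r / h`` along the
    circumferential direction, axial ``sigma_z = p r / 2h`` along the tube
    axis and zero radially, rotated into global coordinates.  When a Young's
    modulus is supplied, element areas are scaled with the linear-elastic
    hoop strain ``p r / (E h)`` so the areal strain metric has a closed form.

    Returns ``(mesh, stress_series, area_series)``.
    """
    from .mechanics import AreaSeries

    p = np.asarray(pressure_values, dtype=float)
    if p.shape != (window.n_samples,):
        raise ValueError("pressure_values must match the window's sample count")
    r, h = spec.radius_zero_pressure, spec.wall_thickness
    if h / r > 0.2:
        warnings.warn(f"h/r = {h / r:.2f} exceeds the thin-wall range; computed anyway")

    mesh, _ = make_tube_surface(spec, axis=axis)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # per-element circumferential direction: axis x radial
    radial = mesh.element_centroid - np.outer(mesh.element_centroid @ axis, axis)
    radial /= np.linalg.norm(radial, axis=1)[:, None]
    hoop = np.cross(axis[None, :], radial)

    s_theta = p * r / h  # (n_t,)
    s_z = p * r / (2.0 * h)
    # sigma = s_theta * hoop x hoop + s_z * axis x axis, per element and time
    hh = np.einsum("ei,ej->eij", hoop, hoop)
    zz = np.einsum("i,j->ij", axis, axis)
    sigma = s_theta[:, None, None, None] * hh[None] + s_z[:, None, None, None] * zz[None, None]
    comps = np.stack(
        [
            sigma[..., 0, 0],
            sigma[..., 1, 1],
            sigma[..., 2, 2],
            sigma[..., 0, 1],
            sigma[..., 0, 2],
            sigma[..., 1, 2],
        ],
        axis=-1,
    )
    stress = FieldSeries(
        kind="sym_tensor3", attachment="element", values=comps, units="Pa", window=window
    )

    A0 = mesh.element_area
    if youngs_modulus is not None:
        eps_hoop = p * r / (youngs_modulus * h)
        An = A0[None, :] * (1.0 + eps_hoop[:, None])
    else:
        An = np.tile(A0, (window.n_samples, 1))
    areas = AreaSeries(A0=A0, An=An, window=window)
    return mesh, stress, areas


def disturbed_velocity_series(
    base: FieldSeries,
    perturbation_amplitude: float,
    perturbation_frequency: float,
    seed: int,
    trend_cutoff_harmonics: int = 10,
) -> FieldSeries:
    """Add a seeded high-frequency sinusoid to a scalar velocity series.

    Each point receives ``eps * sin(2 pi f t + phi(x))`` with an independent
    uniform random phase, emulating transitional velocity perturbations whose
    cycle RMS is ``eps / sqrt(2)``.  The perturbation frequency must exceed
    the trend cutoff, otherwise a Fourier-truncation trend would absorb it.
    """
    window = base.window
    cutoff_hz = trend_cutoff_harmonics / window.period_T
    if perturbation_frequency <= cutoff_hz:
        raise ValueError(
            f"perturbation frequency {perturbation_frequency:g} Hz is not above the "
            f"trend cutoff {cutoff_hz:g} Hz; it would be absorbed into the trend"
        )
    u = base.scalar_values()
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=u.shape[1])
    t = window.sample_times[:, None]
    pert = perturbation_amplitude * np.sin(2.0 * np.pi * perturbation_frequency * t + phi[None, :])
    return FieldSeries(
        kind="scalar",
        attachment=base.attachment,
        values=(u + pert)[:, :, None],
        units=base.units,
        window=window,
    )


@dataclass
class AnastomosisSurface:
    """Idealized end-to-side graft–vein junction with ground-truth labels."""

    mesh: SurfaceMesh
    regions: dict[str, RegionMask]
    junction: np.ndarray
    centreline: Centreline  # graft inlet -> junction -> venous outlet


def make_anastomosis_surface(
    graft_spec: TubeSpec,
    vein_spec: TubeSpec,
    angle: float = np.pi / 4,
    anastomosis_radius: float = 0.012,
    junction_fraction: float = 1.0 / 3.0,
    suture_margin: float = 1.0e-3,
) -> AnastomosisSurface:
    """End-to-side junction of a graft tube onto a vein tube.

    The vein runs along +z; the graft meets the vein axis at
    ``junction_fraction`` of the venous length, inclined at ``angle`` to the
    vein axis.  Wall elements of either tube lying inside the other, plus a
    ``suture_margin`` collar around the opening where the two idealized tubes
    interpenetrate, are removed — the union is not watertight there and those
    strips belong to neither wall.  Ground-truth region masks: ``graft`` and
    ``vein`` partition the surface; ``anastomosis`` holds the elements whose
    centroid lies within ``anastomosis_radius`` of the junction.
    """
    if angle <= 1e-6 or angle > np.pi / 2:
        raise ValueError("anastomosis angle must lie in (0, pi/2]")
    vein_mesh, _ = make_tube_surface(vein_spec)
    zj = junction_fraction * vein_spec.length
    junction = np.array([0.0, 0.0, zj])
    d = np.array([np.sin(angle), 0.0, np.cos(angle)])
    graft_mesh, _ = make_tube_surface(graft_spec, origin=junction, axis=d)

    # anastomotic opening: drop each wall where it lies inside (or within the
    # suture collar of) the other tube
    inside_vein = (
        np.linalg.norm(graft_mesh.element_centroid[:, :2], axis=1)
        < vein_spec.radius_zero_pressure + suture_margin
    )
    keep_graft = ~inside_vein
    vc = vein_mesh.element_centroid - junction
    t_v = vc @ d
    perp = np.linalg.norm(vc - np.outer(t_v, d), axis=1)
    inside_graft = (perp < graft_spec.radius_zero_pressure + suture_margin) & (
        t_v > -graft_spec.radius_zero_pressure
    )
    keep_vein = ~inside_graft

    def _submesh(mesh, keep):
        tris = mesh.triangles[keep]
        used = np.unique(tris)
        remap = -np.ones(mesh.n_nodes, dtype=np.int64)
        remap[used] = np.arange(used.size)
        return mesh.points[used], remap[tris]

    gp, gt = _submesh(graft_mesh, keep_graft)
    vp, vt = _submesh(vein_mesh, keep_vein)
    points = np.vstack([gp, vp])
    tris = np.vstack([gt, vt + len(gp)])
    mesh = SurfaceMesh(points=points, triangles=tris)

    n_graft = len(gt)
    graft_ids = np.arange(n_graft)
    vein_ids = np.arange(n_graft, mesh.n_elements)
    dist_j = np.linalg.norm(mesh.element_centroid - junction, axis=1)
    regions = {
        "graft": RegionMask(element_ids=graft_ids, label="graft", mesh=mesh),
        "vein": RegionMask(element_ids=vein_ids, label="vein", mesh=mesh),
        "anastomosis": RegionMask(
            element_ids=np.flatnonzero(dist_j < anastomosis_radius),
            label="anastomosis",
            mesh=mesh,
        ),
    }
    # Labelling centreline: graft inlet -> wall-entry point -> vein axis ->
    # venous outlet, with the graft-vein transition at the wall entry.  Ending
    # the graft leg at the vein wall (not the axis) keeps the graft axis'
    # "shadow" on the vein wall from being mislabelled graft.
    inlet = junction + graft_spec.length * d
    wall_entry = junction + vein_spec.radius_zero_pressure * d
    graft_leg = inlet[None, :] + np.linspace(0, 1, 16)[:, None] * (wall_entry - inlet)[None, :]
    vein_leg = np.column_stack(
        [
            np.zeros(15),
            np.zeros(15),
            np.linspace(zj, vein_spec.length, 16)[1:],
        ]
    )
    cl_points = np.vstack([graft_leg, junction[None, :], vein_leg])
    s_cut = graft_spec.length - vein_spec.radius_zero_pressure
    centreline = Centreline(points=cl_points, landmarks={"transition": s_cut})
    return AnastomosisSurface(mesh=mesh, regions=regions, junction=junction, centreline=centreline)
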