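"""Material parameters, tube law and compliance-mismatch utilities.

Vessel walls are characterised by a single linearised Young's modulus and a
thin-wall (Laplace) tube law: hoop stress ``sigma_theta = p r / h``, hoop
strain ``p r / (E h)`` and the linear pressure-diameter relation

    d(p) = d0 * (1 + p * r0 / (E * h)),       r0 = d0 / 2.

Shipped moduli: cephalic vein 0.445 MPa (stress-strain behaviour linearised
over the 30-60 mmHg post-operative working range), ePTFE graft 55 MPa, ePU
graft 1.5 MPa.  The vein-vs-graft difference in dA/dp under this law is the
compliance mismatch implicated in disturbed anastomotic flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MMHG_TO_PA
from .synthetic import TubeSpec


@dataclass(frozen=True)
class MaterialSpec:
    """Wall material: Young's modulus plus wall thickness.

    Thickness may be absolute (``wall_thickness``, m) or relative to the
    zero-pressure radius (``thickness_ratio`` = h / r0); exactly one must be
    given.
    """

    name: str
    youngs_modulus: float
    wall_thickness: float | None = None
    thickness_ratio: float | None = None

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if (self.wall_thickness is None) == (self.thickness_ratio is None):
            raise ValueError("give exactly one of wall_thickness / thickness_ratio")
        if self.wall_thickness is not None and self.wall_thickness <= 0:
            raise ValueError("wall thickness must be positive")
        if self.thickness_ratio is not None and self.thickness_ratio <= 0:
            raise ValueError("thickness ratio must be positive")

    def thickness_for(self, r0: float) -> float:
        if self.wall_thickness is not None:
            return self.wall_thickness
        return self.thickness_ratio * r0


#: Default registry of the modelled graft-vein system.
MATERIALS: dict[str, MaterialSpec] = {
    "vein": MaterialSpec("vein", youngs_modulus=0.445e6, thickness_ratio=0.1),
    "ePTFE": MaterialSpec("ePTFE", youngs_modulus=55e6, wall_thickness=0.63e-3),
    "ePU": MaterialSpec("ePU", youngs_modulus=1.5e6, wall_thickness=0.63e-3),
}

#: Default zero-pressure diameters (m).
DIAMETERS: dict[str, float] = {"vein": 7.14e-3, "ePTFE": 6.0e-3, "ePU": 6.0e-3}


@dataclass(frozen=True)
class StressStrainCurve:
    """Piecewise-linear stress-strain data with strictly increasing strain."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        eps = np.asarray(self.strain, dtype=float)
        sig = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", eps)
        object.__setattr__(self, "stress", sig)
        if eps.size < 2 or eps.shape != sig.shape:
            raise ValueError("curve needs >= 2 (strain, stress) pairs")
        if np.any(np.diff(eps) <= 0):
            raise ValueError("strain values must be strictly increasing")

    def strain_at_stress(self, sigma: float) -> float:
        """Inverse interpolation (requires monotone stress)."""
        if np.any(np.diff(self.stress) <= 0):
            raise ValueError("stress must be strictly increasing for inversion")
        if not (self.stress[0] <= sigma <= self.stress[-1]):
            raise ValueError(
                f"stress {sigma:g} Pa outside the curve's span "
                f"[{self.stress[0]:g}, {self.stress[-1]:g}] Pa"
            )
        return float(np.interp(sigma, self.stress, self.strain))


def linearise_modulus(
    curve: StressStrainCurve,
    pressure_range: tuple[float, float],
    tube: TubeSpec,
) -> float:
    """Effective Young's modulus over a transmural-pressure working range.

    The pressure range is mapped to hoop stresses via the Laplace law
    ``sigma = p r / h`` for the given tube; the least-squares slope of the
    stress-strain curve restricted to that stress interval (endpoints
    interpolated linearly) is returned.
    """
    p_lo, p_hi = sorted(pressure_range)
    r, h = tube.radius_zero_pressure, tube.wall_thickness
    s_lo, s_hi = p_lo * r / h, p_hi * r / h
    e_lo = curve.strain_at_stress(s_lo)
    e_hi = curve.strain_at_stress(s_hi)
    inside = (curve.strain > e_lo) & (curve.strain < e_hi)
    eps = np.concatenate([[e_lo], curve.strain[inside], [e_hi]])
    sig = np.concatenate([[s_lo], curve.stress[inside], [s_hi]])
    if eps.size == 2:
        return float((sig[1] - sig[0]) / (eps[1] - eps[0]))
    slope = np.polyfit(eps, sig, 1)[0]
    return float(slope)


def _strain_coefficient(material: MaterialSpec, d0: float, pressure: float) -> float:
    """Hoop strain p*r0/(E*h) of the linear law at diameter d0."""
    r0 = d0 / 2.0
    h = material.thickness_for(r0)
    return pressure * r0 / (material.youngs_modulus * h)


def tube_distension(material: MaterialSpec, d0: float, pressure: float) -> float:
    """Pressurised diameter ``d(p) = d0 (1 + p r0 / (E h))`` in metres."""
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    eps = _strain_coefficient(material, d0, pressure)
    if eps > 0.3:
        import warnings

        warnings.warn(
            f"hoop strain {eps:.2f} exceeds 0.3; linearised tube law out of range"
        )
    return d0 * (1.0 + eps)


def zero_pressure_diameter(
    measured_d: float, pressure_at_measurement: float, material: MaterialSpec
) -> float:
    """Invert the tube law: the d0 whose distension at p equals measured_d.

    Solved by bisection on ``d0 -> tube_distension(d0, p)`` (monotone in d0)
    to 1e-12 m, which covers both the fixed-thickness case (quadratic in d0)
    and the thickness-ratio case (linear).
    """
    if measured_d <= 0:
        raise ValueError("measured diameter must be positive")
    p = pressure_at_measurement
    if p == 0:
        return measured_d

    import warnings

    def resid(d0):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return tube_distension(material, d0, p) - measured_d

    lo, hi = 1e-9, measured_d
    if resid(hi) < 0:
        raise ValueError("no zero-pressure diameter in (0, measured_d]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


def compliance_per_length(material: MaterialSpec, d0: float, pressure: float) -> float:
    """Distensibility dA/dp (m^2/Pa per unit length) of the linear tube law.

    With ``A(p) = pi d(p)^2 / 4`` and ``dd/dp = d0 r0 / (E h)``,
    ``C = pi d(p) d0 r0 / (2 E h)``.
    """
    d_p = tube_distension(material, d0, pressure)
    r0 = d0 / 2.0
    h = material.thickness_for(r0)
    return float(np.pi * d_p * d0 * r0 / (2.0 * material.youngs_modulus * h))


def mmhg_range(lo_mmhg: float, hi_mmhg: float) -> tuple[float, float]:
    """Convenience conversion of a pressure range from mmHg to Pa."""
    return lo_mmhg * MMHG_TO_PA, hi_mmhg * MMHG_TO_PA
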