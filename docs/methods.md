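# Methods

## Scope and model

`graftmetrics` post-processes time-resolved fields from cardiovascular
simulations of arteriovenous grafts; it does not solve flow or mechanics
itself. All quantities are computed over exactly one cardiac cycle
`[t0, t0 + T]` whose sample times may be non-uniform (solvers commonly
shorten the step through systole); every time integral is the trapezoidal
rule on the actual sample times. Internal units are SI throughout; mmHg is
converted at the interfaces with 1 mmHg = 133.322 Pa. Metric maps are
element-attached (cell-centred): area-weighted statistics need per-element
areas, and node-attached solver output is converted by the unweighted mean
of an element's vertex values. Whether a solver writes node- or
cell-attached fields varies, so both attachments are accepted with that
documented conversion.

## Shear metrics

TAWSS, the sampled time-maximum WSS and the OSI are computed per element
from the WSS vector series. Numerical choices:

- **Time maximum is sampled, not interpolated.** No sub-sample
  interpolation rule is standard; at the ~10⁻⁴ s output cadence of typical
  simulations the difference is negligible and the sampled maximum is
  exactly reproducible.
- **Degenerate OSI.** Where the cycle integral of ‖τ‖ falls below
  `zero_tolerance · T` (default 10⁻¹² Pa·s/s) the index is 0/0; such
  elements are reported as 0 — no oscillation, the physically conservative
  reading — and flagged in the map.
- **Strict threshold inequalities.** Exceedance fractions use strict
  comparisons (`> 7 Pa`, `> 40 Pa`, `< 0.1 Pa`, `> 0.25`), matching the
  printed operators of the thresholds; equality at the bound is a
  measure-zero event on continuous fields.
- **Robust maxima.** Reported maxima drop the highest-valued elements
  holding the top 1% of region area (ties broken by element id) before
  taking the maximum, so isolated mesh artefacts cannot dominate. The rule
  removes the minimal top-value prefix whose cumulative area reaches the
  omission fraction; with fraction 0 it degenerates to the plain maximum.
- **Medians are area-weighted** (the value at which cumulative member area
  first reaches half the region area): element-count medians would depend
  on local mesh density. A count-based median remains available behind a
  flag for comparison.

## Flow disturbance

The Reynolds decomposition splits the velocity *magnitude* (not the
components) into trend and perturbation. The trend estimator is Fourier
truncation: the signal's spectrum on one cycle is cut at a configurable
number of cardiac harmonics (default 10), the perturbation is the pointwise
remainder, so additivity holds exactly at the sample times. Published
descriptions of this procedure rarely fix the estimator or cutoff, and the
absolute perturbation RMS depends directly on that choice — the cutoff is
therefore recorded in every report row. Non-uniformly sampled series are
linearly resampled onto 2^k uniform points (spacing at most the smallest
input spacing) before the FFT; the truncated series is then evaluated at
the original sample times.

Cross-sectional statistics take the plain median over mesh nodes whose
projection onto the local centreline tangent lies within ±1 mm (default
half-width; the appropriate value is mesh-dependent and unreported in the
literature this mirrors). Centreline pressure profiles interpolate the
cycle-averaged nodal pressure barycentrically inside the containing
tetrahedron, with a nearest-node fallback (warned) for points that leak
outside the mesh.

## Wall mechanics

Von Mises stress is computed per element and time from the deviatoric part
of the 6-component symmetric Cauchy tensor. The areal engineering strain
ε = √((Aₙ − A₀)/A₀) is undefined for transiently compressed elements
(Aₙ < A₀); those receive the signed extension −√((A₀ − Aₙ)/A₀) and a
warning rather than an error, keeping maps total while preserving the
root-law verbatim on its domain. Inner and outer wall surfaces are treated
as separate meshes and reported separately; no pooling rule across the two
is imposed. "Maximum pulsatility" applies the robust-maximum rule to the
per-element pulsatility map, mirroring the global artefact-omission rule
for all reported maxima. Regional medians and robust maxima of stress use
the cycle-averaged map; stress is tabulated in kPa, strain in %.

## Regions of interest

Sphere ROIs (anastomosis, default radius 1.2 cm) and graft/vein segment
labels decide membership by element centroid — unambiguous and consistent
with area weighting. The sphere centre must be supplied by the user (the
synthetic generator supplies its junction point as the default); every
report records the centre used. Segment labelling assigns each element to
the nearest point of a centreline polyline carrying a transition landmark;
the synthetic anastomosis terminates the graft leg of that polyline at the
vein wall-entry point so that the graft axis' geometric "shadow" on the
vein wall cannot be claimed by the graft.

## Synthetic data

The generator exists to give every downstream stage an analytically known
answer; it makes no claim of flow realism.

- **Quasi-steady Poiseuille WSS** on a cylinder: |τ|(t) = 4μQ(t)/(πr³),
  axially directed. Chosen over a full Womersley solution because it yields
  exact closed forms for TAWSS/OSI under any waveform, which is what metric
  validation needs.
- **Prescribed-OSI signal**: forward fraction f of the cycle at +m, the
  rest at −m, with OSI = ½(1 − |2f − 1|). The reversal is a linear ramp of
  half-width δ = T·10⁻⁹ whose knots are inserted into the sample times, so
  trapezoidal quadrature integrates the signal exactly and the computed
  index matches the target to round-off; f is solved from the exact
  quadrature identity (f = 1 − OSI up to O(δ/T)).
- **Laplace-law wall stress**: hoop pr/h, axial pr/2h, radial 0, rotated
  into global coordinates per element; areas scale with the linear-elastic
  hoop strain pr/(Eh) when a modulus is given. Valid for thin walls
  (h/r ≤ 0.2; thicker walls warn but compute).
- **Seeded perturbations**: ε·sin(2πft + φ(x)) with one uniform random
  phase per node from a single seeded generator; cycle RMS ε/√2. The
  perturbation frequency must exceed the trend cutoff or the construction
  is rejected.
- **Idealized anastomosis**: two structured tube surfaces joined
  end-to-side at 45° (default), the junction at one third of the venous
  length. Wall elements inside the other tube, plus a 1 mm suture-margin
  collar around the opening where the tubes interpenetrate, are removed:
  the union is not watertight there and the strip belongs to neither wall.
  Ground-truth graft/vein/anastomosis masks come with the mesh. No claim is
  made that flow through this geometry resembles the patient case.
- **Waveform**: Q(t) = mean + Σ aₖ sin(2πkt/T + φₖ), strictly positive
  (no retrograde graft flow); the default (600 ml/min mean, ~2× systolic
  peak, T = 1 s) is a parametric stand-in for a measured dialysis-graft
  inflow, not a digitisation of any particular recording.

Synthetic fields emulate magnitudes, directional reversal and stochastic
high-frequency content, but not spatial flow structures (jets, secondary
flow, impingement); passing tests therefore demonstrate the correctness of
the metric implementations, not the physiological realism of any
simulation they may be applied to.

## Materials and tube law

The linear thin-wall law d(p) = d₀(1 + p·r₀/(E·h)) is the package's
distension model; its inverse (zero-pressure diameter from a pressurised
measurement) is solved by bisection to 10⁻¹² m, which uniformly covers
the fixed-thickness case (quadratic in d₀) and the thickness-ratio case
(linear). Published zero-pressure diameters reconstructed from ultrasound
(e.g. the 7.14 mm vein default) are treated as input constants of the
parameter registry, not as quantities this package re-derives; the
implemented inversion is a declared stand-in for whichever reconstruction
produced them. Modulus linearisation maps a transmural pressure range to
hoop stresses via the Laplace law and returns the least-squares slope of
the stress–strain curve restricted to that interval (endpoints linearly
interpolated); for any affine curve this returns the slope exactly,
regardless of range. Hoop strains above 0.3 trigger an out-of-range
warning for the linearisation.

## Pipeline and determinism

`run_pipeline` validates the config (all referenced files must exist)
before any computation, executes shear metrics → disturbance → mechanics →
report per case, and writes the report CSV, per-case metric maps (VTP cell
data) and a JSON run manifest (config hash, input checksums, region sizes,
collected warnings, stage timings). Outputs are a pure function of
(config, inputs, seed): report CSVs are byte-identical across reruns. The
demo dataset uses 33 samples per cycle and a ~1000-element mesh — small
enough to run in seconds while exercising every stage; the velocity
perturbation is injected at cardiac harmonic 13, above the 10-harmonic
trend cutoff and below the Nyquist harmonic of the stored sampling.

## Known limitations

- No turbulence modelling or spectral analysis of perturbations; the
  disturbance RMS is estimator-dependent by construction.
- No additional WSS indices (relative residence time, transWSS); the
  metric-map/threshold machinery is the extension point.
- The tube law is linear-elastic and isotropic; no finite-deformation or
  anisotropic constitutive behaviour.
- The idealized anastomosis surface is not watertight at the junction and
  is unsuitable for solving flow — it is a labelling and reporting
  test-bed.
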