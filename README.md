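# graftmetrics

Post-processing metrics for haemodynamic and mechanical performance of
arteriovenous dialysis grafts (AVGs).

Synthetic AVGs connect an artery to a vein for haemodialysis access. Their
dominant failure mode is neointimal hyperplasia at the graft–vein
anastomosis, driven by disturbed flow, non-physiological wall shear stress
(WSS) and pulsatile overloading of the vein — all of which are aggravated by
the compliance mismatch between a stiff graft (ePTFE) and the native vein,
and potentially mitigated by compliant electrospun polyurethane (ePU)
grafts. This package turns time-resolved simulation output (WSS vectors,
velocity, pressure, Cauchy stress, wall displacement over one cardiac cycle
on unstructured meshes) into the standard comparative metrics used to judge
graft designs, and ships a synthetic-field generator with closed-form
answers so every stage can be verified without running a fluid–structure
interaction solver.

## Metrics

For the WSS vector τ(t, **x**) over one cycle of period *T*:

- **TAWSS** = (1/T) ∫₀ᵀ ‖τ‖ dt — cycle-averaged magnitude; values below
  0.1 Pa are non-physiologically low.
- **WSS_max** = max over the cycle of ‖τ‖ — values above 7 Pa are
  non-physiologically high, above 40 Pa damaging.
- **OSI** = ½ (1 − ‖∫τ dt‖ / ∫‖τ‖ dt) ∈ [0, 0.5] — directional oscillation;
  OSI > 0.25 flags highly oscillatory shear.

Flow disturbance: the velocity magnitude is Reynolds-decomposed,
u = ū + ũ, with the trend ū a Fourier reconstruction retaining the first
10 cardiac harmonics (configurable); the cycle RMS of ũ per point
quantifies transitional/turbulent perturbations.

Wall mechanics: von Mises stress σ_M = √(3/2 tr(σ_d·σ_d)) from the
deviatoric Cauchy stress, areal engineering strain ε = √((Aₙ − A₀)/A₀) of
surface elements, and per-element cycle pulsatility (max − min).

Region statistics are area-weighted (medians, threshold-exceedance area
percentages) and reported maxima omit the highest-valued elements holding
the top 1% of region area to suppress mesh artefacts. The anastomotic
region of interest is a 1.2 cm-radius sphere around the junction.

Materials: a linearised thin-wall tube law d(p) = d₀(1 + p·r₀/(E·h)) with
its exact inverse (zero-pressure diameter reconstruction), modulus
linearisation of stress–strain curves over a pressure working range, and
per-length compliance dA/dp for mismatch comparisons. Shipped constants:
vein E = 0.445 MPa (h = 10% of radius, d₀ = 7.14 mm), ePTFE E = 55 MPa,
ePU E = 1.5 MPa (h = 0.63 mm, d₀ = 6 mm); blood μ = 4.5·10⁻³ Pa·s,
ρ = 1000 kg/m³.

I/O: ASCII VTK XML (`.vtu`/`.vtp`) is the canonical dialect; legacy
`.vtk`, XDMF+HDF5 and STL (geometry only) are read-compatible. Reports are
CSV; internal units are strictly SI with mmHg conversion at the interface.

## Worked example

`examples/` holds one narrative script per capability. Shear metrics of a
pulsatile 600 ml/min flow through a 6 mm graft
(`python examples/01_wss_metrics.py`):

```
median TAWSS   : 2.122 Pa
median WSS_max : 2.882 Pa
median OSI     : 0.0000
(steady-flow closed form at the mean flow: 2.122 Pa)
area with       OSI>0.25:   0.0 %
...
```

The median TAWSS reproduces the Poiseuille closed form 4μQ/(πr³) at the
mean flow; a unidirectional signal has OSI 0 everywhere. The tube-law
example (`python examples/04_tube_law.py`) prints

```
material  d0 (mm)  d(50 mmHg) (mm)  dA/dp (m^2/Pa)
vein         7.14            8.210       2.069e-09
ePTFE        6.00            6.003       4.899e-12
ePU          6.00            6.127       1.833e-10

vein / ePTFE compliance ratio: 422x
vein / ePU   compliance ratio: 11.3x
```

— the stiff ePTFE graft is two orders of magnitude less distensible than
the vein it feeds, while ePU cuts that mismatch to about one order.
`examples/05_comparative_report.py` runs the full two-case pipeline on the
synthetic anastomosis and prints the comparative table.

## Command line

```sh
graftmetrics demo --out demo --seed 7     # synthetic stiff-vs-compliant dataset
graftmetrics run demo/config.yaml --out results_dir
graftmetrics tube --material vein --d0 7.14 --pressure 45
```

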