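"""Config-driven end-to-end runs: field series in, comparative report out.

A run is described by a YAML config naming one field-series manifest per
case (e.g. a stiff ePTFE and a compliant ePU simulation of the same
geometry), the anastomotic sphere ROI, the centreline with the graft-vein
transition landmark, thresholds and the trend cutoff.  ``run_pipeline``
executes WSS metrics, flow disturbance, wall mechanics and report assembly
per case and writes ``report.csv``, per-case metric maps and a JSON run
manifest with config hash, input checksums and collected warnings.

``make_demo`` generates a ready-to-run synthetic two-case dataset on an
idealized anastomosis surface, with the stiff case carrying higher wall
shear (smaller distended lumen) and stronger velocity perturbations.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import CycleWindow, FieldSeries, MetricMap
from .disturbance import TrendSpec, perturbation_rms, reynolds_decompose
from .io import (
    read_centreline_csv,
    read_field_series,
    read_series_manifest,
    write_centreline_csv,
    write_metric_map,
    write_series_manifest,
    write_vtk_xml,
)
from .materials import MATERIALS
from .mechanics import AreaSeries
from .roi import CaseInputs, SphereROI, build_report, label_segments, sphere_region
from .synthetic import (
    FluidSpec,
    TubeSpec,
    WaveformSpec,
    disturbed_velocity_series,
    make_anastomosis_surface,
)
from .wss import ThresholdSpec, DEFAULT_THRESHOLDS, region_median


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg["_base_dir"] = str(Path(path).parent)
    return cfg


def _resolve(cfg: dict, p: str) -> Path:
    p = Path(p)
    return p if p.is_absolute() else Path(cfg.get("_base_dir", ".")) / p


def validate_config(cfg: dict) -> list[Path]:
    """Check the config before any computation; returns referenced files."""
    files = []
    if "cases" not in cfg or not cfg["cases"]:
        raise ValueError("config must define at least one case")
    for name, case in cfg["cases"].items():
        if "manifest" not in case:
            raise ValueError(f"case {name!r} has no series manifest")
        files.append(_resolve(cfg, case["manifest"]))
    if "centreline" in cfg:
        files.append(_resolve(cfg, cfg["centreline"]))
    for f in files:
        if not f.exists():
            raise FileNotFoundError(f"config references missing file: {f}")
    return files


def _thresholds_from(cfg: dict) -> tuple[ThresholdSpec, ...]:
    if "thresholds" not in cfg:
        return DEFAULT_THRESHOLDS
    return tuple(
        ThresholdSpec(
            metric_name=t["metric"],
            bound=float(t["bound"]),
            direction=t["direction"],
            units=t.get("units", "Pa"),
        )
        for t in cfg["thresholds"]
    )


def run_pipeline(config: str | Path | dict, output_dir: str | Path | None = None) -> dict:
    """Execute a configured run; returns paths of the written artefacts."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    files = validate_config(cfg)
    out = Path(output_dir or cfg.get("output_dir", "graftmetrics_out"))
    out.mkdir(parents=True, exist_ok=True)

    collected_warnings: list[str] = []
    timings: dict[str, float] = {}
    thresholds = _thresholds_from(cfg)
    trend = TrendSpec(cutoff_harmonics=int(cfg.get("trend_cutoff", 10)))
    omit = float(cfg.get("omit_area_fraction", 0.01))

    centreline = None
    if "centreline" in cfg:
        centreline = read_centreline_csv(_resolve(cfg, cfg["centreline"]))

    cases: dict[str, CaseInputs] = {}
    rms_rows = []
    regions = None
    mesh0 = None
    for name in sorted(cfg["cases"]):
        t_case = time.perf_counter()
        stage = f"case {name!r}"
        try:
            times, paths = read_series_manifest(_resolve(cfg, cfg["cases"][name]["manifest"]))
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                mesh, wss = read_field_series(paths, times, "element", "wss")
                window = wss.window
                stress = None
                areas = None
                try:
                    _, stress = read_field_series(paths, times, "element", "stress")
                except KeyError:
                    pass
                try:
                    _, area_series = read_field_series(paths, times, "element", "area")
                    areas = AreaSeries(
                        A0=mesh.element_area, An=area_series.scalar_values(), window=window
                    )
                except KeyError:
                    pass
                velocity = None
                try:
                    _, velocity = read_field_series(paths, times, "node", "velocity")
                except KeyError:
                    pass
            collected_warnings += [f"{stage}: {w.message}" for w in caught]
        except Exception as err:
            raise RuntimeError(f"pipeline failed in stage {stage}: {err}") from err

        if mesh0 is None:
            mesh0 = mesh
            region_cfg = cfg.get("regions", {})
            regions = {}
            if centreline is not None:
                regions.update(
                    label_segments(
                        mesh, centreline, region_cfg.get("transition_landmark", "transition")
                    )
                )
            if "anastomosis" in region_cfg:
                roi = SphereROI(
                    center=tuple(region_cfg["anastomosis"]["center"]),
                    radius=float(region_cfg["anastomosis"].get("radius", 0.012)),
                )
                regions["anastomosis"] = sphere_region(mesh, roi)
            if not regions:
                regions = {"all": mesh.all_elements_mask("custom")}

        cases[name] = CaseInputs(mesh=mesh, wss=wss, stress=stress, areas=areas)

        if velocity is not None:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                _, pert = reynolds_decompose(velocity, window, trend)
                rms = perturbation_rms(pert, window)
            collected_warnings += [f"{stage} disturbance: {w.message}" for w in caught]
            rms_map = MetricMap(
                values=rms.values[mesh.triangles].mean(axis=1),
                units="m/s",
                metric_name="u_prime_RMS",
                window=window,
            )
            for region_name in sorted(regions):
                rms_rows.append(
                    {
                        "case": name,
                        "region": region_name,
                        "metric": f"median u_prime_RMS (cutoff {trend.cutoff_harmonics})",
                        "value": region_median(rms_map, regions[region_name]),
                        "units": "m/s",
                    }
                )
        timings[f"load:{name}"] = time.perf_counter() - t_case

    t0 = time.perf_counter()
    report = build_report(cases, regions, thresholds, omit)
    if rms_rows:
        import pandas as pd

        report = pd.concat([report, pd.DataFrame(rms_rows)], ignore_index=True)
        report = report.sort_values(["case", "region", "metric"], kind="stable").reset_index(
            drop=True
        )
    timings["report"] = time.perf_counter() - t0

    report_path = out / "report.csv"
    report.to_csv(report_path, index=False, float_format="%.12g")

    from .wss import compute_osi, compute_tawss, compute_wss_max

    map_paths = {}
    for name, case in cases.items():
        window = case.wss.window
        maps = [
            compute_tawss(case.wss, window),
            compute_wss_max(case.wss, window),
            compute_osi(case.wss, window),
        ]
        p = out / f"maps_{name}.vtp"
        write_metric_map(case.mesh, maps, p)
        map_paths[name] = str(p)

    manifest = {
        "software": f"graftmetrics {__version__}",
        "config_hash": hashlib.sha256(
            json.dumps({k: v for k, v in cfg.items() if not k.startswith("_")}, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": {str(f): _sha256(f) for f in files},
        "trend_cutoff": trend.cutoff_harmonics,
        "omit_area_fraction": omit,
        "regions": {k: int(v.n_elements) for k, v in regions.items()},
        "warnings": collected_warnings,
        "timings_s": timings,
    }
    manifest_path = out / "run_manifest.json"
    tmp = manifest_path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2))
    tmp.replace(manifest_path)  # atomic finalisation

    return {"report": str(report_path), "manifest": str(manifest_path), "maps": map_paths}


def make_demo(out_dir: str | Path, seed: int = 7, n_samples: int = 33) -> Path:
    """Generate a paired stiff/compliant synthetic dataset plus run config.

    Both cases share the idealized anastomosis geometry and inflow waveform;
    they differ in the graft material (ePTFE vs ePU).  The compliant graft
    distends more at the working pressure, so its effective lumen is larger
    and its prescribed wall shear lower; its velocity perturbations are
    weaker; its wall stress series follows its own modulus.  Returns the
    config path.
    """
    from .materials import tube_distension

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed)

    graft = TubeSpec(3e-3, 0.03, 0.63e-3, n_circ=16, n_axial=12)
    vein = TubeSpec(3.57e-3, 0.075, 0.357e-3, n_circ=16, n_axial=24)
    model = make_anastomosis_surface(graft, vein)
    mesh = model.mesh
    waveform = WaveformSpec()
    fluid = FluidSpec()
    window = CycleWindow.uniform(waveform.period_T, n_samples)
    t = window.sample_times
    q = waveform.evaluate(t)
    p_mean = 50.0 * 133.322
    p_t = p_mean + 10.0 * 133.322 * np.sin(2 * np.pi * t / waveform.period_T)

    graft_ids = model.regions["graft"].element_ids
    vein_ids = model.regions["vein"].element_ids
    is_graft = np.zeros(mesh.n_elements, dtype=bool)
    is_graft[graft_ids] = True
    d_axis = np.array([np.sin(np.pi / 4), 0.0, np.cos(np.pi / 4)])
    axial = np.where(is_graft[:, None], d_axis[None, :], np.array([0.0, 0.0, 1.0])[None, :])

    # oscillatory transverse shear confined to the anastomotic neighbourhood
    dist_j = np.linalg.norm(mesh.element_centroid - model.junction, axis=1)
    osc_weight = np.exp(-((dist_j / 0.008) ** 2))
    hoop = np.cross(mesh.element_normal, axial)
    hoop /= np.maximum(np.linalg.norm(hoop, axis=1)[:, None], 1e-12)

    cases = {"ePTFE": MATERIALS["ePTFE"], "ePU": MATERIALS["ePU"]}
    vein_mat = MATERIALS["vein"]
    config_cases = {}
    for name, mat in cases.items():
        d_eff = tube_distension(mat, 2 * graft.radius_zero_pressure, p_mean)
        r_eff = d_eff / 2.0
        r_vein_eff = tube_distension(vein_mat, 2 * vein.radius_zero_pressure, p_mean) / 2.0
        tau_graft = 4 * fluid.dynamic_viscosity * q / (np.pi * r_eff**3)
        tau_vein = 4 * fluid.dynamic_viscosity * q / (np.pi * r_vein_eff**3)
        tau_ax = np.where(is_graft[None, :], tau_graft[:, None], tau_vein[:, None])
        osc_amp = 12.0 if name == "ePTFE" else 6.0
        tau_osc = (
            osc_amp
            * osc_weight[None, :]
            * np.sin(2 * np.pi * 3 * t / waveform.period_T)[:, None]
        )
        wss = tau_ax[:, :, None] * axial[None, :, :] + tau_osc[:, :, None] * hoop[None, :, :]

        # Laplace-law stress and distended areas, material per region
        stress = np.zeros((n_samples, mesh.n_elements, 6))
        area = np.zeros((n_samples, mesh.n_elements))
        for ids, spec, material in (
            (graft_ids, graft, mat),
            (vein_ids, vein, vein_mat),
        ):
            r, h = spec.radius_zero_pressure, spec.wall_thickness
            s_th = p_t * r / h
            s_zz = p_t * r / (2 * h)
            hh = np.einsum("ei,ej->eij", hoop[ids], hoop[ids])
            aa = np.einsum("ei,ej->eij", axial[ids], axial[ids])
            sig = s_th[:, None, None, None] * hh[None] + s_zz[:, None, None, None] * aa[None]
            stress[:, ids, :] = np.stack(
                [
                    sig[..., 0, 0],
                    sig[..., 1, 1],
                    sig[..., 2, 2],
                    sig[..., 0, 1],
                    sig[..., 0, 2],
                    sig[..., 1, 2],
                ],
                axis=-1,
            )
            eps_h = p_t * r / (material.youngs_modulus * h)
            area[:, ids] = mesh.element_area[None, ids] * (1.0 + eps_h[:, None])

        # nodal velocity magnitude: trend from the waveform, seeded perturbations
        u_base = (q / (np.pi * r_eff**2))[:, None] * np.ones((1, mesh.n_nodes))
        base = FieldSeries(
            kind="scalar", attachment="node", values=u_base[:, :, None], units="m/s", window=window
        )
        # perturbation harmonic must sit above the trend cutoff (10) and below
        # the Nyquist harmonic of the stored sampling ((n_samples - 1) / 2)
        amp = 0.05 if name == "ePTFE" else 0.03
        disturbed = disturbed_velocity_series(
            base, amp, 13.0 / waveform.period_T, seed=rng_seed + (0 if name == "ePTFE" else 1)
        )

        case_dir = out / name
        case_dir.mkdir(exist_ok=True)
        step_files = []
        for i in range(n_samples):
            f = case_dir / f"step_{i:03d}.vtp"
            write_vtk_xml(
                f,
                mesh.points,
                mesh.triangles,
                point_data={"velocity": disturbed.values[i, :, 0]},
                cell_data={"wss": wss[i], "stress": stress[i], "area": area[i]},
            )
            step_files.append(f"{name}/step_{i:03d}.vtp")
        write_series_manifest(case_dir / "manifest.csv", t, [f"step_{i:03d}.vtp" for i in range(n_samples)])
        # manifest paths are resolved relative to the manifest file itself
        config_cases[name] = {"manifest": f"{name}/manifest.csv"}

    write_centreline_csv(out / "centreline.csv", model.centreline)
    cfg = {
        "seed": rng_seed,
        "trend_cutoff": 10,
        "omit_area_fraction": 0.01,
        "centreline": "centreline.csv",
        "regions": {
            "anastomosis": {
                "center": [float(x) for x in model.junction],
                "radius": 0.012,
            },
            "transition_landmark": "transition",
        },
        "cases": config_cases,
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path
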