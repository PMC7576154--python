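"""End-to-end orchestration: masks -> kinematics -> pressure -> forces ->
profiles -> cohort statistics, with checksum-keyed stage caching and a
reproducibility manifest."""
from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cohort_stats, field_io, flow_profiles, kinematics, masking, pressure, surface_forces
from .config import AnalysisConfig
from .errors import InvalidParameterError, PipelineStageError
from .fields import FluidProperties, ScalarField
from .synthetic import (
    make_decaying_vortex_lattice,
    make_line_vortex,
    make_paddle_scene,
    make_uniform_flow,
)

STAGES = ("mask", "kinematics", "pressure", "forces", "profiles", "stats")


# ---------------------------------------------------------------------------
# fixture generation

_SCENES = {
    "uniform": make_uniform_flow,
    "vortex_lattice": make_decaying_vortex_lattice,
    "line_vortex": make_line_vortex,
    "paddle": make_paddle_scene,
}


def generate_fixtures(
    scene_name: str, outdir: str | Path, params: dict | None = None, seed: int = 0
) -> Path:
    """Write a complete, immediately analyzable input set for one scene
    (velocity manifest, reference pressure, centerlines when the scene has
    them, and a key-value parameter sidecar)."""
    if scene_name not in _SCENES:
        raise InvalidParameterError(
            f"unknown scene '{scene_name}'; valid names: {', '.join(sorted(_SCENES))}"
        )
    params = dict(params or {})
    if scene_name == "uniform" and "speed" not in params:
        params["speed"] = 0.01
    if scene_name == "line_vortex":
        params.setdefault("circulation", 5e-5)
        params.setdefault("core_radius", 5e-4)
    if scene_name == "paddle":
        params.setdefault("seed", seed)
    scene = _SCENES[scene_name](**params)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    field_io.write_velocity_sequence(scene.fields, out / "velocity.txt")
    for t, ref in enumerate(scene.reference_pressure):
        field_io.write_scalar_field(ref, out / f"reference_pressure_{t:03d}.txt")
    if scene.centerlines is not None:
        for t, cl in enumerate(scene.centerlines):
            field_io.write_contour_csv(
                cl.points, out / f"centerline_{t:03d}.csv", closed=False
            )
    lines = [f"scene {scene_name}"] + [
        f"{k} {v}" for k, v in sorted(scene.params.items(), key=lambda kv: kv[0])
    ]
    (out / "params.txt").write_text("\n".join(lines) + "\n")
    return out


# ---------------------------------------------------------------------------
# caching helpers


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_key(cfg_part: dict, inputs: list[Path], upstream: list[str]) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(cfg_part, sort_keys=True, default=str).encode())
    for p in sorted(inputs):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    for key in upstream:
        h.update(key.encode())
    return h.hexdigest()


class _Cache:
    def __init__(self, outdir: Path):
        self.path = outdir / "cache.json"
        self.data = {}
        if self.path.exists():
            try:
                self.data = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                self.data = {}

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        return self.data.get(stage) == key and all(p.exists() for p in outputs)

    def store(self, stage: str, key: str) -> None:
        self.data[stage] = key
        tmp = self.path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.data, indent=2))
        tmp.replace(self.path)


# ---------------------------------------------------------------------------
# the pipeline


def _frame_files(input_dir: Path, pattern: str | None, n: int) -> list[Path] | None:
    if pattern is None:
        return None
    paths = [input_dir / pattern.format(frame=t) for t in range(n)]
    return paths if all(p.exists() for p in paths) else None


def run_analysis(
    config: AnalysisConfig,
    input_dir: str | Path,
    outdir: str | Path,
    stages: list[str] | None = None,
) -> Path:
    """Run the requested stages (all by default) on one input directory.

    Re-running with unchanged inputs and config skips cached stages and
    reproduces byte-identical outputs.
    """
    input_dir = Path(input_dir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages is not None else list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise InvalidParameterError(f"unknown stage '{s}'; valid: {', '.join(STAGES)}")
    cache = _Cache(out)
    manifest = {
        "software_version": __version__,
        "config": config.to_dict(),
        "input_dir": str(input_dir),
        "inputs": {},
        "timings_s": {},
        "warnings": [],
    }
    vel_path = input_dir / config.paths.velocity
    if not vel_path.exists():
        raise PipelineStageError(f"stage setup: velocity file {vel_path} not found")
    seq = field_io.read_velocity_sequence(vel_path)
    manifest["inputs"][config.paths.velocity] = _sha256_file(vel_path)
    fluid = FluidProperties.from_kinematic(
        config.fluid.density, config.fluid.kinematic_viscosity
    )
    n = seq.n_frames
    centerline_files = _frame_files(input_dir, config.paths.centerlines, n)

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineStageError(f"stage {stage}: {exc}") from exc
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)

    # ---- mask ------------------------------------------------------------
    masks_raster: list[np.ndarray] | None = None
    contours: list[np.ndarray] | None = None

    def load_mask_outputs():
        nonlocal masks_raster, contours
        masks_raster, contours = [], []
        for t in range(n):
            sf = field_io.read_scalar_field(out / f"mask_{t:03d}.txt")
            masks_raster.append(sf.values > 0.5)
            contours.append(field_io.read_contour_csv(out / f"contour_{t:03d}.csv")[0])

    def stage_mask():
        nonlocal masks_raster, contours
        mcfg = config.masking
        image_path = input_dir / config.paths.images if config.paths.images else None
        contour_files = _frame_files(input_dir, config.paths.contours, n)
        raw_contours: list[np.ndarray] = []
        if image_path and image_path.exists():
            frames, px = field_io.read_image_stack(
                image_path, pixel_size=config.calibration.pixel_size
            )
            if len(frames) not in (1, n):
                raise InvalidParameterError(
                    f"image stack has {len(frames)} frames, velocity has {n}"
                )
            for t in range(n):
                img = frames[min(t, len(frames) - 1)]
                c = masking.segment_body(
                    img,
                    threshold_method=mcfg.threshold_method,
                    min_area_px=mcfg.min_area_px,
                    pixel_size=px,
                    invert=mcfg.invert,
                )
                raw_contours.append(masking.smooth_contour(c, mcfg.smoothing_window))
        elif contour_files:
            for p in contour_files:
                raw_contours.append(field_io.read_contour_csv(p)[0])
        elif centerline_files:
            for p in centerline_files:
                pts, _ = field_io.read_contour_csv(p)
                raw_contours.append(
                    masking.thicken_centerline(pts, mcfg.centerline_half_width)
                )
        else:
            masks_raster = None
            contours = None
            manifest["warnings"].append("mask stage: no mask source; masks disabled")
            return
        masks_raster, contours = [], []
        for t, c in enumerate(raw_contours):
            bm = masking.rasterize_mask(c, seq.grid, dilation_cells=mcfg.dilation_cells)
            masks_raster.append(bm.raster)
            contours.append(c)
            field_io.write_scalar_field(
                ScalarField(
                    values=bm.raster.astype(float), grid=seq.grid, units="mask"
                ),
                out / f"mask_{t:03d}.txt",
            )
            field_io.write_contour_csv(c, out / f"contour_{t:03d}.csv", closed=True)

    if "mask" in stages:
        key = _stage_key(
            {"masking": config.to_dict()["masking"], "paths": config.to_dict()["paths"]},
            [p for p in [vel_path] + (centerline_files or []) if p.exists()],
            [],
        )
        outputs = [out / f"mask_{t:03d}.txt" for t in range(n)]
        if cache.fresh("mask", key, outputs):
            load_mask_outputs()
            manifest["timings_s"]["mask"] = 0.0
        else:
            timed("mask", stage_mask)
            if masks_raster is not None:
                cache.store("mask", key)
    elif (out / f"mask_{n-1:03d}.txt").exists():
        load_mask_outputs()

    # ---- kinematics ------------------------------------------------------
    centerlines: list[kinematics.Centerline] | None = None
    stroke_window = tuple(config.stroke_window) if config.stroke_window else (0, n - 1)

    def stage_kinematics():
        nonlocal centerlines, stroke_window
        if not centerline_files:
            manifest["warnings"].append("kinematics stage: no centerlines; skipped")
            return
        centerlines = []
        rows = []
        for t, p in enumerate(centerline_files):
            pts, _ = field_io.read_contour_csv(p)
            cl = kinematics.resample_centerline(pts, config.kinematics.n_points)
            centerlines.append(cl)
            fit = kinematics.fit_bend(cl)
            rows.append(
                {
                    "frame": t,
                    "angle_deg": fit.bend_angle,
                    "inflexion_fraction": fit.inflexion_fraction,
                    "residual_m": fit.fit_residual,
                    "reliable": fit.reliable,
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "kinematics.csv", index=False)
        if config.stroke_window is None:
            tips = np.array([c.points[-1] - c.points[0] for c in centerlines])
            ang = np.unwrap(np.arctan2(tips[:, 1], tips[:, 0]))
            stroke_window = kinematics.detect_power_stroke(ang)
        mid = kinematics.select_mid_power_stroke(stroke_window)
        speed = kinematics.tip_speed(centerlines, seq.dt, mid)
        L = centerlines[mid].L
        summary = {
            "mid_stroke_frame": mid,
            "stroke_start": stroke_window[0],
            "stroke_end": stroke_window[1],
            "bend_angle_deg": df.loc[mid, "angle_deg"],
            "inflexion_fraction": df.loc[mid, "inflexion_fraction"],
            "tip_speed_m_per_s": speed,
            "propulsor_length_m": L,
            "reynolds": kinematics.compute_reynolds(
                speed, L, fluid.kinematic_viscosity
            )
            if speed > 0
            else float("nan"),
        }
        pd.DataFrame([summary]).to_csv(out / "kinematics_summary.csv", index=False)

    if "kinematics" in stages:
        timed("kinematics", stage_kinematics)
    elif centerline_files:
        centerlines = [
            kinematics.resample_centerline(
                field_io.read_contour_csv(p)[0], config.kinematics.n_points
            )
            for p in centerline_files
        ]

    # ---- pressure --------------------------------------------------------
    pressure_fields: list[ScalarField] | None = None

    def load_pressure_outputs():
        nonlocal pressure_fields
        pressure_fields = [
            field_io.read_scalar_field(out / f"pressure_{t:03d}.txt") for t in range(n)
        ]

    def stage_pressure():
        nonlocal pressure_fields
        pressure_fields, diags = pressure.compute_pressure_sequence(
            seq, masks=masks_raster, fluid=fluid
        )
        for t, pf in enumerate(pressure_fields):
            field_io.write_scalar_field(pf, out / f"pressure_{t:03d}.txt")
        diags.to_csv(out / "pressure_diagnostics.csv", index=False)

    if "pressure" in stages:
        key = _stage_key(
            {"fluid": config.to_dict()["fluid"], "masking": config.to_dict()["masking"]},
            [vel_path],
            [cache.data.get("mask", "")],
        )
        outputs = [out / f"pressure_{t:03d}.txt" for t in range(n)]
        if cache.fresh("pressure", key, outputs):
            load_pressure_outputs()
            manifest["timings_s"]["pressure"] = 0.0
        else:
            timed("pressure", stage_pressure)
            cache.store("pressure", key)
    elif (out / f"pressure_{n-1:03d}.txt").exists():
        load_pressure_outputs()

    # ---- forces ----------------------------------------------------------
    def stage_forces():
        if pressure_fields is None or contours is None:
            manifest["warnings"].append("forces stage: needs pressure and contours; skipped")
            return
        axis = _thrust_axis(config, masks_raster, seq)
        surfaces = [
            surface_forces.make_surface(c, config.forces.n_segments, closed=True)
            for c in contours
        ]
        series = surface_forces.stroke_series(
            pressure_fields,
            surfaces,
            axis,
            window=stroke_window,
            dt=seq.dt,
            probe_offset_cells=config.forces.probe_offset_cells,
        )
        df = series.to_frame()
        df.to_csv(out / "forces.csv", index=False)
        pd.DataFrame(
            [
                {
                    "pull_push_ratio": series.pull_push_ratio,
                    "thrust_axis_x": axis[0],
                    "thrust_axis_y": axis[1],
                    "stroke_start": stroke_window[0],
                    "stroke_end": stroke_window[1],
                }
            ]
        ).to_csv(out / "forces_summary.csv", index=False)

    if "forces" in stages:
        timed("forces", stage_forces)

    # ---- profiles --------------------------------------------------------
    def stage_profiles():
        if centerlines is None:
            manifest["warnings"].append("profiles stage: no centerlines; skipped")
            return
        delta = config.profiles.delta_cells * min(seq.grid.dx, seq.grid.dy)
        rows = []
        metric_rows = []
        for t in range(n):
            cl = centerlines[t]
            t0, t1 = max(t - 1, 0), min(t + 1, n - 1)
            disp = centerlines[t1].points[len(cl.points) // 2] - centerlines[t0].points[
                len(cl.points) // 2
            ]
            if np.linalg.norm(disp) == 0:
                disp = np.array([1.0, 0.0])
            motion = disp / np.linalg.norm(disp)
            curves = flow_profiles.offset_curves(cl, delta, motion)
            prof = flow_profiles.sample_profile(
                seq,
                t,
                curves,
                cl,
                pressure=pressure_fields[t] if pressure_fields else None,
            )
            for k, frac in enumerate(prof.fractions):
                row = {
                    "frame": t,
                    "fraction": frac,
                    "leeward_speed": prof.leeward_speed[k],
                    "flowward_speed": prof.flowward_speed[k],
                }
                if prof.leeward_pressure is not None:
                    row["leeward_pressure"] = prof.leeward_pressure[k]
                    row["flowward_pressure"] = prof.flowward_pressure[k]
                rows.append(row)
            metric_rows.append(
                {
                    "frame": t,
                    "peak_flow_fraction": flow_profiles.peak_flow_fraction(prof),
                    "side_velocity_ratio": flow_profiles.side_velocity_ratio(prof),
                    "pressure_asymmetry_ratio": (
                        flow_profiles.pressure_asymmetry_ratio(prof)
                        if prof.leeward_pressure is not None
                        else float("nan")
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(out / "profiles.csv", index=False)
        pd.DataFrame(metric_rows).to_csv(out / "profile_metrics.csv", index=False)

    if "profiles" in stages:
        timed("profiles", stage_profiles)

    # ---- stats -----------------------------------------------------------
    def stage_stats():
        if not config.paths.cohort:
            manifest["warnings"].append("stats stage: no cohort table; skipped")
            return
        table = cohort_stats.validate_cohort(
            pd.read_csv(input_dir / config.paths.cohort)
        )
        all_rows = []
        anova_rows = []
        for metric in dict.fromkeys(table["metric"]):
            summ = cohort_stats.summarize(table, metric)
            summ.insert(0, "metric", metric)
            all_rows.append(summ)
            groups = [
                g["value"].to_numpy()
                for _, g in table[table["metric"] == metric].groupby(
                    "species", sort=False
                )
            ]
            res = cohort_stats.one_way_anova(groups)
            anova_rows.append(
                {
                    "metric": metric,
                    "f_stat": res.f_stat,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "p_value": res.p_value,
                }
            )
        pd.concat(all_rows).to_csv(out / "cohort_summary.csv", index=False)
        pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)

    if "stats" in stages:
        timed("stats", stage_stats)

    if config.figures:
        from . import plots

        try:
            plots.save_overview_figures(out, seq, pressure_fields, contours)
        except Exception as exc:  # figures are optional outputs, never inputs
            manifest["warnings"].append(f"figures: {exc}")

    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    tmp.replace(out / "manifest.json")
    return out


def _thrust_axis(config: AnalysisConfig, masks_raster, seq) -> np.ndarray:
    if config.thrust_axis != "auto":
        a = np.asarray(config.thrust_axis, dtype=float)
        norm = np.linalg.norm(a)
        if norm == 0:
            raise InvalidParameterError("thrust_axis must be nonzero")
        return a / norm
    if not masks_raster:
        raise InvalidParameterError("thrust_axis auto-estimation needs masks")
    X, Y = seq.grid.mesh()
    cents = np.array(
        [[X[m].mean(), Y[m].mean()] for m in masks_raster if m.any()]
    )
    disp = cents[-1] - cents[0]
    norm = np.linalg.norm(disp)
    if norm == 0:
        raise InvalidParameterError("mask centroids do not move; supply thrust_axis")
    return disp / norm
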