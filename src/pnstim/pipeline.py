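"""End-to-end orchestration: phantom → dosimetry → fibers → thresholds → margins.

A :class:`RunConfig` describes one study: the phantom, the exposure, the
averaging rule used to seed fibers, the fiber protocol, the axon preset,
the frequency grid of the threshold sweep, and the limit curves to compare
against.  :func:`run_pipeline` executes the stages, writes every artifact
(CSV/JSON/NIfTI) into the run directory, and records a provenance manifest
with the config, seed, solver residuals and stage timings.  Runs are
deterministic given the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .axon import AxonParams
from .dielectrics import assign_conductivity, load_cole_cole_table
from .fibers import curved_fiber, sample_quasipotential, straight_fiber, uniform_field_fiber
from .limits import margin_report, packaged_limits
from .phantom import make_layered_cylinder, write_grid
from .postprocess import cube_average, line_average, percentile_filter, top_hotspots
from .spfd import ExposureSpec, solve_field
from .thresholds import (StimulusWaveform, find_threshold,
                         population_thresholds, sd_protocol)

__all__ = ["RunConfig", "run_pipeline"]

STRAIGHT_ANGLES_DEG = (0, 30, 60, 90, 120, 150, 180)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    # phantom
    radius_mm: float = 150.0
    height_mm: float = 60.0
    voxel_size_mm: float = 2.0
    layer_thicknesses: dict = dc_field(
        default_factory=lambda: {"skin": 2.0, "fat": 10.0})
    # exposure
    b_amplitude_mt: float = 0.3
    direction: tuple = (0.0, 1.0, 0.0)     # front-to-back
    base_frequency_hz: float = 1000.0
    # averaging / hotspots
    averaging: str = "line5mm"             # 'cube2mm' | 'line5mm' | 'none'
    hotspot_tissues: tuple = ("fat", "skin")
    n_hotspots: int = 10
    hotspot_separation_mm: float = 10.0
    # fiber protocol
    fiber_diameter_um: float = 20.0
    n_nodes: int = 21
    curved: bool = True
    straight_angles_deg: tuple = STRAIGHT_ANGLES_DEG
    n_fibers: int = 10
    # axon / thresholds
    axon_preset: str = "perceptual"        # 'perceptual' | 'uncomfortable'
    rel_tol: float = 0.01
    run_sd_calibration: bool = False
    sd_widths_us: tuple = (20, 50, 100, 150, 200, 300, 500, 700, 1000)
    # sweep & limits
    frequency_grid_hz: tuple = (1000.0, 10000.0)
    limit_curves: tuple = ("icnirp2010_occupational_rl",
                           "ieee_c951_restricted_erl")
    # bookkeeping
    seed: int = 0
    solver_tol: float = 1e-6

    def __post_init__(self):
        lo, hi = min(self.frequency_grid_hz), max(self.frequency_grid_hz)
        if lo < 300.0 or hi > 1e6:
            raise ValueError("frequency grid must lie within 300 Hz - 1 MHz")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _axon_params(cfg: RunConfig) -> AxonParams:
    if cfg.axon_preset == "perceptual":
        return AxonParams.perceptual(cfg.fiber_diameter_um)
    if cfg.axon_preset == "uncomfortable":
        return AxonParams.uncomfortable(cfg.fiber_diameter_um)
    raise ValueError(f"unknown axon preset {cfg.axon_preset!r}")


def _averaged(field, grid, method: str):
    if method == "cube2mm":
        return cube_average(field, grid)
    if method == "line5mm":
        return line_average(field, grid)
    if method == "none":
        return np.where(grid.labels != 0, field.e_mag, np.nan)
    raise ValueError(f"unknown averaging method {method!r}")


def _write_csv(df, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all stages and write artifacts into ``outdir``.

    Returns a result dictionary with the in-memory stage products and the
    paths of everything written.  Any stage failure raises with the stage
    name; artifacts of completed stages remain on disk.
    """
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_all = time.time()
    timings, artifacts = {}, {}
    result: dict = {"config": config, "artifacts": artifacts}
    stage = "init"
    try:
        # --- phantom -------------------------------------------------------
        stage = "phantom"
        t0 = time.time()
        grid = make_layered_cylinder(
            radius_mm=config.radius_mm, height_mm=config.height_mm,
            layer_thicknesses=config.layer_thicknesses,
            voxel_size_mm=config.voxel_size_mm)
        write_grid(grid, out / "phantom.nii")
        artifacts["phantom"] = str(out / "phantom.nii")
        result["grid"] = grid
        timings[stage] = time.time() - t0

        # --- dosimetry at the base frequency -------------------------------
        stage = "dosimetry"
        t0 = time.time()
        table = load_cole_cole_table()
        exposure = ExposureSpec(b_amplitude_t=config.b_amplitude_mt * 1e-3,
                                direction=tuple(config.direction),
                                frequency_hz=config.base_frequency_hz)
        cond = assign_conductivity(grid, table, exposure.frequency_hz)
        field = solve_field(cond, exposure, tol=config.solver_tol)
        result["field"] = field
        import nibabel as nib
        affine = np.diag([grid.voxel_size] * 3 + [1.0])
        affine[:3, 3] = grid.origin + 0.5 * grid.voxel_size
        nib.save(nib.Nifti1Image(field.e_vec.astype(np.float32), affine),
                 str(out / "field.nii"))
        artifacts["field"] = str(out / "field.nii")
        (out / "field.json").write_text(json.dumps({
            "frequency_hz": exposure.frequency_hz,
            "b_amplitude_t": exposure.b_amplitude_t,
            "direction": list(exposure.direction),
            "residual": field.residual,
            "e99_voxel_vm": percentile_filter(
                field.e_mag[grid.labels != 0], 99.0),
        }, indent=1))
        artifacts["field_meta"] = str(out / "field.json")
        timings[stage] = time.time() - t0

        # --- averaging and hotspots ----------------------------------------
        stage = "hotspots"
        t0 = time.time()
        avg = _averaged(field, grid, config.averaging)
        nib.save(nib.Nifti1Image(avg.astype(np.float32), affine),
                 str(out / "field_averaged.nii"))
        artifacts["field_averaged"] = str(out / "field_averaged.nii")
        hotspots = top_hotspots(avg, grid, tissues=config.hotspot_tissues,
                                n=config.n_hotspots,
                                min_separation_mm=config.hotspot_separation_mm,
                                method=config.averaging)
        _write_csv(hotspots.to_dataframe(), out / "hotspots.csv")
        artifacts["hotspots"] = str(out / "hotspots.csv")
        result["hotspots"] = hotspots
        timings[stage] = time.time() - t0

        # --- fiber thresholds at the base frequency ------------------------
        stage = "fibers"
        t0 = time.time()
        params = _axon_params(config)
        waveform = StimulusWaveform.sinusoid(exposure.frequency_hz)
        rows = []
        fiber_frames = []
        if config.curved:
            pop = population_thresholds(
                hotspots, field, params, n_fibers=config.n_fibers,
                curved=True, waveform=waveform,
                diameter_um=config.fiber_diameter_um,
                n_nodes=config.n_nodes, seed=config.seed,
                rel_tol=config.rel_tol)
            result["population"] = pop
            for i, (th, f) in enumerate(zip(pop.thresholds_mt, pop.fibers)):
                rows.append({"fiber": i, "geometry": "curved",
                             "theta_deg": "", "threshold_mT": th})
                if f is None:
                    continue
                df = f.to_dataframe()
                df.insert(0, "fiber", i)
                fiber_frames.append(df)
            _write_csv(pd.DataFrame({
                "group_size": pop.group_sizes,
                "median_mT": pop.group_medians_mt,
                "iqr_mT": pop.group_iqr_mt}), out / "population.csv")
            artifacts["population"] = str(out / "population.csv")
        else:
            for i, h in enumerate(hotspots.entries[:config.n_fibers]):
                for th_deg in config.straight_angles_deg:
                    f = straight_fiber(h.world_mm, th_deg,
                                       diameter_um=config.fiber_diameter_um,
                                       n_nodes=config.n_nodes, grid=grid)
                    try:
                        sample_quasipotential(f, field)
                        amp = find_threshold(f, params, waveform,
                                             rel_tol=config.rel_tol)
                    except (RuntimeError, ValueError):
                        # orientations nearly perpendicular to the field may
                        # not activate in bounds; surface-tangent fibers may
                        # leave the solved grid
                        amp = float("nan")
                    rows.append({"fiber": i, "geometry": "straight",
                                 "theta_deg": th_deg, "threshold_mT": amp})
                    df = f.to_dataframe()
                    df.insert(0, "fiber", i)
                    df.insert(1, "theta_deg", th_deg)
                    fiber_frames.append(df)
        thr_df = pd.DataFrame(rows)
        _write_csv(thr_df, out / "thresholds.csv")
        _write_csv(pd.concat(fiber_frames, ignore_index=True),
                   out / "fibers.csv")
        artifacts["thresholds"] = str(out / "thresholds.csv")
        artifacts["fibers"] = str(out / "fibers.csv")
        result["thresholds"] = thr_df
        timings[stage] = time.time() - t0

        # --- optional uniform-field S-D calibration check ------------------
        if config.run_sd_calibration:
            stage = "sd_calibration"
            t0 = time.time()
            uf = uniform_field_fiber(config.fiber_diameter_um, config.n_nodes)
            curve = sd_protocol(uf, params,
                                widths_s=[w * 1e-6 for w in config.sd_widths_us],
                                rel_tol=config.rel_tol)
            _write_csv(curve.to_dataframe(), out / "sd_curve.csv")
            (out / "sd_fit.json").write_text(json.dumps({
                "rheobase_vm": curve.rheobase,
                "chronaxie_us": curve.chronaxie_s * 1e6,
                "residual": curve.residual}, indent=1))
            artifacts["sd_curve"] = str(out / "sd_curve.csv")
            result["sd_curve"] = curve
            timings[stage] = time.time() - t0

        # --- threshold-frequency sweep -------------------------------------
        stage = "sweep"
        t0 = time.time()
        # representative fiber: the median-threshold hotspot of the base run
        finite = thr_df[np.isfinite(thr_df["threshold_mT"])]
        if finite.empty:
            raise RuntimeError("no fiber activated at the base frequency")
        med_idx = finite.index[int(np.argsort(
            finite["threshold_mT"].to_numpy())[len(finite) // 2])]
        seed_hotspot = hotspots.entries[
            int(thr_df.loc[med_idx, "fiber"])]
        sweep_rows = []
        for f_hz in sorted(config.frequency_grid_hz):
            # conductivity is frequency dependent: re-solve per frequency
            cond_f = assign_conductivity(grid, table, f_hz)
            expo_f = ExposureSpec(b_amplitude_t=1e-3,
                                  direction=tuple(config.direction),
                                  frequency_hz=f_hz)
            fld = solve_field(cond_f, expo_f, tol=config.solver_tol)
            if config.curved:
                fib = curved_fiber(seed_hotspot.world_mm, fld,
                                   diameter_um=config.fiber_diameter_um,
                                   n_nodes=config.n_nodes)
            else:
                from .thresholds import _local_field_direction, straight_along
                fib = straight_along(seed_hotspot.world_mm,
                                     _local_field_direction(
                                         fld, seed_hotspot.world_mm),
                                     diameter_um=config.fiber_diameter_um,
                                     n_nodes=config.n_nodes)
            sample_quasipotential(fib, fld)
            wf = StimulusWaveform.sinusoid(f_hz)
            b_th_mt = find_threshold(fib, params, wf, rel_tol=config.rel_tol)
            avg_f = _averaged(fld, grid, config.averaging)
            e_per_mt = avg_f[seed_hotspot.index]
            if not np.isfinite(e_per_mt):
                e_per_mt = fld.e_mag[seed_hotspot.index]
            sweep_rows.append({"frequency_hz": f_hz,
                               "threshold_mT": b_th_mt,
                               "threshold_internal_vm": b_th_mt * e_per_mt,
                               "residual": fld.residual})
        sweep_df = pd.DataFrame(sweep_rows)
        _write_csv(sweep_df, out / "threshold_frequency.csv")
        artifacts["sweep"] = str(out / "threshold_frequency.csv")
        result["sweep"] = sweep_df
        timings[stage] = time.time() - t0

        # --- margin report --------------------------------------------------
        stage = "margins"
        t0 = time.time()
        lims = packaged_limits()
        margin_rows = []
        for name in config.limit_curves:
            curve = lims[name]
            if curve.quantity == "external_B":
                th = {r["frequency_hz"]: r["threshold_mT"] * 1e-3
                      for r in sweep_rows}
            else:
                th = {r["frequency_hz"]: r["threshold_internal_vm"]
                      for r in sweep_rows}
            rep = margin_report(th, curve,
                                response_class=config.axon_preset)
            for f_hz, ratio in zip(rep.frequencies_hz, rep.ratios):
                margin_rows.append({"curve": name,
                                    "quantity": curve.quantity,
                                    "frequency_hz": f_hz, "ratio": ratio})
            result.setdefault("margins", {})[name] = rep
        _write_csv(pd.DataFrame(margin_rows), out / "margins.csv")
        artifacts["margins"] = str(out / "margins.csv")
        timings[stage] = time.time() - t0
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage '{stage}' failed "
            f"(artifacts so far: {sorted(artifacts)})") from err

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t_all, 3),
        "solver_residual": result["field"].residual,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = str(out / "manifest.json")
    return result
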