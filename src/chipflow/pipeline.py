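"""Configuration-driven orchestration of the whole study.

One YAML config drives: geometry build -> composite flow solve -> surface
statistics sweep -> Lagrangian cell tracing -> synthetic displacement
velocimetry -> report bundle (CSV/JSON/VTU + provenance manifest).  All
internal computation is SI; the summary tables use the reporting units of
the field (m/s and dyne/cm^2).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ChipParams, build_chip
from .fem import FluidProperties, flowrate_to_inlet_velocity
from .composite import CompositeChipModel
from . import particles as pt
from . import velocimetry as vm
from .io import write_vtu, flow_point_data
from .units import PA_TO_DYNE_CM2, ML_PER_H, UL

__all__ = ["RunConfig", "StageError", "load_config", "run_study",
           "compare_to_reference", "reference_tables"]


class StageError(RuntimeError):
    """A pipeline stage failed; reports the stage and completed artifacts."""

    def __init__(self, stage: str, completed: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}; "
                         f"completed artifacts: {list(completed.values())}")
        self.stage, self.completed, self.cause = stage, completed, cause


DEFAULT_TRACE = {"dt": 2e-3, "fps": 30.0, "t_end": 20.0}
DEFAULT_VELOCIMETRY = {"pixel_size": 0.5e-6, "jitter_px": 0.5}
DEFAULT_SEEDS = {"trace": 1, "velocimetry": 1}


@dataclass
class RunConfig:
    chip: ChipParams = field(default_factory=ChipParams)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    flow_rate_m3_s: float | None = None
    inlet_velocity_m_s: float | None = None
    sweep_velocities: list = field(default_factory=list)
    cells: dict = field(default_factory=dict)     # mean_diameter, cv, n_cells, ...
    trace: dict = field(default_factory=lambda: dict(DEFAULT_TRACE))
    velocimetry: dict = field(default_factory=lambda: dict(DEFAULT_VELOCIMETRY))
    seeds: dict = field(default_factory=lambda: dict(DEFAULT_SEEDS))
    solver: dict = field(default_factory=dict)    # h_gap, h_header, ...
    outdir: str = "results/run"

    def __post_init__(self):
        n_given = sum(v is not None
                      for v in (self.flow_rate_m3_s, self.inlet_velocity_m_s))
        if n_given > 1 or (n_given == 0 and not self.sweep_velocities):
            raise ValueError(
                "exactly one of flow_rate_m3_s / inlet_velocity_m_s must be set")

    @property
    def inlet_velocity(self) -> float:
        if self.inlet_velocity_m_s is not None:
            return float(self.inlet_velocity_m_s)
        return flowrate_to_inlet_velocity(self.flow_rate_m3_s,
                                          self.chip.inlet_width, self.chip.depth)

    def digest(self) -> str:
        payload = {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                   for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    chip = ChipParams(**raw.get("chip", {}))
    fluid = FluidProperties(**raw.get("fluid", {}))
    inj = raw.get("injection", {})
    q = inj.get("flow_rate_m3_s")
    if q is None and "flow_rate_ml_h" in inj:
        q = inj["flow_rate_ml_h"] * ML_PER_H
    return RunConfig(
        chip=chip, fluid=fluid, flow_rate_m3_s=q,
        inlet_velocity_m_s=inj.get("inlet_velocity_m_s"),
        sweep_velocities=raw.get("sweep", {}).get("inlet_velocities_m_s", []),
        cells=raw.get("cells", {}), trace=raw.get("trace", dict(DEFAULT_TRACE)),
        velocimetry=raw.get("velocimetry", dict(DEFAULT_VELOCIMETRY)),
        seeds=raw.get("seeds", dict(DEFAULT_SEEDS)),
        solver=raw.get("solver", {}), outdir=raw.get("outdir", "results/run"))


def reference_tables() -> pd.DataFrame:
    """The packaged transcription of the published sweep tables (comparison
    reference only, never a computation input)."""
    with resources.files("chipflow.data").joinpath("tables_reference.csv").open() as fh:
        return pd.read_csv(fh)


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns {artifact name: path}."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    done: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:
                raise StageError(name, done, exc) from exc
        return deco

    model_box = {}

    @stage("geometry")
    def _geometry():
        geom = build_chip(config.chip)
        path = out / "chip_geometry.json"
        path.write_text(geom.to_json())
        done["geometry"] = str(path)
        model_box["geom"] = geom

    @stage("solve")
    def _solve():
        model = CompositeChipModel(config.chip, config.fluid,
                                   **{k: v for k, v in config.solver.items()
                                      if k in ("h_post_patch", "h_gap", "h_header")})
        model_box["model"] = model
        if model.post_patch is not None:
            path = out / "post_patch.vtu"
            write_vtu(model.post_patch.mesh, path,
                      point_data=flow_point_data(model.post_patch))
            done["post_patch_vtu"] = str(path)
        path = out / "header_patch.vtu"
        write_vtu(model.header_patch.mesh, path,
                  point_data=flow_point_data(model.header_patch))
        done["header_patch_vtu"] = str(path)

    @stage("sweep")
    def _sweep():
        model = model_box["model"]
        df = model.sweep(list(config.sweep_velocities))
        # hard post-check: rows must be exactly linear in v_inlet
        if len(df) > 1:
            for col in ("shear_avg_dyn_cm2", "vel_avg_m_s",
                        "shear_max_dyn_cm2", "vel_max_m_s"):
                r = df[col] / df["v_inlet_m_s"]
                if len(r) and (r.max() - r.min()) > 1e-3 * abs(r.mean()):
                    raise RuntimeError(f"sweep linearity violated in {col}")
        path = out / "sweep_summary.csv"
        df.to_csv(path, index=False)
        done["sweep_summary"] = str(path)
        model_box["sweep"] = df

    @stage("trace")
    def _trace():
        if not config.cells:
            return
        c = config.cells
        model = model_box["model"]
        ev = model.evaluator(config.inlet_velocity)
        pop = pt.sample_population(
            int(c.get("n_cells", 1000)), c.get("mean_diameter", 12e-6),
            c.get("cv"), seed=config.seeds.get("trace", 1),
            concentration=(c.get("count_in_volume", 0)
                           / (c.get("medium_volume_ul", 170) * UL)) or None)
        traj = pt.trace(ev, pop, dt=config.trace.get("dt", 2e-3),
                        t_end=config.trace.get("t_end", 20.0),
                        fps=config.trace.get("fps", 30.0),
                        seed=config.seeds.get("trace", 1))
        model_box["traj"] = traj
        rows = []
        for fi, t in enumerate(traj.times):
            live = traj.status[fi] != pt.EXITED
            for cid in np.where(live)[0]:
                x, y = traj.positions[fi, cid]
                rows.append((cid, t, x, y, int(traj.status[fi, cid])))
        df = pd.DataFrame(rows, columns=["cell_id", "t_s", "x_m", "y_m", "status"])
        path = out / "trajectories.csv"
        df.to_csv(path, index=False)
        done["trajectories"] = str(path)

        fa = pt.first_arrival_time(traj)
        t_snap = fa if fa is not None else traj.times[-1]
        counts, edges, per_channel = pt.position_histogram(traj, t_snap, 50)
        hist = pd.DataFrame({"x_lo_m": edges[:-1], "x_hi_m": edges[1:],
                             "count": counts})
        path = out / "position_histogram.csv"
        hist.to_csv(path, index=False)
        done["histogram"] = str(path)
        model_box["summary"] = {
            "first_arrival_s": fa,
            "occupancy": pt.channel_occupancy(traj, t_snap),
            "mean_cell_speed_channels_m_s":
                pt.mean_cell_speed(traj, region="channels"),
        }

    @stage("velocimetry")
    def _velocimetry():
        traj = model_box.get("traj")
        if traj is None:
            return
        vcfg = config.velocimetry
        stack = vm.render_frames(traj, fps=config.trace.get("fps", 30.0),
                                 pixel_size=vcfg.get("pixel_size", 0.5e-6),
                                 jitter_px=vcfg.get("jitter_px", 0.5),
                                 seed=config.seeds.get("velocimetry", 1))
        cal = vm.calibrate_pixels(vm.measure_channel_width_px(stack),
                                  stack.true_channel_width)
        ref = model_box.get("summary", {}).get("mean_cell_speed_channels_m_s")
        u_center = 1.5 * model_box["model"].channel_mean_velocity(config.inlet_velocity)
        res = vm.estimate_speeds(stack, cal, expected_speed=u_center,
                                 reference_speed=ref)
        path = out / "velocimetry.json"
        path.write_text(json.dumps({
            "mean_speed_m_s": res.mean_speed, "n_tracks": len(res.track_speeds),
            "n_links": res.n_links, "calibration_m_per_px": res.calibration,
            "percentage_error_vs_trace": res.percentage_error_vs}, indent=2))
        done["velocimetry"] = str(path)

    @stage("report")
    def _report():
        manifest = {
            "config_digest": config.digest(),
            "seeds": config.seeds,
            "inlet_velocity_m_s": (config.inlet_velocity
                                   if (config.inlet_velocity_m_s is not None
                                       or config.flow_rate_m3_s is not None) else None),
            "solver_residuals": {},
            "summary": model_box.get("summary", {}),
        }
        model = model_box.get("model")
        if model is not None:
            if model._post_patch is not None:
                manifest["solver_residuals"]["post_patch"] = \
                    model.post_patch.meta["linear_residual"]
            if model._header_patch is not None:
                manifest["solver_residuals"]["header_patch"] = \
                    model.header_patch.meta["linear_residual"]
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, default=float))
        done["manifest"] = str(path)

    return done


def compare_to_reference(sweep: pd.DataFrame, reference: pd.DataFrame | None = None,
                         tolerance: float = 0.15) -> pd.DataFrame:
    """Relative deviation of a sweep against a reference table.

    ``sweep`` uses the summary-CSV schema; the reference defaults to the
    packaged published tables.  Raises on missing rows; flags deviations
    beyond ``tolerance``.
    """
    ref = reference_tables() if reference is None else reference
    rows = []
    for _, r in ref.iterrows():
        m = sweep[(np.isclose(sweep["chip_width_um"], r["chip_width_um"]))
                  & (np.isclose(sweep["v_inlet_m_s"], r["v_inlet_m_s"], rtol=1e-6))]
        if len(m) == 0:
            raise KeyError(f"sweep is missing row chip={r['chip_width_um']} "
                           f"v_inlet={r['v_inlet_m_s']}")
        m = m.iloc[0]
        if r["table"] == "avg":
            pairs = [("shear", m["shear_avg_dyn_cm2"], r["shear_dyn_cm2"]),
                     ("velocity", m["vel_avg_m_s"], r["vel_m_s"])]
        else:
            pairs = [("shear", m["shear_max_dyn_cm2"], r["shear_dyn_cm2"]),
                     ("velocity", m["vel_max_m_s"], r["vel_m_s"])]
        for qty, ours, ref_v in pairs:
            dev = (ours - ref_v) / ref_v
            rows.append({"table": r["table"], "chip_width_um": r["chip_width_um"],
                         "v_inlet_m_s": r["v_inlet_m_s"], "quantity": qty,
                         "model": ours, "reference": ref_v,
                         "rel_deviation": dev,
                         "within_tolerance": abs(dev) <= tolerance})
    return pd.DataFrame(rows)
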