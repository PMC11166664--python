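"""Scenario configuration, the built-in scenario registry, and the runnable
pipeline: mesh -> transient flow -> thermal transport -> reporting.

A scenario is a fully resolved :class:`ScenarioConfig`; the registry bundles
the arterial rupture case (``paper_rupture``, with and without nanoparticle
loading) and the verification cases whose exact answers are known in closed
form (plane/axisymmetric Poiseuille, uniform-temperature invariance, steady
conduction, manufactured-solution convergence).  ``run_scenario`` executes a
config deterministically and returns a :class:`RunReport` carrying per-step
conservation logs, extremes tables, and pass/fail verification verdicts.
"""
from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field, replace
from importlib import resources
from io import StringIO
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .flow import FlowBCs, FlowSolver, FlowSolverConfig, StepLog
from .geometry import (MeshSizing, VesselGeometry, build_geometry, generate_mesh,
                       rectangle_mesh)
from .postprocess import ExtremesTable, Snapshot, export_fields, extremes
from .properties import Loading, effective_bundle, material_table
from .thermal import ThermalBCs, ThermalConfig, ThermalSolver, viscous_dissipation_field

__all__ = [
    "ScenarioConfig",
    "RunReport",
    "load_config",
    "dump_config",
    "builtin_scenarios",
    "run_scenario",
    "compare_extremes",
    "reference_extremes",
]


@dataclass(frozen=True)
class MaterialsConfig:
    path: Optional[str] = None
    base: str = "blood"
    species1: str = "gold"
    species2: str = "silver"
    corrected_silver_cp: bool = False


@dataclass(frozen=True)
class StructuredMesh:
    """Structured-rectangle meshing override (verification scenarios)."""

    nz: int = 28
    nx: int = 8


@dataclass(frozen=True)
class RunOptions:
    kind: str = "rupture"  # rupture | poiseuille_channel | poiseuille_tube |
    #                        uniform_thermal | conduction_strip | mms
    steady: bool = False
    run_thermal: bool = True
    output_times: tuple = (0.0, 0.4, 0.8, 1.2, 2.4)
    outdir: Optional[str] = None
    seed: int = 0


@dataclass(frozen=True)
class ScenarioConfig:
    name: str = "paper_rupture"
    geometry: VesselGeometry = field(default_factory=VesselGeometry)
    sizing: MeshSizing = field(default_factory=MeshSizing)
    structured: Optional[StructuredMesh] = None
    loading: Loading = field(default_factory=lambda: Loading(0.01, 0.01))
    materials: MaterialsConfig = field(default_factory=MaterialsConfig)
    flow: FlowBCs = field(default_factory=FlowBCs)
    solver: FlowSolverConfig = field(default_factory=FlowSolverConfig)
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    thermal_bcs: ThermalBCs = field(default_factory=ThermalBCs)
    run: RunOptions = field(default_factory=RunOptions)

    def __post_init__(self) -> None:
        if not self.run.steady:
            for t in self.run.output_times:
                if t > self.solver.t_end + 1e-12:
                    raise ValueError(
                        f"output time {t} exceeds t_end={self.solver.t_end}")
        if abs(self.thermal.dt - self.solver.dt) > 1e-15:
            raise ValueError("thermal dt must match the flow dt")

    def reporting_line(self) -> tuple:
        """Default line-graph segment: the channel midline."""
        g = self.geometry
        return ((0.0, g.height / 2), (g.length, g.height / 2), 201)


_SECTION_TYPES = {
    "geometry": VesselGeometry,
    "sizing": MeshSizing,
    "structured": StructuredMesh,
    "loading": Loading,
    "materials": MaterialsConfig,
    "flow": FlowBCs,
    "solver": FlowSolverConfig,
    "thermal": ThermalConfig,
    "thermal_bcs": ThermalBCs,
    "run": RunOptions,
}


class ConfigError(ValueError):
    pass


def _build_section(cls, data: dict, base=None):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if base is not None:
        merged = {**dataclasses.asdict(base), **data}
    else:
        merged = data
    if cls is RunOptions and "output_times" in merged and merged["output_times"] is not None:
        merged["output_times"] = tuple(merged["output_times"])
    return cls(**merged)


def load_config(path=None, overrides: Optional[dict] = None) -> ScenarioConfig:
    """Resolve a scenario config from a YAML file (or a dict of overrides)
    over the ``paper_rupture`` defaults.  Unknown keys are hard errors."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict):
                data.setdefault(k, {}).update(v)
            else:
                data[k] = v
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    base = ScenarioConfig()
    unknown = set(data) - set(_SECTION_TYPES) - {"name"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {"name": data.get("name", base.name)}
    for sec, cls in _SECTION_TYPES.items():
        if sec in data and data[sec] is not None:
            if not isinstance(data[sec], dict):
                raise ConfigError(f"section {sec!r} must be a mapping")
            base_sec = getattr(base, sec)
            kwargs[sec] = _build_section(cls, data[sec], base_sec)
        else:
            kwargs[sec] = getattr(base, sec)
    return ScenarioConfig(**kwargs)


def dump_config(config: ScenarioConfig) -> str:
    """Serialize a config to normalized YAML (round-trips through
    :func:`load_config`)."""
    d = dataclasses.asdict(config)
    d["run"]["output_times"] = list(d["run"]["output_times"])
    return yaml.safe_dump(d, sort_keys=True)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """Named, fully resolved study and verification scenarios."""
    rupture = ScenarioConfig()
    no_part = replace(rupture, name="paper_rupture_no_particles",
                      loading=Loading(0.0, 0.0))
    channel = ScenarioConfig(
        name="poiseuille_channel",
        geometry=VesselGeometry(has_sac=False, has_orifice=False),
        structured=StructuredMesh(28, 8),
        loading=Loading(0.0, 0.0),
        flow=FlowBCs(inlet_profile="parabolic"),
        run=RunOptions(kind="poiseuille_channel", steady=True,
                       run_thermal=False, output_times=()),
    )
    tube = ScenarioConfig(
        name="poiseuille_tube_axisym",
        geometry=VesselGeometry(length=0.7, height=0.045, mode="axisymmetric",
                                has_sac=False, has_orifice=False),
        structured=StructuredMesh(28, 8),
        loading=Loading(0.0, 0.0),
        flow=FlowBCs(inlet_profile="parabolic"),
        run=RunOptions(kind="poiseuille_tube", steady=True,
                       run_thermal=False, output_times=()),
    )
    uniform = ScenarioConfig(
        name="uniform_thermal",
        thermal=ThermalConfig(include_dissipation=False),
        run=RunOptions(kind="uniform_thermal", output_times=(0.0, 1.2, 2.4)),
    )
    strip = ScenarioConfig(
        name="conduction_strip",
        geometry=VesselGeometry(has_sac=False, has_orifice=False),
        structured=StructuredMesh(20, 4),
        loading=Loading(0.0, 0.0),
        flow=FlowBCs(v0=0.0),
        thermal=ThermalConfig(include_dissipation=False, supg=False),
        thermal_bcs=ThermalBCs(T_inlet=310.0, pinned={"OUTLET": 300.0}),
        run=RunOptions(kind="conduction_strip", steady=True, output_times=()),
    )
    mms = ScenarioConfig(
        name="mms_convergence",
        geometry=VesselGeometry(length=1.0, height=1.0, has_sac=False,
                                has_orifice=False),
        run=RunOptions(kind="mms", steady=True, run_thermal=False,
                       output_times=()),
    )
    return {s.name: s for s in (rupture, no_part, channel, tube, uniform,
                                strip, mms)}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class Verdict:
    check: str
    measured: float
    tolerance: float
    passed: bool

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    config: ScenarioConfig
    mesh_stats: dict
    step_logs: list
    extremes_domain: Optional[ExtremesTable]
    extremes_line: Optional[ExtremesTable]
    verdicts: list
    artifacts: list
    snapshots: list = field(default_factory=list)
    mesh: object = None
    mms_orders: Optional[list] = None

    @property
    def passed(self) -> bool:
        return all(v.passed for v in self.verdicts)

    def verdicts_json(self) -> str:
        return json.dumps({"scenario": self.config.name,
                           "passed": self.passed,
                           "checks": [v.as_dict() for v in self.verdicts]},
                          indent=2)


def _props_for(config: ScenarioConfig):
    mats = material_table(config.materials.path,
                          corrected_silver_cp=config.materials.corrected_silver_cp)
    m = config.materials
    return effective_bundle(mats[m.base], mats[m.species1], mats[m.species2],
                            config.loading)


def _mesh_for(config: ScenarioConfig):
    if config.structured is not None:
        g = config.geometry
        return rectangle_mesh(g.length, g.height, config.structured.nz,
                              config.structured.nx, mode=g.mode)
    return generate_mesh(build_geometry(config.geometry), config.sizing,
                         seed=config.run.seed)


def _snapshot(mesh, flow_state, thermal_state, props, space) -> Snapshot:
    nv = mesh.n_nodes
    return Snapshot(
        t=flow_state.t if flow_state is not None else thermal_state.t,
        velocity=flow_state.velocity[:nv].copy(),
        pressure=flow_state.pressure.copy(),
        temperature=(thermal_state.temperature.copy()
                     if thermal_state is not None else None),
        dissipation=viscous_dissipation_field(flow_state, props, mesh, space=space),
    )


def run_scenario(config: ScenarioConfig, log_every: int = 0) -> RunReport:
    """Execute one scenario end to end; deterministic for identical configs."""
    from .geometry import quality_report

    if config.run.kind == "mms":
        from .verification import convergence_study
        res = convergence_study()
        verdicts = [Verdict("mms_velocity_order", res.order_u, 2.8,
                            res.order_u >= 2.8)]
        return RunReport(config=config, mesh_stats={}, step_logs=[],
                         extremes_domain=None, extremes_line=None,
                         verdicts=verdicts, artifacts=[],
                         mms_orders=res.orders_u)

    props = _props_for(config)
    mesh = _mesh_for(config)
    qr = quality_report(mesh)
    solver = FlowSolver(mesh, props, config.flow, config.solver)
    thermal = None
    if config.run.run_thermal:
        thermal = ThermalSolver(mesh, props, config.thermal_bcs, config.thermal,
                                space=solver.space)

    step_logs: list[StepLog] = []
    snapshots: list[Snapshot] = []
    if config.run.steady:
        flow_state = solver.solve_steady()
        flow_state.t = 0.0
        T_state = thermal.solve_steady(flow_state) if thermal is not None else None
        if T_state is not None:
            T_state.t = 0.0
        snapshots.append(_snapshot(mesh, flow_state, T_state, props, solver.space))
        step_logs.append(solver.step_log(flow_state))
    else:
        dt, t_end = config.solver.dt, config.solver.t_end
        n_steps = int(round(t_end / dt))
        out_times = sorted(config.run.output_times)
        flow_state, prev_flow = solver.initial_state(), None
        T_state = thermal.initial_state() if thermal is not None else None
        prev_T = None
        if out_times and abs(out_times[0]) < dt / 2:
            snapshots.append(_snapshot(mesh, flow_state, T_state, props, solver.space))
        for k in range(n_steps):
            new_flow = solver.step(flow_state, prev_flow)
            prev_flow, flow_state = flow_state, new_flow
            if thermal is not None:
                new_T = thermal.step(T_state, flow_state, prev_T, prev_flow)
                prev_T, T_state = T_state, new_T
            lg = solver.step_log(flow_state)
            step_logs.append(lg)
            if log_every and (k + 1) % log_every == 0:
                print(f"  t={lg.t:.3f} picard={lg.picard_iters} "
                      f"res={lg.residual:.2e} fluxbal={lg.flux_balance:.2e}")
            matched = [t for t in out_times if abs(flow_state.t - t) < dt / 2]
            if matched:
                snap = _snapshot(mesh, flow_state, T_state, props, solver.space)
                snap.t = matched[0]  # report the nominal output time
                snapshots.append(snap)

    line = config.reporting_line()
    table_domain = table_line = None
    if snapshots:
        times = [s.t for s in snapshots]
        table_domain = extremes(snapshots, times)
        table_line = extremes(snapshots, times, line=line, mesh=mesh)

    verdicts = _verdicts(config, props, mesh, solver, thermal, snapshots,
                         step_logs)
    artifacts = []
    if config.run.outdir:
        os.makedirs(config.run.outdir, exist_ok=True)
        artifacts = export_fields(snapshots, mesh, config.run.outdir, line=line)
        vpath = os.path.join(config.run.outdir, "verdicts.json")
        with open(vpath, "w") as fh:
            fh.write(RunReport(config, {}, [], None, None, verdicts, []).verdicts_json())
        artifacts.append(vpath)
        cpath = os.path.join(config.run.outdir, "config.yaml")
        with open(cpath, "w") as fh:
            fh.write(dump_config(config))
        artifacts.append(cpath)
        lpath = os.path.join(config.run.outdir, "run.log")
        with open(lpath, "w") as fh:
            for lg in step_logs:
                fh.write(f"t={lg.t:.6g} picard={lg.picard_iters} "
                         f"residual={lg.residual:.6e} div={lg.div_norm:.6e} "
                         f"fluxbal={lg.flux_balance:.6e}\n")
        artifacts.append(lpath)

    mesh_stats = {"n_elements": qr.n_elements, "n_vertices": qr.n_vertices,
                  "min_quality": qr.min_quality, "avg_quality": qr.avg_quality,
                  "total_area": qr.total_area}
    return RunReport(config=config, mesh_stats=mesh_stats, step_logs=step_logs,
                     extremes_domain=table_domain, extremes_line=table_line,
                     verdicts=verdicts, artifacts=artifacts,
                     snapshots=snapshots, mesh=mesh)


def _verdicts(config, props, mesh, solver, thermal, snapshots, step_logs):
    """Closed-form verification checks keyed by scenario kind."""
    kind = config.run.kind
    out: list[Verdict] = []
    g = config.geometry
    if kind in ("poiseuille_channel", "poiseuille_tube") and snapshots:
        snap = snapshots[-1]
        U = config.flow.v0
        peak = 2.0 if kind == "poiseuille_tube" else 1.5
        ratio = float(np.hypot(*snap.velocity.T).max()) / U
        out.append(Verdict(f"u_max_over_U_vs_{peak}", ratio, 0.01 * peak,
                           abs(ratio - peak) <= 0.01 * peak))
        from .postprocess import sample_line
        x_line = 0.0 if g.mode == "axisymmetric" else g.height / 2
        zs, ze = 0.1 * g.length, 0.9 * g.length
        p0 = sample_line(snap.pressure, mesh, (zs, x_line), (ze, x_line), 2).values
        dpdz = float((p0[0] - p0[1]) / (ze - zs))
        if kind == "poiseuille_tube":
            exact = 8.0 * props.mu * U / g.height**2
        else:
            exact = 12.0 * props.mu * U / g.height**2
        out.append(Verdict("pressure_gradient_vs_closed_form", dpdz,
                           0.02 * exact, abs(dpdz - exact) <= 0.02 * exact))
    if kind == "uniform_thermal" and snapshots:
        drift = max(float(np.abs(s.temperature - config.thermal_bcs.T_inlet).max())
                    for s in snapshots if s.temperature is not None)
        out.append(Verdict("uniform_temperature_drift_K", drift, 1e-9,
                           drift <= 1e-9))
    if kind == "conduction_strip" and snapshots:
        T = snapshots[-1].temperature
        T_in = config.thermal_bcs.T_inlet
        T_out = (config.thermal_bcs.pinned or {}).get("OUTLET", T_in)
        exact = T_in + (T_out - T_in) * mesh.nodes[:, 0] / g.length
        err = float(np.abs(T - exact).max() / max(abs(T_in), 1.0))
        out.append(Verdict("steady_conduction_profile_relerr", err, 1e-6,
                           err <= 1e-6))
    if kind == "rupture" and step_logs:
        worst = max(lg.flux_balance for lg in step_logs)
        out.append(Verdict("mass_flux_balance", worst, 1e-6, worst <= 1e-6))
    return out


# ---------------------------------------------------------------------------
# reported-table comparison
# ---------------------------------------------------------------------------

def reference_extremes() -> pd.DataFrame:
    """The bundled reported line-graph extremes table (see the CSV header for
    interpretation caveats)."""
    text = resources.files("sacflow.data").joinpath("table4_reference.csv").read_text()
    return pd.read_csv(StringIO(text), comment="#")


def compare_extremes(table: ExtremesTable,
                     reference: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Signed relative deviation (ours - reference) / reference per cell, for
    the times present in both tables.  Raises on a time mismatch."""
    ref = reference_extremes() if reference is None else reference
    ours = table.frame.set_index("t")
    cols = [c for c in ref.columns if c != "t"]
    rows = []
    for _, r in ref.iterrows():
        t = r["t"]
        match = ours.index[np.isclose(ours.index.to_numpy(), t, atol=1e-9)]
        if len(match) == 0:
            raise ValueError(f"no computed row at reference time t={t}")
        mine = ours.loc[match[0]]
        rows.append({"t": t, **{c: (mine[c] - r[c]) / r[c] for c in cols}})
    return pd.DataFrame(rows)
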