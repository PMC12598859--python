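"""Scenario orchestration: trajectory ensembles and their analysis.

:func:`run_experiment` equilibrates a scenario, generates an ensemble of
independent driven/active trajectories (one derived random stream per
trajectory, so any execution order gives identical results), integrates the
local dissipation on a slab (or grid) record partition, and writes a
long-format ensemble CSV plus a manifest; interrupted runs resume from the
manifest and produce byte-identical final files.

:func:`analyze_experiment` turns an ensemble directory into asymmetry
curves, origin-constrained slope fits, kappa estimates with bootstrap
errors, local fluctuation-theorem consistency reports, a kappa(L) scan,
and (for grid records) spatial maps, all summarized in one JSON file.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import __version__
from .dissipation import (CSV_COLUMNS, DissipationSample, EnsembleTable,
                          integrate_dissipation, load_ensemble)
from .dynamics import (IntegratorConfig, build_initial_state, draw_momenta,
                       equilibrate, run_trajectory, trajectory_rng)
from .flucstats import (InsufficientNegativeEvents, asymmetry_function,
                        dissipation_map, kappa, kappa_scan, local_ft_check)
from .interactions import write_extxyz
from .model import (RegionPartition, ScenarioSpec, ValidationError,
                    make_scenario)

logger = logging.getLogger("localft")

__all__ = ["ExperimentPlan", "run_experiment", "analyze_experiment",
           "DEFAULT_DURATION", "default_record_cells"]

#: Trajectory durations used by the three study conditions.
DEFAULT_DURATION = {"channel": 5.0, "obstacle": 5.0, "active": 3.0}

#: Default number of record slabs per scenario (record width = Lx / cells).
_DEFAULT_RECORD_CELLS = {"channel": 25, "obstacle": 20, "active": 10}


def default_record_cells(kind: str) -> int:
    return _DEFAULT_RECORD_CELLS[kind]


@dataclass
class ExperimentPlan:
    """A fully specified ensemble computation.

    ``analysis_widths`` lists the local-region sizes L (each an integer
    multiple of the record slab width); the local region of size L is the
    contiguous block of record slabs centered on the box center.  A
    ``grid_shape`` switches the record partition to a 2D grid for mapping
    runs (slab analyses are then unavailable).
    """

    scenario: ScenarioSpec
    n_trajectories: int
    duration: float | None = None
    base_seed: int = 0
    record_cells: int | None = None
    analysis_widths: list = dc_field(default_factory=list)
    grid_shape: tuple | None = None
    n_equilibrium: int = 100
    equil_spacing: float = 5.0
    burn_in: float = 50.0
    bin_width: float | None = None
    min_count: int = 10
    dump_xyz: bool = False

    def __post_init__(self):
        if self.n_trajectories < 1:
            raise ValidationError("n_trajectories must be >= 1")
        if self.duration is None:
            self.duration = DEFAULT_DURATION[self.scenario.kind]
        if self.record_cells is None:
            self.record_cells = default_record_cells(self.scenario.kind)
        lx = self.scenario.params.box_lengths[0]
        w = lx / self.record_cells
        if not self.analysis_widths and self.grid_shape is None:
            self.analysis_widths = [w]
        for L in self.analysis_widths:
            m = L / w
            if abs(m - round(m)) > 1e-6 or not (0 < round(m) <= self.record_cells):
                raise ValidationError(
                    f"analysis width {L} is not a multiple of the record "
                    f"slab width {w:.6g}")

    @property
    def record_partition(self) -> RegionPartition:
        lx, ly = self.scenario.params.box_lengths
        if self.grid_shape is not None:
            return RegionPartition.grid((lx, ly), self.grid_shape)
        return RegionPartition(mode="slabs_x",
                               cell_size=(lx / self.record_cells,),
                               n_cells=(self.record_cells,))

    def local_cells(self, width: float) -> list[int]:
        """Record-slab indices of the centered local region of size L."""
        lx = self.scenario.params.box_lengths[0]
        w = lx / self.record_cells
        m = int(round(width / w))
        start = int(round(lx / (2 * w) - m / 2.0)) % self.record_cells
        return [(start + i) % self.record_cells for i in range(m)]

    def to_config(self) -> dict:
        return {
            "version": __version__,
            "scenario": self.scenario.to_dict(),
            "n_trajectories": self.n_trajectories,
            "duration": self.duration,
            "base_seed": self.base_seed,
            "record_cells": self.record_cells,
            "analysis_widths": list(map(float, self.analysis_widths)),
            "grid_shape": list(self.grid_shape) if self.grid_shape else None,
            "n_equilibrium": self.n_equilibrium,
            "equil_spacing": self.equil_spacing,
            "burn_in": self.burn_in,
            "bin_width": self.bin_width,
            "min_count": self.min_count,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "ExperimentPlan":
        return cls(scenario=ScenarioSpec.from_dict(cfg["scenario"]),
                   n_trajectories=cfg["n_trajectories"],
                   duration=cfg["duration"], base_seed=cfg["base_seed"],
                   record_cells=cfg["record_cells"],
                   analysis_widths=list(cfg["analysis_widths"]),
                   grid_shape=tuple(cfg["grid_shape"]) if cfg.get("grid_shape")
                   else None,
                   n_equilibrium=cfg["n_equilibrium"],
                   equil_spacing=cfg["equil_spacing"],
                   burn_in=cfg["burn_in"], bin_width=cfg.get("bin_width"),
                   min_count=cfg.get("min_count", 10))


def _csv_row(fh, tid, seed, t, b, om, fe, xi, nn):
    fh.write(f"{tid},{seed},{t!r},{b},{om!r},{fe!r},{xi!r},{nn!r}\n")


def run_experiment(plan: ExperimentPlan, out_dir) -> dict:
    """Generate (or resume) the ensemble described by ``plan``.

    Writes ``config.json``, ``scenario.toml``, ``ensemble.csv`` (long
    format), ``current_series.csv`` (per-trajectory global-current
    relaxation), and ``manifest.json``.  Trajectory ``i`` uses the random
    stream derived from ``(base_seed, i)`` and starts from equilibrium
    snapshot ``i mod n_equilibrium`` with fresh Maxwell momenta, so a
    resumed run reproduces an uninterrupted one exactly.
    """
    os.makedirs(out_dir, exist_ok=True)
    spec = plan.scenario
    cfg_path = os.path.join(out_dir, "config.json")
    manifest_path = os.path.join(out_dir, "manifest.json")
    ens_path = os.path.join(out_dir, "ensemble.csv")
    cur_path = os.path.join(out_dir, "current_series.csv")

    config = plan.to_config()
    if os.path.exists(cfg_path):
        with open(cfg_path) as fh:
            if json.load(fh) != config:
                raise ValidationError(
                    f"{out_dir} holds a different experiment; refusing to mix")
    else:
        with open(cfg_path, "w") as fh:
            json.dump(config, fh, indent=1, sort_keys=True)
        with open(os.path.join(out_dir, "scenario.toml"), "w") as fh:
            fh.write(spec.to_toml())
    logger.info("localft %s experiment in %s: %s", __version__, out_dir,
                json.dumps(config["scenario"]))

    done = -1
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            done = json.load(fh)["last_completed"]
    if done < 0:
        header = "# config: " + json.dumps(
            dict(config, duration=plan.duration), sort_keys=True) + "\n"
        with open(ens_path, "w") as fh:
            fh.write(header)
            fh.write(",".join(CSV_COLUMNS) + "\n")
        with open(cur_path, "w") as fh:
            fh.write("# global color current at sampled times, one row per "
                     "trajectory\n")

    nsteps = int(round(plan.duration / spec.params.timestep))
    stride = max(1, nsteps // 50)
    icfg = IntegratorConfig(sample_stride=stride)
    part = plan.record_partition

    snapshots = equilibrate(spec, plan.n_equilibrium,
                            spacing=plan.equil_spacing, seed=plan.base_seed,
                            burn_in=plan.burn_in)
    for i in range(done + 1, plan.n_trajectories):
        rng = trajectory_rng(plan.base_seed, i)
        start = snapshots[i % len(snapshots)].copy()
        draw_momenta(start, spec, rng)
        if spec.activity_enabled:
            fluid = start.wall_flag == 0
            start.ou_value = np.zeros(start.n_particles)
            start.ou_value[fluid] = spec.params.ou_amplitude * \
                rng.standard_normal(int(fluid.sum()))
        if plan.dump_xyz and i < 10:
            write_extxyz(os.path.join(out_dir, "trajectories.xyz"), start,
                         spec.params.box_lengths, comment=f"traj={i} start")
        rec = run_trajectory(start, spec, plan.duration, icfg, seed=rng,
                             part=part)
        if plan.dump_xyz and i < 10:
            write_extxyz(os.path.join(out_dir, "trajectories.xyz"),
                         rec.final_state, spec.params.box_lengths,
                         comment=f"traj={i} end")
        samp = integrate_dissipation(rec, spec.params)
        with open(ens_path, "a") as fh:
            _csv_row(fh, i, i, plan.duration, -1, samp.omega_total,
                     samp.omega_fe_total, samp.omega_xi_total,
                     float(samp.n_avg_bins.sum()))
            for b in range(part.total_cells):
                _csv_row(fh, i, i, plan.duration, b,
                         float(samp.omega_bins[b]),
                         float(samp.omega_fe_bins[b]),
                         float(samp.omega_xi_bins[b]),
                         float(samp.n_avg_bins[b]))
        with open(cur_path, "a") as fh:
            fh.write(",".join(repr(float(v))
                              for v in rec.j_series.sum(axis=1)) + "\n")
        with open(manifest_path, "w") as fh:
            json.dump({"last_completed": i,
                       "n_trajectories": plan.n_trajectories,
                       "complete": i == plan.n_trajectories - 1}, fh)
    return {"out_dir": str(out_dir), "ensemble": ens_path,
            "config": cfg_path, "manifest": manifest_path}


def _analyze_region(table: EnsembleTable, cells, bin_width, min_count,
                    seed, components) -> dict:
    local, comp = table.local_and_complement(cells)
    entry: dict = {"cells": list(map(int, cells))}
    if np.var(comp) < 1e-24:
        entry["kappa"], entry["kappa_err"] = 0.0, 0.0
    else:
        try:
            entry["kappa"], entry["kappa_err"] = kappa(local, comp, seed=seed)
        except ValidationError as exc:
            entry["kappa"] = None
            entry["kappa_note"] = str(exc)
            return entry
    for name, mat in components.items():
        vals = mat[:, cells].sum(axis=1) if name != "total" else local
        try:
            curve = asymmetry_function(vals, bin_width=bin_width,
                                       min_count=min_count)
            rep = local_ft_check(curve, entry["kappa"], entry["kappa_err"])
            rep["curve"] = {
                "A": curve.a_values.tolist(),
                "log_ratio": curve.log_ratio.tolist(),
                "stderr": curve.stderr.tolist(),
                "bin_width": curve.bin_width,
            }
            entry[name] = rep
        except InsufficientNegativeEvents:
            entry[name] = "global-FT regime, asymmetry unavailable"
        except ValidationError as exc:
            entry[name] = f"asymmetry unavailable: {exc}"
    return entry


def analyze_experiment(out_dir, bin_width: float | None = None,
                       min_count: int | None = None,
                       widths: list | None = None) -> dict:
    """Analyze an ensemble directory and write ``summary.json``.

    For every requested local-region size L: kappa with bootstrap error,
    asymmetry curves and origin-constrained slopes for the total local
    dissipation and (active scenario) its deterministic and stochastic
    components, and the slope-vs-(1 + kappa) consistency report.  Also
    writes ``kappa_scan.csv``, ``current_relaxation.csv``, per-L asymmetry
    CSVs, and ``map.csv`` for grid-partition ensembles.
    """
    cfg_path = os.path.join(out_dir, "config.json")
    if not os.path.exists(cfg_path):
        raise ValidationError(
            f"no experiment found in {out_dir} (missing config.json); "
            "run the experiment first")
    with open(cfg_path) as fh:
        config = json.load(fh)
    plan = ExperimentPlan.from_config(config)
    table = load_ensemble(os.path.join(out_dir, "ensemble.csv"))
    spec = plan.scenario
    table.meta.setdefault("beta", spec.params.inverse_temperature)
    table.meta.setdefault("field_strength", spec.params.field_strength)
    bin_width = bin_width if bin_width is not None else plan.bin_width
    min_count = min_count if min_count is not None else plan.min_count

    tot = table.omega_total
    n = len(tot)
    summary: dict = {
        "scenario": spec.kind,
        "n_trajectories": n,
        "duration": plan.duration,
        "global": {
            "mean_omega": float(tot.mean()),
            "se_omega": float(tot.std(ddof=1) / math.sqrt(n)) if n > 1 else None,
            "frac_negative": float(np.mean(tot < 0)),
        },
    }
    try:
        gcurve = asymmetry_function(tot, bin_width=bin_width,
                                    min_count=min_count)
        summary["global"]["asymmetry"] = local_ft_check(gcurve, 0.0, 0.0)
    except InsufficientNegativeEvents:
        summary["global"]["asymmetry"] = \
            "global-FT regime, asymmetry unavailable"
    except ValidationError as exc:
        summary["global"]["asymmetry"] = f"asymmetry unavailable: {exc}"

    if plan.grid_shape is not None:
        part = plan.record_partition
        dmap = dissipation_map(table, part)
        _write_map_csv(os.path.join(out_dir, "map.csv"), dmap)
        summary["map"] = {"grid_shape": list(plan.grid_shape),
                          "cells_missing": int(dmap.missing.sum())}
    else:
        components = {"total": table.omega}
        if spec.kind == "active":
            components["fe"] = table.omega_fe
            components["xi"] = table.omega_xi
        widths = widths or plan.analysis_widths
        locals_out = []
        scan_input = {}
        for L in widths:
            cells = plan.local_cells(L)
            entry = _analyze_region(table, cells, bin_width, min_count,
                                    seed=plan.base_seed + 7,
                                    components=components)
            entry["L"] = float(L)
            locals_out.append(entry)
            scan_input[float(L)] = table.local_and_complement(cells)
            _write_curves_csv(out_dir, entry)
        summary["locals"] = locals_out
        if len(scan_input) >= 2:
            scan = kappa_scan(scan_input, seed=plan.base_seed + 11)
            with open(os.path.join(out_dir, "kappa_scan.csv"), "w") as fh:
                fh.write("L,kappa,stderr,n\n")
                for i in range(len(scan.lengths)):
                    fh.write(f"{scan.lengths[i]!r},{scan.kappa[i]!r},"
                             f"{scan.stderr[i]!r},{scan.n_samples[i]}\n")

    _write_relaxation_csv(out_dir, plan)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return summary


def _write_curves_csv(out_dir, entry: dict) -> None:
    for name in ("total", "fe", "xi"):
        rep = entry.get(name)
        if not isinstance(rep, dict):
            continue
        fn = os.path.join(out_dir, f"asymmetry_L{entry['L']:g}_{name}.csv")
        with open(fn, "w") as fh:
            fh.write("A,log_ratio,stderr\n")
            c = rep["curve"]
            for a, y, e in zip(c["A"], c["log_ratio"], c["stderr"]):
                fh.write(f"{a!r},{y!r},{e!r}\n")


def _write_map_csv(path, dmap) -> None:
    nx, ny = dmap.partition.n_cells
    with open(path, "w") as fh:
        fh.write("# row-major grid, origin at the box corner\n")
        fh.write("ix,iy,mean_omega,se_omega,mean_current,mean_count\n")
        for iy in range(ny):
            for ix in range(nx):
                c = ix + nx * iy
                fh.write(f"{ix},{iy},{dmap.mean_omega[c]!r},"
                         f"{dmap.se_omega[c]!r},{dmap.mean_current[c]!r},"
                         f"{dmap.mean_count[c]!r}\n")


def _write_relaxation_csv(out_dir, plan: ExperimentPlan) -> None:
    cur_path = os.path.join(out_dir, "current_series.csv")
    if not os.path.exists(cur_path):
        return
    rows = np.loadtxt(cur_path, delimiter=",", comments="#", ndmin=2)
    if rows.size == 0:
        return
    nsteps = int(round(plan.duration / plan.scenario.params.timestep))
    stride = max(1, nsteps // 50)
    times = plan.scenario.params.timestep * stride * np.arange(rows.shape[1])
    mean = rows.mean(axis=0)
    se = rows.std(axis=0, ddof=1) / math.sqrt(rows.shape[0]) \
        if rows.shape[0] > 1 else np.zeros_like(mean)
    with open(os.path.join(out_dir, "current_relaxation.csv"), "w") as fh:
        fh.write("time,mean_current,stderr\n")
        for t, m, s in zip(times, mean, se):
            fh.write(f"{t!r},{m!r},{s!r}\n")
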