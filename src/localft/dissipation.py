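"""Dissipation and entropy-production bookkeeping.

For the color-field-driven systems the dissipation function of a trajectory
of duration t, restricted to a slab (or grid cell) of size L, is

    Omega_{L,t} = beta F_e J_{x,L,t},

with J_{x,L,t} the time integral of the instantaneous local color current
j_{x,L} = sum_{i in cell} c_i p_{x,i} / m_i, each particle attributed to
the cell containing its instantaneous wrapped position.  For the active
(AOUP) scenario the dissipation splits into a deterministic (field) and an
active stochastic part,

    Omega = Omega_Fe + Omega_xi
          = beta F_e J_x + beta * integral of sum_i xi_i p_{x,i} dt,

localized the same way.  Under the Gaussian ergostat (obstacle scenario)
dH/dt = 0, so the dissipation equals the entropy production Sigma_{L,t}.

Instantaneous-position attribution makes the partition identity
sum_bins Omega_{L,t} = Omega_t hold at every instant, and the complement is
defined as Omega*_{L,t} = Omega_t - Omega_{L,t} exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .interactions import ForceField, obstacle_force, tether_force, wca_pair
from .model import (ModelParams, RegionPartition, ScenarioSpec,
                    SimulationState, ValidationError, assign_bins)
from .dynamics import TrajectoryRecord

__all__ = [
    "DissipationSample",
    "EnsembleTable",
    "instantaneous_current",
    "integrate_dissipation",
    "total_energy",
    "save_ensemble",
    "load_ensemble",
]


@dataclass
class DissipationSample:
    """Per-trajectory integrated dissipation, globally and per bin.

    ``omega_bins`` is Omega_{L,t} per cell; ``omega_star_bins`` the
    complement Omega* = Omega_t - Omega_{L,t}; ``omega_fe_bins`` and
    ``omega_xi_bins`` the deterministic and active components (the latter is
    zero outside the active scenario); ``sigma_bins`` the entropy production
    (equal to Omega by construction under the ergostat); ``n_avg_bins`` the
    time-averaged fluid particle count per cell.
    """

    duration: float
    omega_total: float
    omega_bins: np.ndarray
    omega_star_bins: np.ndarray
    omega_fe_total: float
    omega_fe_bins: np.ndarray
    omega_xi_total: float
    omega_xi_bins: np.ndarray
    sigma_bins: np.ndarray
    n_avg_bins: np.ndarray
    partition: RegionPartition
    seed: int = -1
    trajectory_id: int = -1


def instantaneous_current(state: SimulationState, part: RegionPartition,
                          box) -> np.ndarray:
    """Per-cell instantaneous color current j_{x,L} (unit masses).

    Summing the cells gives the global current J_x = sum_i c_i p_{x,i}.
    """
    idx = assign_bins(state, part, box)
    contrib = state.color_charge.astype(np.float64) * state.momenta[:, 0]
    out = np.zeros(part.total_cells)
    np.add.at(out, idx, contrib)
    return out


def _aggregate_map(rec_part: RegionPartition, part: RegionPartition,
                   box) -> np.ndarray:
    """Map record cells onto (coarser, aligned) analysis cells."""
    if rec_part.mode != "slabs_x" or part.mode != "slabs_x":
        raise ValidationError(
            "re-binning a record is supported for slabs_x partitions only")
    edges = rec_part.bin_edges_x(box[0])
    target = np.empty(rec_part.n_cells[0], dtype=np.int64)
    for i in range(rec_part.n_cells[0]):
        left, right = edges[i], edges[i + 1]
        tl = int(np.floor((left + 1e-9) / part.cell_size[0]))
        tr = int(np.floor((right - 1e-9) / part.cell_size[0]))
        tl = min(tl, part.n_cells[0] - 1)
        tr = min(tr, part.n_cells[0] - 1)
        if tl != tr:
            raise ValidationError(
                "analysis partition edges do not align with the record "
                f"partition (record cell [{left}, {right}) straddles a "
                "boundary)")
        target[i] = tl
    return target


def integrate_dissipation(rec: TrajectoryRecord, params: ModelParams,
                          part: RegionPartition | None = None,
                          duration: float | None = None) -> DissipationSample:
    """Turn a trajectory record into a :class:`DissipationSample`.

    The record already carries full-resolution trapezoidal time integrals of
    the per-cell current and propulsion-power integrands; this routine
    applies the beta F_e prefactors, optionally re-bins onto a coarser
    aligned slab partition, and forms the complement and component splits.
    """
    if duration is not None and abs(duration - rec.duration) > 1e-9:
        raise ValidationError(
            f"record duration {rec.duration} does not match requested "
            f"{duration}")
    beta = params.inverse_temperature
    f_e = params.field_strength
    box = params.box_lengths

    j_int = rec.j_integral
    xip_int = rec.xip_integral
    cnt_int = rec.cnt_integral
    out_part = rec.partition
    if part is not None and part != rec.partition:
        target = _aggregate_map(rec.partition, part, box)
        nc = part.total_cells
        j_int = np.bincount(target, weights=j_int, minlength=nc)
        xip_int = np.bincount(target, weights=xip_int, minlength=nc)
        cnt_int = np.bincount(target, weights=cnt_int, minlength=nc)
        out_part = part

    omega_fe_bins = beta * f_e * j_int
    omega_xi_bins = beta * xip_int
    omega_bins = omega_fe_bins + omega_xi_bins
    omega_total = float(omega_bins.sum())
    dur = rec.duration if rec.duration > 0 else 1.0
    return DissipationSample(
        duration=rec.duration,
        omega_total=omega_total,
        omega_bins=omega_bins,
        omega_star_bins=omega_total - omega_bins,
        omega_fe_total=float(omega_fe_bins.sum()),
        omega_fe_bins=omega_fe_bins,
        omega_xi_total=float(omega_xi_bins.sum()),
        omega_xi_bins=omega_xi_bins,
        sigma_bins=omega_bins.copy(),
        n_avg_bins=cnt_int / dur,
        partition=out_part)


def total_energy(state: SimulationState, spec_or_ff, box=None) -> float:
    """Internal energy H = sum p^2/2m + U_pair + U_tether + U_obstacle.

    The color-field coupling is not part of H.  ``spec_or_ff`` may be a
    :class:`ScenarioSpec` (box taken from it) or a :class:`ForceField` with
    an explicit ``box``.
    """
    if isinstance(spec_or_ff, ScenarioSpec):
        ff = ForceField.from_scenario(spec_or_ff)
        box = spec_or_ff.params.box_lengths
    else:
        ff = spec_or_ff
        if box is None:
            raise ValidationError("total_energy needs a box with a ForceField")
    _, u = wca_pair(state, box, periodic_y=ff.periodic_y)
    if (state.wall_flag == 1).any():
        _, u_t = tether_force(state, ff.spring_constant, box)
        u += u_t
    if ff.obstacle is not None:
        cx, cy, r = ff.obstacle
        _, u_o = obstacle_force(state, (cx, cy), r, box)
        u += u_o
    ke = 0.5 * float(np.sum(state.momenta ** 2))
    return ke + u


# ---------------------------------------------------------------------------
# Ensemble I/O
# ---------------------------------------------------------------------------

@dataclass
class EnsembleTable:
    """A dissipation ensemble as dense per-bin arrays (one row per
    trajectory)."""

    duration: float
    omega: np.ndarray       # (ntraj, ncells) total local dissipation
    omega_fe: np.ndarray    # deterministic (field) component
    omega_xi: np.ndarray    # active stochastic component
    n_avg: np.ndarray       # time-averaged particle counts
    seeds: np.ndarray
    trajectory_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_trajectories(self) -> int:
        return self.omega.shape[0]

    @property
    def omega_total(self) -> np.ndarray:
        return self.omega.sum(axis=1)

    def local_and_complement(self, cells) -> tuple[np.ndarray, np.ndarray]:
        """(Omega_L, Omega*) for a local region made of the given cells."""
        cells = np.atleast_1d(cells)
        local = self.omega[:, cells].sum(axis=1)
        return local, self.omega_total - local

    @classmethod
    def from_samples(cls, samples: list[DissipationSample],
                     meta: dict | None = None) -> "EnsembleTable":
        if not samples:
            raise ValidationError("empty ensemble")
        return cls(duration=samples[0].duration,
                   omega=np.array([s.omega_bins for s in samples]),
                   omega_fe=np.array([s.omega_fe_bins for s in samples]),
                   omega_xi=np.array([s.omega_xi_bins for s in samples]),
                   n_avg=np.array([s.n_avg_bins for s in samples]),
                   seeds=np.array([s.seed for s in samples]),
                   trajectory_ids=np.array([s.trajectory_id for s in samples]),
                   meta=dict(meta or {}))


#: Column schema of the long-format CSV ensemble files.  bin_index = -1
#: denotes the global (whole-system) row.
CSV_COLUMNS = ("trajectory_id", "seed", "t", "bin_index", "omega", "omega_fe",
               "omega_xi", "n_avg")


def save_ensemble(table: EnsembleTable, path) -> None:
    """Write an ensemble as long-format CSV (.csv) or HDF5 (.h5/.hdf5).

    CSV files begin with a ``#`` comment line embedding the resolved
    configuration as JSON.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["meta"] = json.dumps(table.meta, sort_keys=True)
            fh.attrs["duration"] = table.duration
            for name in ("omega", "omega_fe", "omega_xi", "n_avg", "seeds",
                         "trajectory_ids"):
                fh.create_dataset(name, data=getattr(table, name))
        return
    with open(path, "w") as fh:
        fh.write("# config: " + json.dumps(
            dict(table.meta, duration=table.duration), sort_keys=True) + "\n")
        fh.write(",".join(CSV_COLUMNS) + "\n")
        ncells = table.omega.shape[1]
        tot = table.omega_total
        tot_fe = table.omega_fe.sum(axis=1)
        tot_xi = table.omega_xi.sum(axis=1)
        tot_n = table.n_avg.sum(axis=1)
        dur = float(table.duration)
        for r in range(table.n_trajectories):
            tid, sd = int(table.trajectory_ids[r]), int(table.seeds[r])
            fh.write(f"{tid},{sd},{dur!r},-1,{float(tot[r])!r},"
                     f"{float(tot_fe[r])!r},{float(tot_xi[r])!r},"
                     f"{float(tot_n[r])!r}\n")
            for b in range(ncells):
                fh.write(f"{tid},{sd},{dur!r},{b},"
                         f"{float(table.omega[r, b])!r},"
                         f"{float(table.omega_fe[r, b])!r},"
                         f"{float(table.omega_xi[r, b])!r},"
                         f"{float(table.n_avg[r, b])!r}\n")


def load_ensemble(path) -> EnsembleTable:
    """Read an ensemble written by :func:`save_ensemble`."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            return EnsembleTable(
                duration=float(fh.attrs["duration"]),
                omega=fh["omega"][()], omega_fe=fh["omega_fe"][()],
                omega_xi=fh["omega_xi"][()], n_avg=fh["n_avg"][()],
                seeds=fh["seeds"][()],
                trajectory_ids=fh["trajectory_ids"][()],
                meta=json.loads(fh.attrs["meta"]))
    import pandas as pd

    with open(path) as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("# config:"):
        meta = json.loads(first[len("# config:"):])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    duration = float(meta.pop("duration", df["t"].iloc[0]))
    bins = df[df.bin_index >= 0]
    ncells = int(bins.bin_index.max()) + 1
    piv = bins.sort_values(["trajectory_id", "bin_index"])
    ntraj = piv.trajectory_id.nunique()

    def mat(col):
        return piv[col].to_numpy().reshape(ntraj, ncells)

    ids = piv.trajectory_id.to_numpy().reshape(ntraj, ncells)[:, 0]
    seeds = piv.seed.to_numpy().reshape(ntraj, ncells)[:, 0]
    return EnsembleTable(duration=duration, omega=mat("omega"),
                         omega_fe=mat("omega_fe"), omega_xi=mat("omega_xi"),
                         n_avg=mat("n_avg"), seeds=seeds, trajectory_ids=ids,
                         meta=meta)
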