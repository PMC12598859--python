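"""Time integration of the three driven/active model systems.

The three equation sets share the structure

    dq_i/dt = p_i / m_i
    dp_i/dt = F_i + (c_i F_e + xi_i) e_x - [alpha p_i + k (q_i - q0_i)] (walls)

with the Gaussian multiplier alpha determined by the scenario:

* channel  -- isokinetic on the tethered wall atoms only (the walls are the
  heat bath; the fluid is thermalized through wall--fluid collisions);
* obstacle -- Gaussian ergostat holding the total internal energy H fixed,
  alpha = sum_i c_i F_e p_{x,i} / sum_i p_i^2, so that dissipation equals
  entropy production;
* active   -- isokinetic on all fluid particles with the propulsion force
  xi_i e_x included, alpha = sum_i p_i.(F_i + (c_i F_e + xi_i) e_x) / sum p^2,
  and xi_i an Ornstein--Uhlenbeck process with relaxation time tau and
  stationary standard deviation sigma.

Each constraint is enforced exactly (to rounding) at every half-kick by the
closed-form implicit-midpoint multiplier in :mod:`localft._kernels`; the
deterministic scenarios are time-reversible under momentum reversal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .interactions import build_channel_walls, channel_half_width
from .model import (RegionPartition, ScenarioSpec, SimulationState,
                    ValidationError, assign_bins)

__all__ = [
    "IntegratorConfig",
    "TrajectoryRecord",
    "isokinetic_alpha",
    "ergostat_alpha",
    "ou_update",
    "step",
    "equilibrate",
    "run_trajectory",
    "build_initial_state",
    "draw_momenta",
    "trajectory_rng",
]

logger = logging.getLogger("localft")

_THERMO_CODE = {"channel": K.THERMO_WALLS_ISO, "obstacle": K.THERMO_ERGOSTAT,
                "active": K.THERMO_FLUID_ISO}


@dataclass(frozen=True)
class IntegratorConfig:
    """Integrator settings.

    ``timestep=None`` means "use the scenario default".  The constraint
    tolerance bounds the allowed per-sample drift of the constrained
    quantity (absolute for kinetic-energy constraints, relative for the
    ergostat energy); drift beyond it aborts the trajectory with a
    diagnostic, since it indicates a broken integration.
    """

    timestep: float | None = None
    scheme: str = "verlet-gaussian"
    sample_stride: int = 1
    constraint_tolerance: float = 1e-8
    rng_seed: int = 0

    def __post_init__(self):
        if self.timestep is not None and not self.timestep > 0:
            raise ValidationError("timestep must be > 0")
        if self.sample_stride < 1:
            raise ValidationError("sample_stride must be >= 1")
        if not self.constraint_tolerance > 0:
            raise ValidationError("constraint_tolerance must be > 0")


@dataclass
class TrajectoryRecord:
    """Per-trajectory time series and full-resolution time integrals.

    ``j_series`` holds the instantaneous per-cell color current
    j_{x,L} = sum_{i in cell} c_i p_{x,i} / m_i at the sampled times;
    ``xip_series`` the per-cell sums of xi_i p_{x,i} (active scenario);
    ``cnt_series`` the per-cell fluid particle counts.  ``j_integral``,
    ``xip_integral`` and ``cnt_integral`` are trapezoidal time integrals
    over the full duration accumulated at every step (stride 1), regardless
    of the sampling stride.  ``conserved`` logs the constrained quantity
    (wall or fluid kinetic energy, or total energy H) and ``alpha`` the
    Gaussian multiplier at the sampled times.
    """

    times: np.ndarray
    j_series: np.ndarray
    xip_series: np.ndarray
    cnt_series: np.ndarray
    conserved: np.ndarray
    alpha: np.ndarray
    j_integral: np.ndarray
    xip_integral: np.ndarray
    cnt_integral: np.ndarray
    partition: RegionPartition
    duration: float
    dt: float
    final_state: SimulationState

    @property
    def n_cells(self) -> int:
        return self.j_integral.shape[0]


def isokinetic_alpha(momenta: np.ndarray, forces: np.ndarray) -> float:
    """Gaussian isokinetic multiplier alpha = sum p.F / sum p^2.

    With this alpha the dynamics dp/dt = F - alpha p conserves sum p^2 over
    the given subset exactly.  Raises if the subset kinetic energy is zero.
    """
    momenta = np.asarray(momenta, dtype=np.float64).reshape(-1, 2)
    forces = np.asarray(forces, dtype=np.float64).reshape(-1, 2)
    p2 = float(np.sum(momenta * momenta))
    if p2 <= 0.0:
        raise ValidationError("isokinetic constraint undefined: sum p^2 = 0")
    return float(np.sum(momenta * forces)) / p2


def ergostat_alpha(state: SimulationState, f_e: float) -> float:
    """Gaussian ergostat multiplier alpha = sum_i c_i F_e p_{x,i} / sum p^2.

    With this alpha the obstacle dynamics conserves the internal energy H
    analytically (the color-field power input is removed as heat).
    """
    p2 = float(np.sum(state.momenta ** 2))
    if p2 <= 0.0:
        raise ValidationError("ergostat constraint undefined: sum p^2 = 0")
    num = f_e * float(np.sum(state.color_charge * state.momenta[:, 0]))
    return num / p2


def ou_update(xi: np.ndarray, tau: float, sigma_noise: float, dt: float,
              rng: np.random.Generator) -> np.ndarray:
    """Exact Ornstein--Uhlenbeck update over a time dt.

    xi' = xi e^(-dt/tau) + sigma sqrt(1 - e^(-2 dt/tau)) G with G standard
    normal, which is the exact discretization of
    dxi/dt = -xi/tau + eta,  <eta(t) eta(t+s)> = 2 sigma^2 delta(s) / tau:
    stationary distribution N(0, sigma^2), autocorrelation e^(-s/tau).
    """
    if tau <= 0:
        raise ValidationError("ou_relaxation tau must be > 0")
    if dt < 0:
        raise ValidationError("dt must be >= 0")
    xi = np.asarray(xi, dtype=np.float64)
    decay = math.exp(-dt / tau)
    amp = sigma_noise * math.sqrt(max(0.0, 1.0 - decay * decay))
    return xi * decay + amp * rng.standard_normal(xi.shape)


def trajectory_rng(base_seed: int, index: int) -> np.random.Generator:
    """Independent, order-independent random stream for one trajectory.

    Streams are derived from (base_seed, index) through a SeedSequence, so
    ensembles are reproducible regardless of execution order.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(base_seed),
                               spawn_key=(int(index),)))


# ---------------------------------------------------------------------------
# Initial configurations
# ---------------------------------------------------------------------------

def _fluid_lattice(n_fluid: int, box, accept) -> np.ndarray:
    """Place n_fluid particles on a square lattice filtered by ``accept``.

    Tries progressively denser lattices (never tighter than spacing 1.02, at
    which the WCA overlap energy is ~1 per pair and relaxes quickly).
    """
    lx, ly = box
    for spacing in np.linspace(1.45, 1.02, 60):
        nx = max(1, int(lx / spacing))
        ny = max(1, int(ly / spacing))
        gx = (np.arange(nx) + 0.5) * (lx / nx)
        gy = (np.arange(ny) + 0.5) * (ly / ny)
        xx, yy = np.meshgrid(gx, gy, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        pts = pts[accept(pts)]
        if len(pts) >= n_fluid:
            sel = np.linspace(0, len(pts) - 1, n_fluid).round().astype(int)
            return pts[np.unique(sel)] if len(np.unique(sel)) == n_fluid \
                else pts[:n_fluid]
    raise ValidationError(
        f"cannot place {n_fluid} fluid particles in the available volume")


def build_initial_state(spec: ScenarioSpec,
                        rng: np.random.Generator) -> SimulationState:
    """Lattice starting configuration with Maxwell momenta.

    Fluid color charges alternate c_i = (-1)^i; wall atoms (channel only)
    sit at their anchors with charge 0; the active propulsion variables are
    drawn from their stationary distribution N(0, sigma^2).
    """
    lx, ly = spec.params.box_lengths
    if spec.kind == "channel":
        anchors = build_channel_walls(spec.geometry["width"],
                                      spec.geometry["amplitude"],
                                      spec.geometry["wall_spacing"],
                                      (lx, ly))
        w0, a = spec.geometry["width"], spec.geometry["amplitude"]

        def accept(pts):
            half = channel_half_width(pts[:, 0], w0, a, lx)
            return np.abs(pts[:, 1] - ly / 2.0) < half - 0.95

        fluid = _fluid_lattice(spec.n_fluid, (lx, ly), accept)
        pos = np.concatenate([fluid, anchors], axis=0)
        n_wall = len(anchors)
    elif spec.kind == "obstacle":
        r = spec.geometry["radius"]

        def accept(pts):
            d = np.hypot(pts[:, 0] - lx / 2.0, pts[:, 1] - ly / 2.0)
            return d > r + 0.95

        pos = _fluid_lattice(spec.n_fluid, (lx, ly), accept)
        anchors = np.empty((0, 2))
        n_wall = 0
    else:
        pos = _fluid_lattice(spec.n_fluid, (lx, ly),
                             lambda pts: np.ones(len(pts), dtype=bool))
        anchors = np.empty((0, 2))
        n_wall = 0

    n = spec.n_fluid + n_wall
    charge = np.zeros(n, dtype=np.int8)
    charge[:spec.n_fluid] = np.where(np.arange(spec.n_fluid) % 2 == 0, 1, -1)
    wall = np.zeros(n, dtype=np.uint8)
    wall[spec.n_fluid:] = 1
    anchor_arr = np.full((n, 2), np.nan)
    anchor_arr[spec.n_fluid:] = anchors
    xi = np.zeros(n)
    if spec.activity_enabled:
        xi[:spec.n_fluid] = spec.params.ou_amplitude * rng.standard_normal(
            spec.n_fluid)
    state = SimulationState(positions=pos, momenta=np.zeros((n, 2)),
                            color_charge=charge, wall_flag=wall,
                            tether_anchor=anchor_arr, ou_value=xi, time=0.0)
    draw_momenta(state, spec, rng)
    return state


def draw_momenta(state: SimulationState, spec: ScenarioSpec,
                 rng: np.random.Generator) -> None:
    """Fresh Maxwell momenta at temperature T, in place.

    The fluid center-of-mass momentum is removed in the periodic scenarios,
    and the constrained subset (wall atoms for the channel, the whole fluid
    for the active scenario) is rescaled to its exact equipartition kinetic
    energy N_subset * T so the isokinetic constraint holds from t = 0.
    """
    temp = spec.params.temperature
    n = state.n_particles
    mom = rng.normal(0.0, math.sqrt(temp), size=(n, 2))
    fluid = state.wall_flag == 0
    if spec.periodic_y:
        mom[fluid] -= mom[fluid].mean(axis=0, keepdims=True)
    if spec.kind == "channel":
        subset = ~fluid
    elif spec.kind == "active":
        subset = fluid
    else:
        subset = None
    if subset is not None and subset.any():
        target = 2.0 * subset.sum() * temp  # sum p^2 at equipartition (2D)
        cur = float(np.sum(mom[subset] ** 2))
        mom[subset] *= math.sqrt(target / cur)
    state.momenta = np.ascontiguousarray(mom)


# ---------------------------------------------------------------------------
# Trajectory integration
# ---------------------------------------------------------------------------

def _kernel_args(spec: ScenarioSpec, f_e: float, use_activity: bool):
    lx, ly = spec.params.box_lengths
    if spec.kind == "obstacle":
        has_obs, ocx, ocy, obs_r = True, lx / 2.0, ly / 2.0, \
            spec.geometry["radius"]
    else:
        has_obs, ocx, ocy, obs_r = False, 0.0, 0.0, 1.0
    return dict(lx=lx, ly=ly, periodic_y=spec.periodic_y,
                thermo=_THERMO_CODE[spec.kind], has_obs=has_obs, ocx=ocx,
                ocy=ocy, obs_r=obs_r, f_e=f_e,
                k_spring=spec.params.spring_constant,
                use_activity=use_activity, tau=spec.params.ou_relaxation,
                sig_noise=spec.params.ou_amplitude)


def _part_args(part: RegionPartition):
    if part.mode == "slabs_x":
        return dict(part_mode=0, dx_cell=part.cell_size[0], dy_cell=1.0,
                    nx_cell=part.n_cells[0], ny_cell=1)
    return dict(part_mode=1, dx_cell=part.cell_size[0],
                dy_cell=part.cell_size[1], nx_cell=part.n_cells[0],
                ny_cell=part.n_cells[1])


def run_trajectory(start: SimulationState, spec: ScenarioSpec,
                   duration: float, cfg: IntegratorConfig | None = None,
                   seed=None, part: RegionPartition | None = None,
                   _thermo_override: int | None = None,
                   _field_override: float | None = None) -> TrajectoryRecord:
    """Integrate the scenario dynamics for ``duration`` from ``start``.

    Records the per-cell instantaneous color current and (active scenario)
    the per-cell propulsion power integrand at every ``sample_stride``
    steps, and accumulates their trapezoidal time integrals at every step.
    ``seed`` may be an int or a numpy Generator; it drives the OU noise and
    defaults to ``cfg.rng_seed``.  Identical (start, spec, cfg, seed) give a
    bit-identical record.
    """
    cfg = cfg or IntegratorConfig()
    dt = cfg.timestep if cfg.timestep is not None else spec.params.timestep
    nsteps = int(round(duration / dt))
    if abs(nsteps * dt - duration) > 1e-9 * max(1.0, duration):
        raise ValidationError("duration must be a multiple of the timestep")
    lx, ly = spec.params.box_lengths
    start.validate((lx, ly))
    part = part or RegionPartition.slabs(lx, lx)
    part.check_tiles((lx, ly))

    state = start.copy()
    # _field_override is used internally for field-free equilibration runs,
    # which also switch the activity off.
    f_e = spec.params.field_strength if _field_override is None \
        else _field_override
    use_activity = spec.activity_enabled and _field_override is None
    kargs = _kernel_args(spec, f_e, use_activity)
    if _thermo_override is not None:
        kargs["thermo"] = _thermo_override

    if kargs["use_activity"]:
        rng = seed if isinstance(seed, np.random.Generator) else \
            np.random.default_rng(cfg.rng_seed if seed is None else seed)
        noise = rng.standard_normal((nsteps, state.n_particles, 2)) \
            if nsteps else np.zeros((1, 1, 2))
    else:
        noise = np.zeros((1, 1, 2))

    ncells = part.total_cells
    n_rec = nsteps // cfg.sample_stride + 1
    j_series = np.zeros((n_rec, ncells))
    xip_series = np.zeros((n_rec, ncells))
    cnt_series = np.zeros((n_rec, ncells))
    conserved = np.zeros(n_rec)
    alpha = np.zeros(n_rec)
    j_acc = np.zeros(ncells)
    xip_acc = np.zeros(ncells)
    cnt_acc = np.zeros(ncells)

    err = K.run_trajectory_kernel(
        state.positions, state.momenta, state.color_charge, state.wall_flag,
        np.nan_to_num(state.tether_anchor), state.ou_value,
        kargs["lx"], kargs["ly"], kargs["periodic_y"], kargs["thermo"],
        kargs["has_obs"], kargs["ocx"], kargs["ocy"], kargs["obs_r"],
        kargs["f_e"], kargs["k_spring"], kargs["use_activity"],
        kargs["tau"], kargs["sig_noise"], dt, nsteps, noise,
        **_part_args(part), sample_stride=cfg.sample_stride,
        j_series=j_series, xip_series=xip_series, cnt_series=cnt_series,
        cons_series=conserved, alpha_series=alpha,
        j_acc=j_acc, xip_acc=xip_acc, cnt_acc=cnt_acc)
    _raise_kernel_error(err, spec)

    if nsteps > 0 and kargs["thermo"] in (K.THERMO_WALLS_ISO,
                                          K.THERMO_FLUID_ISO,
                                          K.THERMO_ERGOSTAT):
        ref = conserved[0]
        drift = np.max(np.abs(conserved - ref))
        scale = max(1.0, abs(ref)) if kargs["thermo"] == K.THERMO_ERGOSTAT \
            else 1.0
        if drift / scale > cfg.constraint_tolerance:
            raise ValidationError(
                f"constraint drift {drift / scale:.3e} exceeds tolerance "
                f"{cfg.constraint_tolerance:.1e} (scenario {spec.kind})")

    state.time = start.time + nsteps * dt
    times = start.time + dt * cfg.sample_stride * np.arange(n_rec)
    return TrajectoryRecord(times=times, j_series=j_series,
                            xip_series=xip_series, cnt_series=cnt_series,
                            conserved=conserved, alpha=alpha,
                            j_integral=j_acc, xip_integral=xip_acc,
                            cnt_integral=cnt_acc, partition=part,
                            duration=nsteps * dt, dt=dt, final_state=state)


def _raise_kernel_error(err: int, spec: ScenarioSpec) -> None:
    if err == 0:
        return
    msgs = {1: "particle overlap or obstacle penetration (r = 0 or d <= 0)",
            2: "non-finite positions during integration",
            3: "Gaussian constraint unsolvable (zero subset kinetic energy?)",
            4: "particle escaped the channel along y"}
    raise ValidationError(
        f"integration failed in scenario {spec.kind!r}: "
        f"{msgs.get(err, f'error code {err}')}")


def step(state: SimulationState, spec: ScenarioSpec,
         cfg: IntegratorConfig | None = None, rng=None) -> SimulationState:
    """Advance the scenario dynamics by a single timestep."""
    cfg = cfg or IntegratorConfig()
    dt = cfg.timestep if cfg.timestep is not None else spec.params.timestep
    rec = run_trajectory(state, spec, dt, cfg, seed=rng)
    return rec.final_state


def equilibrate(spec: ScenarioSpec, n_samples: int, spacing: float = 5.0,
                seed: int = 0, burn_in: float = 50.0) -> list[SimulationState]:
    """Sample equilibrium starting configurations for a scenario.

    Runs field-free (F_e = 0, activity off) dynamics from a lattice start
    with an isokinetic constraint on all particles, discards ``burn_in``
    time units, then takes configuration snapshots separated by ``spacing``.
    Each returned state gets fresh Maxwell momenta (and, for the active
    scenario, fresh stationary OU values), so samples decorrelate in both
    configuration and momentum space.  Deterministic given the seed.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(0x51,)))
    state = build_initial_state(spec, rng)
    cfg = IntegratorConfig(sample_stride=10 ** 9, constraint_tolerance=1e-6)

    def _segment(s, t):
        rec = run_trajectory(s, spec, t, cfg, seed=rng,
                             _thermo_override=K.THERMO_FLUID_ISO,
                             _field_override=0.0)
        return rec.final_state

    state = _segment(state, burn_in)
    samples = []
    u_log = []
    from .dissipation import total_energy  # local import avoids a cycle
    for _ in range(n_samples):
        state = _segment(state, spacing)
        snap = state.copy()
        draw_momenta(snap, spec, rng)
        if spec.activity_enabled:
            xi = np.zeros(snap.n_particles)
            fluid = snap.wall_flag == 0
            xi[fluid] = spec.params.ou_amplitude * rng.standard_normal(
                int(fluid.sum()))
            snap.ou_value = xi
        snap.time = 0.0
        samples.append(snap)
        u_log.append(total_energy(snap, spec)
                     - 0.5 * float(np.sum(snap.momenta ** 2)))
    if len(u_log) >= 8:
        half = len(u_log) // 2
        a, b = np.mean(u_log[:half]), np.mean(u_log[half:])
        se = np.std(u_log) / math.sqrt(half) + 1e-12
        if abs(b - a) > 5 * se:
            logger.warning(
                "equilibration diagnostic: potential energy drifting "
                "(first half %.4g, second half %.4g)", a, b)
    return samples
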