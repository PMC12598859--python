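"""Core domain types for driven and active two-dimensional fluids.

Everything downstream (forces, integrators, dissipation bookkeeping,
statistics) operates on the containers defined here:

* :class:`SimulationState` -- a full phase-space point (positions, momenta)
  plus the per-particle attributes of the three model systems: color charges
  ``c_i``, wall flags ``S_i``, tether anchors ``q_{0,i}``, and the
  Ornstein--Uhlenbeck propulsion variable ``xi_i`` of the active model.
* :class:`ModelParams` -- reduced-unit model parameters (field strength
  ``F_e``, inverse temperature ``beta``, tether spring constant ``k``,
  activity parameters ``tau`` and ``sigma``, timestep, box lengths).
* :class:`ScenarioSpec` -- one of the three model systems: a fluid driven
  through a channel of varying width with thermostatted tethered walls, a
  fluid driven past a static disk obstacle under a Gaussian ergostat, or a
  driven active (AOUP) fluid under a Gaussian isokinetic thermostat.
* :class:`RegionPartition` -- the spatial binning (slabs along x, or a 2D
  grid for maps) over which dissipation is localized.

All quantities are in reduced Lennard-Jones units: the WCA length ``sigma``,
energy ``epsilon``, and particle mass ``m`` are the units of length, energy,
and mass, and all particles have unit mass.
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "ModelParams",
    "ScenarioSpec",
    "SimulationState",
    "RegionPartition",
    "make_scenario",
    "assign_bins",
    "SCENARIO_KINDS",
]

SCENARIO_KINDS = ("channel", "obstacle", "active")


class ValidationError(ValueError):
    """Raised when a spec, parameter set, or state violates an invariant."""


@dataclass(frozen=True)
class ModelParams:
    """Reduced-unit model parameters shared by all three scenarios.

    Attributes
    ----------
    field_strength : float
        Color-field intensity ``F_e`` (reduced force, >= 0).
    inverse_temperature : float
        ``beta = 1/T`` in reduced units. The default temperature is T = 1.
    spring_constant : float
        Spring constant ``k`` tethering each wall atom to its lattice site.
    ou_relaxation : float
        Ornstein--Uhlenbeck relaxation time ``tau`` of the active propulsion.
    ou_amplitude : float
        Stationary standard deviation ``sigma`` of the propulsion force
        ``xi_i`` (the OU noise has covariance ``2 sigma^2 delta(s) / tau``).
    timestep : float
        Integration timestep ``dt`` (reduced time, < 0.01).
    wca_epsilon, wca_sigma : float
        WCA energy and length scales; fixed at 1 (they define the units).
    box_lengths : tuple(float, float)
        Simulation box ``(Lx, Ly)``.
    """

    field_strength: float = 0.0
    inverse_temperature: float = 1.0
    spring_constant: float = 100.0
    ou_relaxation: float = 0.1
    ou_amplitude: float = 0.1
    timestep: float = 0.002
    wca_epsilon: float = 1.0
    wca_sigma: float = 1.0
    box_lengths: tuple = (22.0, 22.0)

    def __post_init__(self):
        if not np.isfinite(self.field_strength) or self.field_strength < 0:
            raise ValidationError("field_strength must be finite and >= 0")
        for name in ("inverse_temperature", "spring_constant", "ou_relaxation",
                     "ou_amplitude", "timestep"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and > 0")
        if self.timestep >= 0.01:
            raise ValidationError("timestep must be < 0.01 reduced time")
        if self.wca_epsilon != 1.0 or self.wca_sigma != 1.0:
            raise ValidationError("wca_epsilon and wca_sigma are fixed at 1 "
                                  "(they define the reduced units)")
        bl = tuple(float(x) for x in self.box_lengths)
        if len(bl) != 2 or any((not math.isfinite(x)) or x <= 0 for x in bl):
            raise ValidationError("box_lengths must be two positive floats")
        object.__setattr__(self, "box_lengths", bl)

    @property
    def temperature(self) -> float:
        return 1.0 / self.inverse_temperature


# Scenario defaults.  The driving and activity parameters follow the model
# definitions (channel: F_e = 0.3; active: F_e = 0.05, sigma = 2 F_e = 0.1,
# tau = 0.1; obstacle radius R = 5).  Geometry and density are package
# choices: fluid number density ~0.5 at T = 1 in every scenario.
_DEFAULTS = {
    "channel": dict(
        params=dict(field_strength=0.3, box_lengths=(50.6, 14.0)),
        geometry=dict(width=10.0, amplitude=2.5, wall_spacing=1.0),
        n_fluid=164,
        thermostat_scope="walls_only",
        activity_enabled=False,
    ),
    "obstacle": dict(
        params=dict(field_strength=0.3, box_lengths=(30.0, 30.0)),
        geometry=dict(radius=5.0),
        n_fluid=400,
        thermostat_scope="all_fluid",
        activity_enabled=False,
    ),
    "active": dict(
        params=dict(field_strength=0.05, ou_amplitude=0.1, ou_relaxation=0.1,
                    box_lengths=(22.0, 22.0)),
        geometry=dict(),
        n_fluid=242,
        thermostat_scope="all_fluid",
        activity_enabled=True,
    ),
}

_GEOMETRY_KEYS = {
    "channel": {"width", "amplitude", "wall_spacing"},
    "obstacle": {"radius"},
    "active": set(),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully resolved description of one of the three model systems.

    ``kind`` selects the equations of motion:

    * ``channel`` -- color-field-driven fluid confined by tethered wall atoms
      whose kinetic energy is held fixed by a Gaussian isokinetic thermostat
      (heat leaves only through the walls); periodic in x only.
    * ``obstacle`` -- color-field-driven periodic fluid flowing past a static
      disk of radius R; a Gaussian ergostat holds the total internal energy H
      constant, so dissipation equals entropy production.
    * ``active`` -- periodic AOUP fluid: each particle carries an
      Ornstein--Uhlenbeck propulsion force along x in addition to the color
      field; a Gaussian isokinetic thermostat holds the fluid kinetic energy.
    """

    kind: str
    geometry: dict
    params: ModelParams
    n_fluid: int
    thermostat_scope: str
    activity_enabled: bool

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValidationError(f"unknown scenario kind {self.kind!r}")
        if self.n_fluid < 1:
            raise ValidationError("n_fluid must be >= 1")
        if self.thermostat_scope not in ("walls_only", "all_fluid"):
            raise ValidationError(
                f"unknown thermostat_scope {self.thermostat_scope!r}")
        # kind-specific coupling invariants
        if self.kind == "channel":
            if self.thermostat_scope != "walls_only" or self.activity_enabled:
                raise ValidationError(
                    "channel scenario requires walls_only thermostat and no "
                    "activity")
            w, a = self.geometry["width"], self.geometry["amplitude"]
            if w <= 0:
                raise ValidationError("geometry.width must be > 0")
            if a < 0 or 2 * a >= w:
                raise ValidationError(
                    "geometry.amplitude must satisfy 0 <= 2*amplitude < width "
                    "(channel must not pinch closed)")
            if self.geometry["wall_spacing"] <= 0:
                raise ValidationError("geometry.wall_spacing must be > 0")
            if w >= self.params.box_lengths[1]:
                raise ValidationError("channel width must fit inside Ly")
        elif self.kind == "obstacle":
            if self.thermostat_scope != "all_fluid" or self.activity_enabled:
                raise ValidationError(
                    "obstacle scenario requires all_fluid ergostat and no "
                    "activity")
            r = self.geometry["radius"]
            if not (r > 0):
                raise ValidationError("geometry.radius must be > 0")
            if 2 * r >= min(self.params.box_lengths):
                raise ValidationError("obstacle diameter must fit in the box")
        else:  # active
            if self.thermostat_scope != "all_fluid" or not self.activity_enabled:
                raise ValidationError(
                    "active scenario requires all_fluid thermostat and "
                    "activity enabled")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"]["box_lengths"] = list(self.params.box_lengths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        p = dict(d["params"])
        p["box_lengths"] = tuple(p["box_lengths"])
        return cls(kind=d["kind"], geometry=dict(d["geometry"]),
                   params=ModelParams(**p), n_fluid=int(d["n_fluid"]),
                   thermostat_scope=d["thermostat_scope"],
                   activity_enabled=bool(d["activity_enabled"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def to_toml(self) -> str:
        """Serialize as a TOML document (scalars and inline values only)."""
        lines = ["[scenario]",
                 f'kind = "{self.kind}"',
                 f"n_fluid = {self.n_fluid}",
                 f'thermostat_scope = "{self.thermostat_scope}"',
                 f"activity_enabled = {str(self.activity_enabled).lower()}",
                 "", "[scenario.geometry]"]
        for k, v in self.geometry.items():
            lines.append(f"{k} = {float(v)!r}")
        lines += ["", "[scenario.params]"]
        for f_ in dataclasses.fields(ModelParams):
            v = getattr(self.params, f_.name)
            if f_.name == "box_lengths":
                lines.append(f"box_lengths = [{v[0]!r}, {v[1]!r}]")
            else:
                lines.append(f"{f_.name} = {float(v)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "ScenarioSpec":
        doc = tomllib.loads(text)["scenario"]
        return cls.from_dict(doc)

    @property
    def periodic_y(self) -> bool:
        """The channel is bounded by walls in y; the others are periodic."""
        return self.kind != "channel"


def make_scenario(kind: str, overrides: dict | None = None) -> ScenarioSpec:
    """Build a validated :class:`ScenarioSpec` with per-kind defaults.

    ``overrides`` may set any :class:`ModelParams` field, any geometry key of
    the chosen kind, or ``n_fluid``.  Unknown keys and invariant violations
    raise :class:`ValidationError` naming the offending field.
    """
    if kind not in SCENARIO_KINDS:
        raise ValidationError(
            f"unknown scenario kind {kind!r}; expected one of {SCENARIO_KINDS}")
    base = _DEFAULTS[kind]
    params_kw = dict(base["params"])
    geometry = dict(base["geometry"])
    n_fluid = base["n_fluid"]
    param_names = {f_.name for f_ in dataclasses.fields(ModelParams)}
    for key, val in (overrides or {}).items():
        if key in param_names:
            params_kw[key] = val
        elif key in _GEOMETRY_KEYS[kind]:
            geometry[key] = val
        elif key == "n_fluid":
            n_fluid = int(val)
        else:
            raise ValidationError(
                f"unknown override {key!r} for scenario kind {kind!r}")
    return ScenarioSpec(kind=kind, geometry=geometry,
                        params=ModelParams(**params_kw), n_fluid=n_fluid,
                        thermostat_scope=base["thermostat_scope"],
                        activity_enabled=base["activity_enabled"])


@dataclass
class SimulationState:
    """A phase-space point with per-particle model attributes.

    Arrays are per-particle and share the same length N: ``positions`` and
    ``momenta`` are (N, 2); ``color_charge`` holds c_i in {-1, 0, +1} (0 for
    wall atoms); ``wall_flag`` holds S_i in {0, 1}; ``tether_anchor`` holds
    the wall lattice sites q_{0,i} (NaN rows for fluid particles);
    ``ou_value`` holds the propulsion variable xi_i (zero when inactive).
    """

    positions: np.ndarray
    momenta: np.ndarray
    color_charge: np.ndarray
    wall_flag: np.ndarray
    tether_anchor: np.ndarray
    ou_value: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.momenta = np.ascontiguousarray(self.momenta, dtype=np.float64)
        self.color_charge = np.ascontiguousarray(self.color_charge,
                                                 dtype=np.int8)
        self.wall_flag = np.ascontiguousarray(self.wall_flag, dtype=np.uint8)
        self.tether_anchor = np.ascontiguousarray(self.tether_anchor,
                                                  dtype=np.float64)
        self.ou_value = np.ascontiguousarray(self.ou_value, dtype=np.float64)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.wall_flag == 0

    def copy(self) -> "SimulationState":
        return SimulationState(self.positions.copy(), self.momenta.copy(),
                               self.color_charge.copy(), self.wall_flag.copy(),
                               self.tether_anchor.copy(), self.ou_value.copy(),
                               self.time)

    def validate(self, box: tuple | None = None) -> None:
        """Check structural invariants; raise :class:`ValidationError`."""
        n = self.positions.shape[0]
        if n < 1 or self.positions.shape != (n, 2):
            raise ValidationError("positions must be a non-empty (N, 2) array")
        for name in ("momenta", "tether_anchor"):
            if getattr(self, name).shape != (n, 2):
                raise ValidationError(f"{name} must have shape (N, 2)")
        for name in ("color_charge", "wall_flag", "ou_value"):
            if getattr(self, name).shape != (n,):
                raise ValidationError(f"{name} must have shape (N,)")
        if not np.isfinite(self.positions).all():
            raise ValidationError("positions contain non-finite values")
        if not np.isfinite(self.momenta).all():
            raise ValidationError("momenta contain non-finite values")
        if not np.isin(self.color_charge, (-1, 0, 1)).all():
            raise ValidationError("color charges must be in {-1, 0, +1}")
        wall = self.wall_flag == 1
        if np.any(self.color_charge[wall] != 0):
            raise ValidationError("wall particles must have color charge 0")
        if wall.any() and not np.isfinite(self.tether_anchor[wall]).all():
            raise ValidationError("wall particles must have finite anchors")
        fluid_c = self.color_charge[~wall]
        if abs(int(fluid_c.sum())) > 1:
            raise ValidationError(
                "fluid color charges must alternate (net charge in {0, +-1})")
        if box is not None:
            lx, ly = box
            x, y = self.positions[:, 0], self.positions[:, 1]
            if np.any(x < 0) or np.any(x >= lx) or np.any(y < 0) or np.any(y >= ly):
                raise ValidationError("positions lie outside the box")


@dataclass(frozen=True)
class RegionPartition:
    """Spatial binning of the box into half-open cells.

    ``slabs_x`` mode tiles the box along x with ``n_cells`` slabs of width
    ``cell_size`` starting at ``origin``; the last cell absorbs any float
    remainder so the slabs tile the full box.  ``grid2d`` mode tiles the box
    with an ``n_cells = (nx, ny)`` grid of ``cell_size = (dx, dy)`` cells.
    Particles are assigned by wrapped instantaneous position with the
    half-open convention [x0, x0 + L).
    """

    mode: str
    cell_size: tuple
    n_cells: tuple
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.mode not in ("slabs_x", "grid2d"):
            raise ValidationError(f"unknown partition mode {self.mode!r}")
        cs = tuple(float(c) for c in np.atleast_1d(self.cell_size))
        nc = tuple(int(c) for c in np.atleast_1d(self.n_cells))
        if any(c <= 0 for c in cs) or any(c < 1 for c in nc):
            raise ValidationError("cell sizes must be > 0 and counts >= 1")
        want = 1 if self.mode == "slabs_x" else 2
        if len(cs) != want or len(nc) != want:
            raise ValidationError(f"{self.mode} needs {want} cell dimension(s)")
        object.__setattr__(self, "cell_size", cs)
        object.__setattr__(self, "n_cells", nc)
        object.__setattr__(self, "origin",
                           tuple(float(o) for o in np.atleast_1d(self.origin)))

    @classmethod
    def slabs(cls, box_length: float, width: float) -> "RegionPartition":
        """Slabs of the given width along x; the last absorbs the remainder."""
        n = max(1, int(math.floor(box_length / width + 1e-9)))
        return cls(mode="slabs_x", cell_size=(width,), n_cells=(n,))

    @classmethod
    def grid(cls, box: tuple, shape: tuple) -> "RegionPartition":
        nx, ny = int(shape[0]), int(shape[1])
        return cls(mode="grid2d", cell_size=(box[0] / nx, box[1] / ny),
                   n_cells=(nx, ny))

    @property
    def total_cells(self) -> int:
        return int(np.prod(self.n_cells))

    def check_tiles(self, box: tuple, rtol: float = 1e-9) -> None:
        """Require the cells to tile the box (last slab absorbs remainder)."""
        if self.mode == "slabs_x":
            covered = self.n_cells[0] * self.cell_size[0]
            if covered > box[0] * (1 + rtol):
                raise ValidationError("slabs overrun the box length")
            if covered < box[0] * (1 - rtol) and self.n_cells[0] * \
                    self.cell_size[0] + self.cell_size[0] <= box[0] * (1 - rtol):
                raise ValidationError("slabs leave more than one cell uncovered")
        else:
            for d in range(2):
                if abs(self.n_cells[d] * self.cell_size[d] - box[d]) > \
                        rtol * box[d]:
                    raise ValidationError("grid does not tile the box")

    def bin_edges_x(self, box_length: float) -> np.ndarray:
        """Slab edges along x; the final edge is the box length itself."""
        if self.mode != "slabs_x":
            raise ValidationError("bin_edges_x is defined for slabs_x only")
        edges = self.origin[0] + self.cell_size[0] * np.arange(
            self.n_cells[0] + 1)
        edges[-1] = box_length
        return edges


def assign_bins(state_or_positions, part: RegionPartition,
                box: tuple) -> np.ndarray:
    """Map each particle to the index of the cell containing it.

    Positions are wrapped into the periodic box first; cells are half-open
    ``[x0, x0 + L)`` and the assignment is deterministic.  For ``grid2d`` the
    flat index is ``ix + nx * iy`` (row-major in x).
    """
    pos = getattr(state_or_positions, "positions", state_or_positions)
    pos = np.asarray(pos, dtype=np.float64)
    if not np.isfinite(pos).all():
        raise ValidationError("cannot bin non-finite positions")
    lx, ly = box
    x = np.mod(pos[:, 0] - part.origin[0], lx)
    if part.mode == "slabs_x":
        idx = np.floor(x / part.cell_size[0]).astype(np.int64)
        return np.clip(idx, 0, part.n_cells[0] - 1)
    y = np.mod(pos[:, 1] - part.origin[1], ly)
    ix = np.clip(np.floor(x / part.cell_size[0]).astype(np.int64), 0,
                 part.n_cells[0] - 1)
    iy = np.clip(np.floor(y / part.cell_size[1]).astype(np.int64), 0,
                 part.n_cells[1] - 1)
    return ix + part.n_cells[0] * iy
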