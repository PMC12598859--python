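"""Forces: WCA pairs, wall tethers, disk obstacle, channel walls, color field.

This module is the plain-NumPy reference implementation of every force in
the three model systems.  The integrator uses compiled kernels
(:mod:`localft._kernels`) for speed; the two paths are cross-checked against
each other in the test suite.  All interactions use the purely repulsive
Weeks--Chandler--Andersen (WCA) potential

    U(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 ] + eps   for r < 2^(1/6) sigma

with eps = sigma = 1 (reduced units), cut and shifted at its minimum so U
and F vanish continuously at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ScenarioSpec, SimulationState, ValidationError

__all__ = [
    "WCA_CUTOFF",
    "ForceField",
    "wca_pair",
    "tether_force",
    "obstacle_force",
    "color_force",
    "build_channel_walls",
    "channel_half_width",
    "write_extxyz",
]

#: WCA cutoff 2^(1/6) sigma: the minimum of the Lennard-Jones potential.
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceField:
    """Resolved interaction parameters for one scenario.

    ``obstacle`` is ``(cx, cy, R)`` or ``None``; ``spring_constant`` applies
    to tethered wall atoms (anchors live on the state).  ``periodic_y``
    selects whether the minimum-image convention applies along y (it never
    applies across the channel walls).
    """

    spring_constant: float
    periodic_y: bool
    obstacle: tuple | None = None
    pair_cutoff: float = WCA_CUTOFF

    def __post_init__(self):
        if self.obstacle is not None and not self.obstacle[2] > 0:
            raise ValidationError("obstacle radius must be > 0")

    @classmethod
    def from_scenario(cls, spec: ScenarioSpec) -> "ForceField":
        obstacle = None
        if spec.kind == "obstacle":
            lx, ly = spec.params.box_lengths
            obstacle = (lx / 2.0, ly / 2.0, spec.geometry["radius"])
        return cls(spring_constant=spec.params.spring_constant,
                   periodic_y=spec.periodic_y, obstacle=obstacle)


def _min_image(dr: np.ndarray, box, periodic_y: bool) -> np.ndarray:
    dr = dr.copy()
    dr[..., 0] -= box[0] * np.round(dr[..., 0] / box[0])
    if periodic_y:
        dr[..., 1] -= box[1] * np.round(dr[..., 1] / box[1])
    return dr


def _wca_u_f(r2: np.ndarray):
    """Pair energy and force magnitude / r for squared distances r2 < rc^2."""
    inv2 = 1.0 / r2
    inv6 = inv2 ** 3
    u = 4.0 * (inv6 * inv6 - inv6) + 1.0
    # f(r)/r = 24 (2 r^-12 - r^-6) / r^2, directed along +dr (repulsive)
    f_over_r = 24.0 * (2.0 * inv6 * inv6 - inv6) * inv2
    return u, f_over_r


def wca_pair(state: SimulationState, box,
             periodic_y: bool = True) -> tuple[np.ndarray, float]:
    """WCA pair forces and total pair energy (O(N^2) reference).

    Returns ``(forces, potential)`` with forces obeying Newton's third law
    pairwise.  The minimum image applies along x always and along y only
    when ``periodic_y`` (the channel is bounded in y).  Raises on coincident
    particles or non-finite positions.
    """
    pos = state.positions
    if not np.isfinite(pos).all():
        raise ValidationError("non-finite positions")
    n = pos.shape[0]
    forces = np.zeros((n, 2))
    dr = _min_image(pos[:, None, :] - pos[None, :, :], box, periodic_y)
    r2 = np.einsum("ijk,ijk->ij", dr, dr)
    iu = np.triu_indices(n, k=1)
    r2u = r2[iu]
    if np.any(r2u == 0.0):
        raise ValidationError("coincident particles (r = 0)")
    mask = r2u < WCA_CUTOFF ** 2
    u = 0.0
    if mask.any():
        uvals, f_over_r = _wca_u_f(r2u[mask])
        u = float(uvals.sum())
        ii = iu[0][mask]
        jj = iu[1][mask]
        fij = f_over_r[:, None] * dr[ii, jj]  # force on i from j
        np.add.at(forces, ii, fij)
        np.add.at(forces, jj, -fij)
    return forces, u


def tether_force(state: SimulationState, k: float,
                 box=None) -> tuple[np.ndarray, float]:
    """Harmonic tether F = -k (q - q0) on wall particles; zero on fluid.

    The displacement uses the minimum image along x only (anchors sit inside
    the box; the tether never wraps across the y walls).  Returns
    ``(forces, potential)``.
    """
    n = state.n_particles
    forces = np.zeros((n, 2))
    wall = state.wall_flag == 1
    if not wall.any():
        return forces, 0.0
    if not np.isfinite(state.tether_anchor[wall]).all():
        raise ValidationError("wall particle with missing tether anchor")
    disp = state.positions[wall] - state.tether_anchor[wall]
    if box is not None:
        disp[:, 0] -= box[0] * np.round(disp[:, 0] / box[0])
    forces[wall] = -k * disp
    return forces, 0.5 * k * float(np.sum(disp * disp))


def obstacle_force(state: SimulationState, center, radius: float,
                   box=None) -> tuple[np.ndarray, float]:
    """Shifted-distance WCA repulsion from a static disk of radius R.

    The WCA form acts on the surface distance ``d = |q - center| - R`` with
    the usual cutoff ``d < 2^(1/6)``; the force is radial and repulsive and
    vanishes continuously at the cutoff.  A particle at or inside the disk
    surface (d <= 0) is an error.
    """
    if not radius > 0:
        raise ValidationError("obstacle radius must be > 0")
    dr = state.positions - np.asarray(center)[None, :]
    if box is not None:
        dr = _min_image(dr, box, True)
    r = np.hypot(dr[:, 0], dr[:, 1])
    d = r - radius
    if np.any(d <= 0):
        raise ValidationError("particle penetrated the obstacle (d <= 0)")
    n = state.n_particles
    forces = np.zeros((n, 2))
    mask = d < WCA_CUTOFF
    u = 0.0
    if mask.any():
        uvals, f_over_d = _wca_u_f(d[mask] ** 2)
        u = float(uvals.sum())
        fmag = f_over_d * d[mask]  # |F| along the outward radial direction
        forces[mask] = (fmag / r[mask])[:, None] * dr[mask]
    return forces, u


def color_force(state: SimulationState, f_e: float) -> np.ndarray:
    """Color-field force ``c_i F_e e_x``; zero for wall particles (c = 0)."""
    forces = np.zeros((state.n_particles, 2))
    forces[:, 0] = state.color_charge.astype(np.float64) * f_e
    return forces


def channel_half_width(x, width: float, amplitude: float,
                       lx: float) -> np.ndarray:
    """Half-width of the channel at position x.

    The channel width is modulated as ``W(x) = W0 - 2 a sin^2(pi x / Lx)``,
    widest at the periodic boundary and narrowest (W0 - 2a) at the box
    center x = Lx / 2.
    """
    return 0.5 * width - amplitude * np.sin(np.pi * np.asarray(x) / lx) ** 2


def build_channel_walls(width: float, amplitude: float, wall_spacing: float,
                        box) -> np.ndarray:
    """Anchor sites for the two tethered wall layers of the channel.

    One single layer of anchors per side, spaced ``wall_spacing`` along x,
    following ``y = Ly/2 +- W(x)/2``.  Returns an (n_wall, 2) array of
    anchors (lower wall first).  Raises if the profile pinches the channel
    closed or the walls do not fit in the box.
    """
    lx, ly = box
    if amplitude < 0 or 2 * amplitude >= width:
        raise ValidationError("channel pinches closed (2*amplitude >= width)")
    if width >= ly:
        raise ValidationError("channel width must be smaller than Ly")
    n_sites = int(round(lx / wall_spacing))
    if n_sites < 2:
        raise ValidationError("wall_spacing too large for the box")
    x = (np.arange(n_sites) + 0.5) * (lx / n_sites)
    half = channel_half_width(x, width, amplitude, lx)
    lower = np.column_stack([x, ly / 2.0 - half])
    upper = np.column_stack([x, ly / 2.0 + half])
    return np.concatenate([lower, upper], axis=0)


def write_extxyz(path, state: SimulationState, box, comment: str = "") -> None:
    """Append one frame in extended-XYZ format.

    Columns: species (W for wall, A/B for color +1/-1), position, momentum,
    color charge, wall flag, OU propulsion value.
    """
    lx, ly = box
    props = ("Properties=species:S:1:pos:R:3:momenta:R:3:color_charge:I:1:"
             "wall_flag:I:1:ou_value:R:1")
    lattice = f'Lattice="{lx} 0.0 0.0 0.0 {ly} 0.0 0.0 0.0 1.0"'
    with open(path, "a") as fh:
        fh.write(f"{state.n_particles}\n")
        fh.write(f"{lattice} {props} Time={state.time!r} {comment}".strip()
                 + "\n")
        for i in range(state.n_particles):
            if state.wall_flag[i]:
                sp = "W"
            else:
                sp = "A" if state.color_charge[i] > 0 else "B"
            x, y = state.positions[i]
            px, py = state.momenta[i]
            fh.write(f"{sp} {x!r} {y!r} 0.0 {px!r} {py!r} 0.0 "
                     f"{int(state.color_charge[i])} {int(state.wall_flag[i])} "
                     f"{state.ou_value[i]!r}\n")
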