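"""interactions: WCA values, force oracles, geometry builders."""

import numpy as np
import pytest

import localft as lf
from localft.interactions import (WCA_CUTOFF, build_channel_walls,
                                  channel_half_width, color_force,
                                  obstacle_force, tether_force, wca_pair,
                                  write_extxyz)


def pair_state(r, periodic_box=(20.0, 20.0)):
    pos = np.array([[5.0, 5.0], [5.0 + r, 5.0]])
    return lf.SimulationState(positions=pos, momenta=np.zeros((2, 2)),
                              color_charge=np.array([1, -1]),
                              wall_flag=np.zeros(2),
                              tether_anchor=np.full((2, 2), np.nan),
                              ou_value=np.zeros(2))


def random_fluid_state(n, box, seed, min_sep=0.9):
    """Random non-overlapping configuration (rejection from a jittered
    lattice)."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n)))
    gx = (np.arange(side) + 0.5) * (box[0] / side)
    gy = (np.arange(side) + 0.5) * (box[1] / side)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    pos = np.column_stack([xx.ravel(), yy.ravel()])[:n]
    pos += rng.uniform(-0.1, 0.1, size=pos.shape)
    pos = np.mod(pos, box)
    charge = np.where(np.arange(n) % 2 == 0, 1, -1)
    return lf.SimulationState(positions=pos, momenta=np.zeros((n, 2)),
                              color_charge=charge, wall_flag=np.zeros(n),
                              tether_anchor=np.full((n, 2), np.nan),
                              ou_value=np.zeros(n))


# -- WCA values -------------------------------------------------------------

def test_wca_contact_values():
    """U(r=1) = epsilon = 1 and |F(r=1)| = 24 in reduced units."""
    forces, u = wca_pair(pair_state(1.0), (20.0, 20.0))
    assert u == pytest.approx(1.0, abs=1e-12)
    assert abs(forces[0, 0]) == pytest.approx(24.0, rel=1e-12)
    assert forces[0, 0] < 0  # repulsive: particle 0 pushed toward -x


def test_wca_cutoff_continuity():
    r = WCA_CUTOFF - 1e-8
    forces, u = wca_pair(pair_state(r), (20.0, 20.0))
    assert abs(u) < 1e-6
    assert np.abs(forces).max() < 1e-6
    forces2, u2 = wca_pair(pair_state(WCA_CUTOFF + 0.01), (20.0, 20.0))
    assert u2 == 0.0 and np.all(forces2 == 0.0)


def test_wca_newton_third_law():
    state = random_fluid_state(25, (8.0, 8.0), seed=3)
    forces, _ = wca_pair(state, (8.0, 8.0))
    assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-12)


def test_wca_coincident_raises():
    with pytest.raises(lf.ValidationError):
        wca_pair(pair_state(0.0), (20.0, 20.0))


def test_wca_minimum_image():
    """A pair straddling the periodic boundary interacts."""
    s = pair_state(1.0)
    s.positions[0] = (0.2, 5.0)
    s.positions[1] = (19.8, 5.0)  # separation 0.4 through the boundary
    forces, u = wca_pair(s, (20.0, 20.0))
    assert u > 0
    assert forces[0, 0] > 0  # pushed toward +x, away through the boundary


# -- central-difference force oracles ---------------------------------------

def _numeric_force(state, energy_fn, h=1e-6):
    n = state.n_particles
    out = np.zeros((n, 2))
    for i in range(n):
        for d in range(2):
            sp = state.copy()
            sp.positions[i, d] += h
            sm = state.copy()
            sm.positions[i, d] -= h
            out[i, d] = -(energy_fn(sp) - energy_fn(sm)) / (2 * h)
    return out


def test_wca_force_matches_gradient():
    box = (8.0, 8.0)
    state = random_fluid_state(16, box, seed=7)
    forces, _ = wca_pair(state, box)
    num = _numeric_force(state, lambda s: wca_pair(s, box)[1])
    scale = max(1.0, np.abs(forces).max())
    assert np.abs(forces - num).max() / scale < 1e-5


def test_obstacle_force_matches_gradient():
    box = (20.0, 20.0)
    state = random_fluid_state(12, box, seed=11)
    # place particles in the obstacle's interaction shell
    rng = np.random.default_rng(4)
    ang = rng.uniform(0, 2 * np.pi, 12)
    rad = 3.0 + rng.uniform(0.0, WCA_CUTOFF * 0.9, 12)
    state.positions = np.column_stack([10.0 + rad * np.cos(ang),
                                       10.0 + rad * np.sin(ang)])
    center, radius = (10.0, 10.0), 3.0
    forces, _ = obstacle_force(state, center, radius, box)
    num = _numeric_force(state,
                         lambda s: obstacle_force(s, center, radius, box)[1])
    assert np.abs(forces - num).max() / max(1.0, np.abs(forces).max()) < 1e-5


def test_obstacle_penetration_raises():
    state = random_fluid_state(2, (20.0, 20.0), seed=0)
    state.positions[0] = (10.0, 10.0)
    with pytest.raises(lf.ValidationError):
        obstacle_force(state, (10.0, 10.0), 3.0, (20.0, 20.0))


def test_tether_force_matches_gradient_and_energy():
    n = 5
    rng = np.random.default_rng(9)
    state = random_fluid_state(n, (10.0, 10.0), seed=9)
    state.wall_flag[:] = 1
    state.color_charge[:] = 0
    state.tether_anchor = state.positions + rng.normal(0, 0.05, (n, 2))
    k = 100.0
    forces, u = tether_force(state, k, (10.0, 10.0))
    num = _numeric_force(state, lambda s: tether_force(s, k, (10.0, 10.0))[1])
    assert np.abs(forces - num).max() < 1e-4
    disp = state.positions - state.tether_anchor
    assert u == pytest.approx(0.5 * k * np.sum(disp ** 2), rel=1e-10)


def test_color_force_signs_and_walls():
    state = random_fluid_state(4, (10.0, 10.0), seed=1)
    state.wall_flag[3] = 1
    state.color_charge[3] = 0
    f = color_force(state, 0.3)
    assert np.allclose(f[:, 1], 0.0)
    assert f[0, 0] == pytest.approx(0.3)
    assert f[1, 0] == pytest.approx(-0.3)
    assert f[3, 0] == 0.0


# -- channel geometry -------------------------------------------------------

def test_channel_profile():
    w0, a, lx = 10.0, 2.5, 50.6
    assert channel_half_width(0.0, w0, a, lx) == pytest.approx(w0 / 2)
    assert channel_half_width(lx / 2, w0, a, lx) == \
        pytest.approx(w0 / 2 - a)  # narrowest at the center
    x = np.linspace(0, lx, 101)
    h = channel_half_width(x, w0, a, lx)
    assert h.min() >= w0 / 2 - a - 1e-12


def test_build_channel_walls_geometry():
    box = (20.0, 14.0)
    anchors = build_channel_walls(10.0, 2.0, 1.0, box)
    assert anchors.shape == (40, 2)  # 20 sites per wall, two walls
    lower, upper = anchors[:20], anchors[20:]
    # symmetric about the channel mid-line
    assert np.allclose(lower[:, 1] + upper[:, 1], box[1])
    # gap equals the local width
    gap = upper[:, 1] - lower[:, 1]
    expect = 2 * channel_half_width(lower[:, 0], 10.0, 2.0, box[0])
    assert np.allclose(gap, expect)


def test_build_channel_walls_rejects_pinch():
    with pytest.raises(lf.ValidationError):
        build_channel_walls(4.0, 2.0, 1.0, (20.0, 10.0))


# -- trajectory dump --------------------------------------------------------

def test_write_extxyz(tmp_path):
    state = random_fluid_state(3, (5.0, 5.0), seed=2)
    path = tmp_path / "frames.xyz"
    write_extxyz(path, state, (5.0, 5.0), comment="frame=0")
    write_extxyz(path, state, (5.0, 5.0), comment="frame=1")
    lines = path.read_text().splitlines()
    assert len(lines) == 2 * (2 + 3)
    assert lines[0].strip() == "3"
    assert "Lattice=" in lines[1] and "frame=0" in lines[1]
    assert lines[2].split()[0] in ("A", "B")
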