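"""flucstats: kappa, asymmetry functions, fixtures, maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import localft as lf
from localft.flucstats import (InsufficientNegativeEvents, asymmetry_function,
                               dissipation_map, fit_kappa_curve,
                               freedman_diaconis_width, gaussian_fixture,
                               kappa, kappa_scan, local_ft_check)
from localft.model import RegionPartition


# -- kappa ------------------------------------------------------------------

def test_kappa_perfect_correlation():
    x = np.linspace(-1, 3, 50)
    k, _ = kappa(x, x.copy(), n_boot=0)
    assert k == pytest.approx(1.0)


def test_kappa_global_limit_zero():
    x = np.random.default_rng(0).normal(1, 1, 100)
    k, _ = kappa(x, np.zeros(100), n_boot=0)
    assert k == pytest.approx(0.0, abs=1e-12)


def test_kappa_negative_half_recovery():
    rng = np.random.default_rng(1)
    local = rng.normal(0.5, 1.0, 200000)
    comp = -0.5 * local + 0.3 * rng.standard_normal(local.size)
    k, err = kappa(local, comp, n_boot=200, seed=2)
    assert k == pytest.approx(-0.5, abs=0.01)
    assert 0 < err < 0.01


def test_kappa_validation():
    with pytest.raises(lf.ValidationError):
        kappa(np.ones(20), np.ones(20), n_boot=0)  # zero variance
    with pytest.raises(lf.ValidationError):
        kappa(np.arange(5.0), np.arange(5.0), n_boot=0)  # too few
    with pytest.raises(lf.ValidationError):
        kappa(np.arange(20.0), np.arange(10.0), n_boot=0)


@given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.1, 4))
@settings(max_examples=30, deadline=None)
def test_kappa_shift_invariance_and_scaling(a, b, s):
    rng = np.random.default_rng(7)
    x = rng.normal(0, 1, 500)
    y = rng.normal(0, 1, 500) + 0.4 * x
    k0, _ = kappa(x, y, n_boot=0)
    k1, _ = kappa(x + a, y + b, n_boot=0)
    assert k1 == pytest.approx(k0, rel=1e-9, abs=1e-9)
    k2, _ = kappa(x, s * y, n_boot=0)
    assert k2 == pytest.approx(s * k0, rel=1e-9, abs=1e-9)


# -- asymmetry function -----------------------------------------------------

def test_symmetric_samples_slope_zero():
    rng = np.random.default_rng(3)
    half = rng.normal(2.0, 0.5, 20000)
    samples = np.concatenate([half, -half])  # exactly symmetric
    curve = asymmetry_function(samples)
    assert np.allclose(curve.log_ratio, 0.0)
    assert curve.slope == pytest.approx(0.0, abs=1e-12)


def test_exact_line_recovery():
    """Counts constructed to lie exactly on y = 1.5 A give slope 1.5."""
    w = 0.5
    centers = w * (np.arange(8) + 0.5)
    neg_counts = np.full(8, 4000)
    pos_counts = np.round(neg_counts * np.exp(1.5 * centers)).astype(int)
    samples = []
    for c, npos, nneg in zip(centers, pos_counts, neg_counts):
        samples += [c] * npos + [-c] * nneg
    curve = asymmetry_function(np.array(samples, dtype=float), bin_width=w)
    # rounding the counts to integers perturbs the line slightly
    assert curve.slope == pytest.approx(1.5, abs=0.01)
    assert curve.n_points == 8


def test_gaussian_closed_form_slope():
    """Normal(mu, v) samples give slope 2 mu / v within 3 stderr."""
    mu, v = 2.0, 4.0
    rng = np.random.default_rng(5)
    samples = rng.normal(mu, math.sqrt(v), 100000)
    curve = asymmetry_function(samples)
    expected = 2 * mu / v
    assert abs(curve.slope - expected) < 3 * curve.slope_err
    assert abs(curve.slope - expected) < 0.1


def test_insufficient_negative_events():
    samples = np.abs(np.random.default_rng(0).normal(5, 1, 5000)) + 0.1
    with pytest.raises(InsufficientNegativeEvents):
        asymmetry_function(samples)


def test_asymmetry_validation():
    with pytest.raises(lf.ValidationError):
        asymmetry_function(np.array([1.0, -1.0]))  # too few samples
    with pytest.raises(lf.ValidationError):
        asymmetry_function(np.random.default_rng(0).normal(0, 1, 1000),
                           bin_width=-1.0)


def test_histogram_count_conservation():
    rng = np.random.default_rng(8)
    samples = rng.normal(0.5, 1.0, 5000)
    w = freedman_diaconis_width(samples)
    amax = np.abs(samples).max()
    nbins = int(np.ceil(amax / w))
    edges = w * np.arange(nbins + 1)
    pos, _ = np.histogram(samples[samples > 0], bins=edges)
    neg, _ = np.histogram(-samples[samples < 0], bins=edges)
    nzero = int(np.sum(samples == 0.0))
    assert pos.sum() + neg.sum() + nzero == samples.size


def test_freedman_diaconis_positive():
    assert freedman_diaconis_width(np.random.default_rng(0).normal(0, 1, 50)) > 0


# -- fixture generator and estimator recovery -------------------------------

@pytest.mark.parametrize("ktrue,expected", [(-0.36, 0.64), (0.0, 1.0),
                                            (0.82, 1.82)])
def test_ft_consistent_fixture_slopes(ktrue, expected):
    omega_l, omega_star = gaussian_fixture(100000, kappa_true=ktrue, var=1.0,
                                           seed=11, ft_consistent=True)
    k, kerr = kappa(omega_l, omega_star, n_boot=200, seed=1)
    assert k == pytest.approx(ktrue, abs=4 * max(kerr, 1e-3))
    curve = asymmetry_function(omega_l)
    assert abs(curve.slope - expected) < 3 * curve.slope_err
    assert abs(curve.slope - expected) < 0.05


@pytest.mark.parametrize("ktrue", [-0.5, 0.0, 0.5, 1.0])
def test_estimator_self_recovery(ktrue):
    """Fitted slope equals 1 + kappa-hat within 3 combined errors."""
    omega_l, omega_star = gaussian_fixture(100000, kappa_true=ktrue, var=1.0,
                                           seed=23, ft_consistent=True)
    k, kerr = kappa(omega_l, omega_star, n_boot=300, seed=5)
    curve = asymmetry_function(omega_l)
    report = local_ft_check(curve, k, kerr)
    assert report["consistent"], report


def test_fixture_validation_and_determinism():
    with pytest.raises(lf.ValidationError):
        gaussian_fixture(100, var=0.0)
    a = gaussian_fixture(50, kappa_true=0.3, seed=9, ft_consistent=True)
    b = gaussian_fixture(50, kappa_true=0.3, seed=9, ft_consistent=True)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


# -- kappa scan and fitting hook --------------------------------------------

def test_kappa_scan_requires_two_lengths():
    x = np.random.default_rng(0).normal(1, 1, 100)
    with pytest.raises(lf.ValidationError):
        kappa_scan({2.0: (x, x)})


def test_kappa_scan_orders_lengths():
    rng = np.random.default_rng(4)
    ens = {}
    for L, k in ((4.0, 0.1), (1.0, 0.6), (2.0, 0.3)):
        loc = rng.normal(1, 1, 2000)
        ens[L] = (loc, k * loc + 0.2 * rng.standard_normal(2000))
    scan = kappa_scan(ens, n_boot=50, seed=0)
    assert list(scan.lengths) == [1.0, 2.0, 4.0]
    assert scan.kappa[0] > scan.kappa[1] > scan.kappa[2]


def test_fit_kappa_curve_generic():
    lengths = np.array([1.0, 2.0, 4.0, 8.0])
    kvals = 0.9 * np.exp(-lengths / 3.0)
    scan = lf.KappaScan(lengths=lengths, kappa=kvals,
                        stderr=np.full(4, 0.01), n_samples=np.full(4, 100))
    params, _ = fit_kappa_curve(scan, lambda L, a, b: a * np.exp(-L / b),
                                p0=(1.0, 1.0))
    assert params[0] == pytest.approx(0.9, rel=1e-4)
    assert params[1] == pytest.approx(3.0, rel=1e-4)


# -- dissipation maps -------------------------------------------------------

def _map_table(ntraj=30, nx=3, ny=2, seed=0, empty_cell=None):
    rng = np.random.default_rng(seed)
    ncells = nx * ny
    fe = rng.normal(1.0, 0.1, (ntraj, ncells))
    navg = np.full((ntraj, ncells), 5.0)
    if empty_cell is not None:
        fe[:, empty_cell] = 0.0
        navg[:, empty_cell] = 0.0
    from localft.dissipation import EnsembleTable
    return EnsembleTable(duration=1.0, omega=fe, omega_fe=fe,
                         omega_xi=np.zeros_like(fe), n_avg=navg,
                         seeds=np.arange(ntraj),
                         trajectory_ids=np.arange(ntraj),
                         meta={"beta": 1.0, "field_strength": 0.05})


def test_dissipation_map_homogeneous():
    part = RegionPartition.grid((6.0, 4.0), (3, 2))
    dmap = dissipation_map(_map_table(), part)
    assert dmap.mean_omega.shape == (6,)
    assert not dmap.missing.any()
    assert np.allclose(dmap.mean_omega, 1.0, atol=0.2)
    # current = omega_fe / (beta F_e)
    assert np.allclose(dmap.mean_current * 0.05, dmap.mean_omega)


def test_dissipation_map_missing_cell():
    part = RegionPartition.grid((6.0, 4.0), (3, 2))
    dmap = dissipation_map(_map_table(empty_cell=4), part)
    assert dmap.missing[4]
    assert np.isnan(dmap.mean_omega[4])
    assert np.isfinite(dmap.mean_omega[[0, 1, 2, 3, 5]]).all()


def test_dissipation_map_partition_mismatch():
    part = RegionPartition.grid((6.0, 4.0), (4, 2))
    with pytest.raises(lf.ValidationError):
        dissipation_map(_map_table(), part)
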