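"""Fluctuation statistics of dissipation ensembles.

The central objects are the asymmetry function of a dissipation sample,

    Y(A) = ln[ p(Omega_{L,t} = A) / p(Omega_{L,t} = -A) ],

whose local fluctuation theorem prediction is a straight line through the
origin with slope 1 + kappa_{L,t}, and the local--surroundings correlation
coefficient

    kappa_{L,t} = Cov(Omega*_{L,t}, Omega_{L,t}) / Var(Omega_{L,t}),

the regression coefficient of the surroundings' dissipation on the local
one.  kappa vanishes when the local region grows to the whole system
(Omega* -> 0), recovering the global fluctuation theorem with slope 1.

For Gaussian samples Normal(mu, v) the asymmetry function is exactly linear
with slope 2 mu / v, which provides a closed-form oracle: an FT-consistent
ensemble satisfies 2 mu / v = 1 + kappa.  The module also ships a synthetic
Gaussian fixture generator so the entire statistics path can be exercised
without any molecular dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import RegionPartition, ValidationError

__all__ = [
    "AsymmetryCurve",
    "KappaScan",
    "DissipationMap",
    "InsufficientNegativeEvents",
    "kappa",
    "asymmetry_function",
    "local_ft_check",
    "kappa_scan",
    "fit_kappa_curve",
    "dissipation_map",
    "gaussian_fixture",
    "freedman_diaconis_width",
]


class InsufficientNegativeEvents(ValidationError):
    """Raised when a sample has too few negative events for an asymmetry
    curve (the expected situation for global dissipation at strong
    driving)."""


@dataclass
class AsymmetryCurve:
    """Binned asymmetry function with an origin-constrained slope fit."""

    a_values: np.ndarray       # positive bin centers A
    log_ratio: np.ndarray      # ln[count(A) / count(-A)]
    stderr: np.ndarray         # Poisson-propagated per-point errors
    slope: float
    slope_err: float
    n_points: int
    bin_width: float
    n_samples: int


@dataclass
class KappaScan:
    lengths: np.ndarray
    kappa: np.ndarray
    stderr: np.ndarray
    n_samples: np.ndarray


@dataclass
class DissipationMap:
    """Per-cell ensemble means over a 2D grid (or slab) partition.

    Cells never visited by any particle carry NaN means ("missing", not
    zero) and are flagged in ``missing``.
    """

    partition: RegionPartition
    mean_omega: np.ndarray
    se_omega: np.ndarray
    mean_current: np.ndarray
    mean_count: np.ndarray
    missing: np.ndarray
    n_trajectories: int


def kappa(local: np.ndarray, complement: np.ndarray, n_boot: int = 1000,
          seed: int = 0) -> tuple[float, float]:
    """Local--surroundings correlation coefficient and bootstrap error.

    kappa = Cov(Omega*, Omega_L) / Var(Omega_L), estimated with sample
    moments; the standard error comes from ``n_boot`` bootstrap resamples
    over trajectories (set ``n_boot=0`` to skip and return NaN).
    """
    local = np.asarray(local, dtype=np.float64)
    complement = np.asarray(complement, dtype=np.float64)
    if local.shape != complement.shape or local.ndim != 1:
        raise ValidationError("local and complement must be equal-length 1D")
    n = local.size
    if n < 10:
        raise ValidationError("kappa needs at least 10 samples")
    var = local.var()
    if var <= 0:
        raise ValidationError("kappa undefined: Var(Omega_L) = 0")

    def _k(a, b):
        return float(np.mean(a * b) - a.mean() * b.mean()) / a.var()

    k = _k(local, complement)
    if n_boot <= 0:
        return k, float("nan")
    rng = np.random.default_rng(seed)
    ks = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        loc = local[idx]
        v = loc.var()
        ks[i] = _k(loc, complement[idx]) if v > 0 else np.nan
    return k, float(np.nanstd(ks))


def freedman_diaconis_width(samples: np.ndarray) -> float:
    """Freedman--Diaconis bin width on the pooled magnitudes |samples|."""
    mags = np.abs(np.asarray(samples, dtype=np.float64))
    q75, q25 = np.percentile(mags, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        iqr = mags.std() or 1.0
    return 2.0 * iqr / len(mags) ** (1.0 / 3.0)


def _wls_origin(a, y, err):
    """Weighted least squares of y = slope * a through the origin."""
    w = 1.0 / err ** 2
    denom = float(np.sum(w * a * a))
    slope = float(np.sum(w * a * y)) / denom
    return slope, math.sqrt(1.0 / denom)


def asymmetry_function(samples: np.ndarray, bin_width: float | None = None,
                       min_count: int = 10, n_boot: int = 0,
                       seed: int = 0) -> AsymmetryCurve:
    """Histogram asymmetry function with an origin-constrained WLS slope.

    Bins are symmetric about zero with the given width (Freedman--Diaconis
    on |samples| by default).  Each positive center A enters the curve only
    when both the +A and -A bins hold at least ``min_count`` events; the
    per-point error propagates Poisson counting noise,
    sqrt(1/n_+ + 1/n_-).  With ``n_boot > 0`` the slope error is replaced
    by a bootstrap over samples.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 1 or samples.size < 2 * min_count:
        raise ValidationError("too few samples for an asymmetry function")
    if bin_width is None:
        bin_width = freedman_diaconis_width(samples)
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")

    a, y, e = _asymmetry_points(samples, bin_width, min_count)
    if a.size == 0:
        raise InsufficientNegativeEvents(
            "insufficient negative events: no +-A bin pair reaches "
            f"min_count={min_count} (global-FT regime?)")
    slope, slope_err = _wls_origin(a, y, e)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        slopes = []
        n = samples.size
        for _ in range(n_boot):
            res = samples[rng.integers(0, n, n)]
            ab, yb, eb = _asymmetry_points(res, bin_width, min_count)
            if ab.size:
                slopes.append(_wls_origin(ab, yb, eb)[0])
        if len(slopes) >= 10:
            slope_err = float(np.std(slopes))
    return AsymmetryCurve(a_values=a, log_ratio=y, stderr=e, slope=slope,
                          slope_err=slope_err, n_points=a.size,
                          bin_width=bin_width, n_samples=samples.size)


def _asymmetry_points(samples, bin_width, min_count):
    amax = float(np.max(np.abs(samples)))
    nbins = max(1, int(math.ceil(amax / bin_width)))
    edges = bin_width * np.arange(nbins + 1)
    pos, _ = np.histogram(samples[samples > 0], bins=edges)
    neg, _ = np.histogram(-samples[samples < 0], bins=edges)
    ok = (pos >= min_count) & (neg >= min_count)
    centers = 0.5 * (edges[:-1] + edges[1:])
    a = centers[ok]
    with np.errstate(divide="ignore"):
        y = np.log(pos[ok] / neg[ok])
    e = np.sqrt(1.0 / pos[ok] + 1.0 / neg[ok])
    return a, y, e


def local_ft_check(curve: AsymmetryCurve, kappa_value: float,
                   kappa_err: float, n_sigma: float = 3.0) -> dict:
    """Compare the fitted asymmetry slope with the prediction 1 + kappa.

    Returns a report with the discrepancy in combined standard errors and a
    consistency flag at the ``n_sigma`` level.
    """
    predicted = 1.0 + kappa_value
    combined = math.hypot(curve.slope_err,
                          0.0 if math.isnan(kappa_err) else kappa_err)
    delta = curve.slope - predicted
    z = abs(delta) / combined if combined > 0 else math.inf
    return {
        "slope": curve.slope,
        "slope_err": curve.slope_err,
        "kappa": kappa_value,
        "kappa_err": kappa_err,
        "predicted_slope": predicted,
        "combined_err": combined,
        "discrepancy_sigma": z,
        "consistent": bool(z <= n_sigma),
    }


def kappa_scan(ensembles: dict, n_boot: int = 1000, seed: int = 0) -> KappaScan:
    """kappa(L) over a family of local-region sizes.

    ``ensembles`` maps L -> (Omega_L samples, Omega* samples).  At least two
    distinct L values are required; kappa values are reported as-is
    (monotonicity is not enforced).
    """
    if len(ensembles) < 2:
        raise ValidationError("kappa_scan needs at least 2 distinct L values")
    lengths = np.array(sorted(ensembles))
    ks, errs, ns = [], [], []
    for i, length in enumerate(lengths):
        local, comp = ensembles[length]
        k, e = kappa(np.asarray(local), np.asarray(comp), n_boot=n_boot,
                     seed=seed + i)
        ks.append(k)
        errs.append(e)
        ns.append(len(local))
    return KappaScan(lengths=lengths, kappa=np.array(ks),
                     stderr=np.array(errs), n_samples=np.array(ns))


def fit_kappa_curve(scan: KappaScan, func, p0, **kwargs):
    """Generic least-squares hook for a user-supplied kappa(L) model.

    No functional form is built in; ``func(L, *params)`` is fitted with
    :func:`scipy.optimize.curve_fit` weighted by the scan's standard errors
    when finite.  Returns (params, covariance).
    """
    from scipy.optimize import curve_fit

    sigma = scan.stderr if np.all(np.isfinite(scan.stderr)) else None
    return curve_fit(func, scan.lengths, scan.kappa, p0=p0, sigma=sigma,
                     **kwargs)


def dissipation_map(table, part: RegionPartition,
                    quantity: str = "omega") -> DissipationMap:
    """Ensemble means of local dissipation/entropy production per cell.

    ``table`` is an :class:`~localft.dissipation.EnsembleTable` whose bins
    were recorded on ``part``.  ``quantity`` selects "omega" (= Sigma under
    the ergostat) or "omega_fe"/"omega_xi" components.  The mean
    time-integrated local current J_{x,L,t} is derived from the
    deterministic component when the table's metadata carries beta and F_e.
    Cells with zero mean particle count are reported missing (NaN).
    """
    vals = getattr(table, quantity)
    if vals.shape[1] != part.total_cells:
        raise ValidationError("partition does not match the ensemble bins")
    ntraj = vals.shape[0]
    mean = vals.mean(axis=0)
    se = vals.std(axis=0, ddof=1) / math.sqrt(ntraj) if ntraj > 1 else \
        np.full(vals.shape[1], np.nan)
    count = table.n_avg.mean(axis=0)
    missing = count <= 1e-12
    mean = np.where(missing, np.nan, mean)
    se = np.where(missing, np.nan, se)
    beta = table.meta.get("beta", np.nan)
    f_e = table.meta.get("field_strength", np.nan)
    if beta and f_e and np.isfinite(beta) and np.isfinite(f_e) and f_e != 0:
        current = table.omega_fe.mean(axis=0) / (beta * f_e)
    else:
        current = np.full(vals.shape[1], np.nan)
    current = np.where(missing, np.nan, current)
    return DissipationMap(partition=part, mean_omega=mean, se_omega=se,
                          mean_current=current, mean_count=count,
                          missing=missing, n_trajectories=ntraj)


def gaussian_fixture(n: int, mu: float | None = None, var: float = 1.0,
                     kappa_true: float = 0.0, seed: int = 0,
                     ft_consistent: bool = False, mu_star: float = 0.0,
                     noise_sd: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic Gaussian (Omega_L, Omega*) ensemble with known kappa.

    Omega_L ~ Normal(mu, var) and
    Omega* = kappa_true (Omega_L - mu) + mu_star + independent noise, so
    the population Cov(Omega*, Omega_L)/Var(Omega_L) equals ``kappa_true``.
    With ``ft_consistent=True`` the mean is set to mu = var (1 + kappa)/2,
    which makes Omega_L satisfy the local fluctuation theorem exactly in
    distribution (asymmetry slope 2 mu / var = 1 + kappa_true).
    Deterministic given the seed.
    """
    if var <= 0:
        raise ValidationError("variance must be > 0")
    if ft_consistent:
        mu = var * (1.0 + kappa_true) / 2.0
    elif mu is None:
        mu = 0.0
    rng = np.random.default_rng(seed)
    omega_l = rng.normal(mu, math.sqrt(var), n)
    if noise_sd is None:
        noise_sd = 0.5 * math.sqrt(var)
    omega_star = (kappa_true * (omega_l - mu) + mu_star
                  + noise_sd * rng.standard_normal(n))
    return omega_l, omega_star
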