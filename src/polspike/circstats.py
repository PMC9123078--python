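"""Axial circular statistics for angle-of-polarization tuning.

The angle of polarization (AoP) is axial: an E-vector at 30 degrees is
indistinguishable from one at 210 degrees. All statistics therefore use
the classical doubling trick: angles are doubled (mod 360), ordinary
circular statistics are applied, and mean directions are halved back to
[0, 180).

Provided primitives:

* :func:`axial_mean` — mean direction (preferred AoP, Phi_max) and mean
  resultant vector length r of an axial sample;
* :func:`circ_linear_corr` — circular-linear correlation between binned
  spike counts and the (doubled) bin angles, with an asymptotic
  chi-square or a permutation p-value;
* :func:`fit_bimodal_von_mises` / :func:`rate_at` — least-squares fit of
  an axially bimodal von Mises firing-rate curve
  ``rate(theta) = b + a * exp(kappa * cos(2*(theta - mu)))`` and its
  evaluation at arbitrary angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AxialSample",
    "CircResult",
    "VonMisesFit",
    "axial_mean",
    "circ_linear_corr",
    "fit_bimodal_von_mises",
    "rate_at",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Input admits no defined result (empty sample, constant counts...)."""


@dataclass
class AxialSample:
    """Angles (degrees, interpreted mod 180) with their doubled images."""

    angles: np.ndarray
    doubled: np.ndarray

    @classmethod
    def from_angles(cls, angles) -> "AxialSample":
        a = np.mod(np.asarray(angles, dtype=float), 360.0)
        return cls(angles=a, doubled=np.mod(2.0 * a, 360.0))

    def __len__(self) -> int:
        return int(self.angles.size)


@dataclass
class CircResult:
    """Axial mean direction and resultant length.

    phi_max is the preferred AoP in [0, 180); undefined (NaN, flagged)
    when the resultant length is numerically zero.
    """

    phi_max: float
    r: float
    n: int
    phi_max_defined: bool = True


def axial_mean(sample: AxialSample | np.ndarray | list) -> CircResult:
    """Mean direction and resultant length of an axial sample.

    Doubles the angles, takes the circular mean of the unit vectors,
    halves the mean direction back to [0, 180). ``r`` is the mean
    resultant length of the doubled angles, in [0, 1].
    """
    if not isinstance(sample, AxialSample):
        sample = AxialSample.from_angles(sample)
    n = len(sample)
    if n == 0:
        raise DegenerateInputError("axial_mean: empty sample")
    rad = np.deg2rad(sample.doubled)
    C = np.cos(rad).sum() / n
    S = np.sin(rad).sum() / n
    r = float(np.hypot(C, S))
    if r < 1e-12:
        return CircResult(phi_max=float("nan"), r=r, n=n, phi_max_defined=False)
    mean_doubled = np.rad2deg(np.arctan2(S, C))  # (-180, 180]
    phi_max = float(np.mod(mean_doubled / 2.0, 180.0))
    return CircResult(phi_max=phi_max, r=min(r, 1.0), n=n)


def circ_linear_corr(
    bin_counts,
    bin_centers_doubled,
    method: str = "asymptotic",
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Circular-linear correlation between bin counts and bin angles.

    ``bin_centers_doubled`` are the doubled AoP bin centers in degrees.
    With x the counts and theta the angles,

        r_cl = sqrt((rcx^2 + rsx^2 - 2 rcx rsx rcs) / (1 - rcs^2))

    where rcx = corr(x, cos theta), rsx = corr(x, sin theta),
    rcs = corr(cos theta, sin theta). The asymptotic p-value refers
    n * r_cl^2 to a chi-square distribution with 2 df; the permutation
    p-value shuffles counts across bins.
    """
    x = np.asarray(bin_counts, dtype=float)
    th = np.deg2rad(np.asarray(bin_centers_doubled, dtype=float))
    if x.size != th.size:
        raise ValueError("bin_counts and bin_centers_doubled must have equal length")
    n = x.size
    if n < 3 or np.ptp(x) == 0:
        raise DegenerateInputError(
            "circ_linear_corr: counts are constant or too few bins"
        )
    c, s = np.cos(th), np.sin(th)
    r_cl = _rcl(x, c, s)
    if method == "asymptotic":
        p = float(stats.chi2.sf(n * r_cl**2, df=2))
    elif method == "permutation":
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100 for the permutation test")
        rng = np.random.default_rng(seed)
        perm = rng.permuted(np.broadcast_to(x, (n_perm, n)).copy(), axis=1)
        r_perm = _rcl_many(perm, c, s)
        p = float((1 + np.sum(r_perm >= r_cl)) / (n_perm + 1))
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return float(r_cl), p


def _rcl(x: np.ndarray, c: np.ndarray, s: np.ndarray) -> float:
    rcx = np.corrcoef(x, c)[0, 1]
    rsx = np.corrcoef(x, s)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    num = rcx**2 + rsx**2 - 2 * rcx * rsx * rcs
    val = num / (1 - rcs**2)
    return float(np.sqrt(max(val, 0.0)))


def _rcl_many(x: np.ndarray, c: np.ndarray, s: np.ndarray) -> np.ndarray:
    # rows of x are permuted count vectors; vectorized Pearson correlations
    xc = x - x.mean(axis=1, keepdims=True)
    xs = xc / np.sqrt((xc**2).sum(axis=1, keepdims=True))
    cc = (c - c.mean()) / np.sqrt(((c - c.mean()) ** 2).sum())
    ss = (s - s.mean()) / np.sqrt(((s - s.mean()) ** 2).sum())
    rcx = xs @ cc
    rsx = xs @ ss
    rcs = float(cc @ ss)
    num = rcx**2 + rsx**2 - 2 * rcx * rsx * rcs
    return np.sqrt(np.clip(num / (1 - rcs**2), 0.0, None))


@dataclass
class VonMisesFit:
    """Axially bimodal von Mises firing-rate curve.

    rate(theta) = offset + gain * exp(kappa * cos(2*(theta - mu))), with
    gain >= 0 so the mode sits at mu and the antimode at mu + 90. The
    exponential is un-normalized: the target is a rate curve, not a
    density, so any normalization constant is absorbed into ``gain``.
    """

    offset: float
    gain: float
    kappa: float
    mu: float
    rss: float
    converged: bool = True
    mu_identifiable: bool = True


def rate_at(fit: VonMisesFit, theta) -> np.ndarray | float:
    """Evaluate the fitted tuning curve at ``theta`` (degrees)."""
    th = np.asarray(theta, dtype=float)
    out = fit.offset + fit.gain * np.exp(
        fit.kappa * np.cos(2.0 * np.deg2rad(th - fit.mu))
    )
    return float(out) if np.isscalar(theta) else out


def _vm_residuals(params: np.ndarray, theta_rad2: np.ndarray, rates: np.ndarray):
    b, a, kappa, mu2 = params  # mu2 = 2*mu in radians
    return b + a * np.exp(kappa * np.cos(theta_rad2 - mu2)) - rates


def fit_bimodal_von_mises(
    bin_centers,
    bin_rates=None,
    mu_starts=(0.0, 45.0, 90.0, 135.0),
    kappa_starts=(0.5, 2.0),
) -> VonMisesFit:
    """Least-squares fit of the bimodal von Mises rate curve to binned rates.

    Accepts either ``(bin_centers, bin_rates)`` arrays or a single binned
    response object exposing ``bin_centers`` and ``rates``. Multistart
    over mu and kappa; the best-RSS solution wins, ties broken toward the
    smallest kappa. The offset is constrained non-negative so the
    predicted rate is non-negative everywhere. A flat profile yields
    gain ~ 0 and an unidentifiable mu (flagged). Non-convergence on all
    starts returns a fit flagged ``converged=False``; callers fall back
    to raw bin rates.
    """
    if bin_rates is None:
        bin_rates = bin_centers.rates
        bin_centers = bin_centers.bin_centers
    theta = np.asarray(bin_centers, dtype=float)
    rates = np.asarray(bin_rates, dtype=float)
    theta_rad2 = 2.0 * np.deg2rad(theta)

    rate_span = float(np.ptp(rates))
    b0 = float(np.min(rates))
    best: VonMisesFit | None = None
    for mu0 in mu_starts:
        for k0 in kappa_starts:
            a0 = max(rate_span / max(np.exp(k0) - np.exp(-k0), 1e-6), 1e-3)
            x0 = np.array([b0, a0, k0, 2.0 * np.deg2rad(mu0)])
            try:
                sol = optimize.least_squares(
                    _vm_residuals,
                    x0,
                    args=(theta_rad2, rates),
                    bounds=([0.0, 0.0, 0.0, -np.inf], [np.inf, np.inf, 50.0, np.inf]),
                    max_nfev=2000,
                )
            except Exception:
                continue
            if not sol.success:
                continue
            rss = float(2.0 * sol.cost)
            cand = VonMisesFit(
                offset=float(sol.x[0]),
                gain=float(sol.x[1]),
                kappa=float(sol.x[2]),
                mu=float(np.mod(np.rad2deg(sol.x[3]) / 2.0, 180.0)),
                rss=rss,
            )
            if (
                best is None
                or rss < best.rss - 1e-12
                or (abs(rss - best.rss) <= 1e-12 and cand.kappa < best.kappa)
            ):
                best = cand
    if best is None:
        return VonMisesFit(
            offset=float(np.mean(rates)),
            gain=0.0,
            kappa=0.0,
            mu=float("nan"),
            rss=float(np.sum((rates - rates.mean()) ** 2)),
            converged=False,
            mu_identifiable=False,
        )
    # mu is unidentifiable when the fitted modulation is negligible
    modulation = best.gain * (np.exp(best.kappa) - np.exp(-best.kappa))
    if modulation < 1e-6 * max(1.0, abs(best.offset)) or best.kappa < 1e-8:
        best.mu_identifiable = False
    return best
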