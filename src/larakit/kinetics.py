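"""Michaelis–Menten nonlinear regression, catalytic efficiency, and the
tested-grid optimum-range rule.

Model
-----
Initial rates follow v = Vmax·[S] / (Km + [S]).  The fit is unweighted
nonlinear least squares (optionally 1/v² weighted); 95% confidence intervals
come from the asymptotic covariance with a Student-t quantile at n − 2
degrees of freedom.  kcat = Vmax / [E]0 assumes 100% active-enzyme (cofactor)
loading, so kcat and kcat/KM are lower bounds when loading is incomplete; an
optional loading fraction rescales them.

Units: concentrations in mM, enzyme in µM, velocities in signal/s (µM/s for
simulated data), kcat in 1/s, and kcat/KM reported in M⁻¹ s⁻¹ (the mM→M
conversion is a factor 1000).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "RateMeasurement",
    "MMFit",
    "ConditionProfile",
    "OptimumRange",
    "Efficiency",
    "MichaelisMentenRegressor",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "round_2sf",
    "optimum_range",
]


@dataclass(frozen=True)
class RateMeasurement:
    """One initial-rate observation."""

    substrate: str
    concentration: float  # mM
    velocity: float  # signal per second
    enzyme_conc: float  # µM
    replicate: int = 0
    enzyme: str = "enzyme"

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("substrate concentration must be positive")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis–Menten parameters with 95% confidence intervals."""

    Km: float  # mM
    Km_ci: tuple[float, float]
    kcat: float  # 1/s
    kcat_ci: tuple[float, float]
    Vmax: float
    residual_sse: float
    n_points: int
    converged: bool


class Efficiency(NamedTuple):
    """Catalytic efficiency in M⁻¹ s⁻¹ plus a 2-significant-figure rendering."""

    value: float
    rendered: str


@dataclass(frozen=True)
class ConditionProfile:
    """Activity as a function of one assay condition (pH or temperature)."""

    condition_type: str  # "pH" or "temperature"
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("profile needs at least one point")
        if any(a < 0 for _, a in self.points):
            raise ValueError("activities must be non-negative")


@dataclass(frozen=True)
class OptimumRange:
    """Tested-condition range where activity exceeds 90% of the maximum."""

    low: float
    high: float
    qualifying: tuple[float, ...]
    contiguous: bool


def _mm(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


class MichaelisMentenRegressor(RegressorMixin, BaseEstimator):
    """Michaelis–Menten curve fit as an estimator.

    ``fit(S, v)`` takes substrate concentrations (mM; shape (n,) or (n, 1))
    and velocities.  Fitted attributes: ``Km_``, ``Vmax_``, ``kcat_`` (when
    ``enzyme_conc`` is set), the corresponding ``*_ci_`` 95% intervals,
    ``residual_sse_``, ``n_points_``, ``converged_``.

    Parameters
    ----------
    enzyme_conc : float or None
        Total enzyme (µM).  Needed to convert Vmax to kcat.
    loading_fraction : float
        Fraction of enzyme carrying active cofactor; kcat is divided by it.
        Default 1.0 (the standard assumption when loading is unknown, which
        makes kcat a lower bound).
    weighting : {None, "1/v2"}
        None = unweighted least squares (default); "1/v2" downweights large
        velocities (appropriate for multiplicative error).
    """

    def __init__(
        self,
        enzyme_conc: float | None = None,
        loading_fraction: float = 1.0,
        weighting: str | None = None,
        max_nfev: int = 10000,
    ):
        self.enzyme_conc = enzyme_conc
        self.loading_fraction = loading_fraction
        self.weighting = weighting
        self.max_nfev = max_nfev

    def fit(self, X, y):
        s = np.asarray(X, dtype=float).reshape(-1)
        v = np.asarray(y, dtype=float).reshape(-1)
        if s.shape != v.shape:
            raise ValueError("X and y must have the same length")
        if not np.all(np.isfinite(s)) or not np.all(np.isfinite(v)):
            raise ValueError("non-finite concentration or velocity")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be positive")
        if len(np.unique(s)) < 3:
            raise ValueError("need at least 3 distinct substrate concentrations")
        vmax_obs = float(v.max())
        if vmax_obs <= 0:
            raise ValueError("all velocities are non-positive; nothing to fit")

        # Initialization: Vmax0 slightly above the observed maximum; Km0 from
        # the concentration at half-maximal velocity by linear interpolation
        # of the mean velocity per concentration.
        uniq = np.unique(s)
        mean_v = np.array([v[s == u].mean() for u in uniq])
        half = vmax_obs / 2.0
        km0 = float(np.interp(half, mean_v, uniq)) if mean_v.max() >= half else float(uniq[-1])
        km0 = max(km0, 1e-9)
        p0 = (1.1 * vmax_obs, km0)

        sigma = None
        if self.weighting == "1/v2":
            sigma = np.abs(v)
            sigma[sigma == 0] = np.min(sigma[sigma > 0]) if np.any(sigma > 0) else 1.0
        elif self.weighting is not None:
            raise ValueError(f"unknown weighting {self.weighting!r}")

        converged = True
        try:
            popt, pcov = optimize.curve_fit(
                _mm,
                s,
                v,
                p0=p0,
                sigma=sigma,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                max_nfev=self.max_nfev,
                xtol=1e-13,
                ftol=1e-13,
                gtol=1e-13,
            )
        except RuntimeError:
            converged = False
            popt = np.array(p0)
            pcov = np.full((2, 2), np.nan)

        vmax, km = float(popt[0]), float(popt[1])
        resid = v - _mm(s, vmax, km)
        n = len(s)
        dof = max(n - 2, 1)
        tq = stats.t.ppf(0.975, dof)
        perr = np.sqrt(np.diag(pcov))

        self.Vmax_ = vmax
        self.Km_ = km
        self.Vmax_ci_ = (vmax - tq * perr[0], vmax + tq * perr[0])
        self.Km_ci_ = (km - tq * perr[1], km + tq * perr[1])
        self.residual_sse_ = float(np.sum(resid**2))
        self.n_points_ = n
        self.converged_ = bool(converged and np.all(np.isfinite(perr)))
        if self.enzyme_conc is not None:
            scale = 1.0 / (self.enzyme_conc * self.loading_fraction)
            self.kcat_ = vmax * scale
            self.kcat_ci_ = (self.Vmax_ci_[0] * scale, self.Vmax_ci_[1] * scale)
        return self

    def predict(self, X):
        s = np.asarray(X, dtype=float).reshape(-1)
        return _mm(s, self.Vmax_, self.Km_)


def fit_michaelis_menten(
    measurements: Sequence[RateMeasurement],
    loading_fraction: float = 1.0,
    weighting: str | None = None,
) -> MMFit:
    """Fit pooled initial-rate measurements for one enzyme/substrate.

    Replicates are pooled into a single least-squares problem.  All
    measurements must share one enzyme concentration.
    """
    if not measurements:
        raise ValueError("no measurements")
    e0 = {m.enzyme_conc for m in measurements}
    if len(e0) != 1:
        raise ValueError(f"measurements mix enzyme concentrations: {sorted(e0)}")
    s = [m.concentration for m in measurements]
    v = [m.velocity for m in measurements]
    reg = MichaelisMentenRegressor(
        enzyme_conc=e0.pop(), loading_fraction=loading_fraction, weighting=weighting
    ).fit(s, v)
    return MMFit(
        Km=reg.Km_,
        Km_ci=reg.Km_ci_,
        kcat=reg.kcat_,
        kcat_ci=reg.kcat_ci_,
        Vmax=reg.Vmax_,
        residual_sse=reg.residual_sse_,
        n_points=reg.n_points_,
        converged=reg.converged_,
    )


def round_2sf(x: float) -> float:
    """Round to two significant figures."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + 1)


def _render_2sf(x: float) -> str:
    r = round_2sf(x)
    exponent = math.floor(math.log10(abs(r))) if r != 0 else 0
    if exponent < 2:
        return f"{r:g}"
    mantissa = r / 10**exponent
    return f"{mantissa:g} × 10^{exponent}"


def catalytic_efficiency(Km: float, kcat: float) -> Efficiency:
    """kcat/KM in M⁻¹ s⁻¹ (Km supplied in mM), with a 2-s.f. rendering."""
    if Km <= 0:
        raise ValueError("Km must be positive")
    value = kcat / (Km * 1e-3)
    return Efficiency(value=value, rendered=_render_2sf(value))


def optimum_range(profile: ConditionProfile) -> OptimumRange:
    """Range of *tested* conditions with activity > 90% of the maximum.

    No interpolation: only conditions actually assayed can qualify, so the
    bounds are grid points.  A warning is raised when the qualifying set is
    non-contiguous on the tested grid (a bimodal or noisy profile).
    """
    points = sorted(profile.points)
    activities = [a for _, a in points]
    peak = max(activities)
    if peak == 0.0:
        # Degenerate flat-zero profile: the >90% predicate excludes every
        # point; report the whole tested range rather than nothing.
        idx = list(range(len(points)))
    else:
        idx = [i for i, (_, a) in enumerate(points) if a > 0.9 * peak]
    qualifying = [points[i][0] for i in idx]
    contiguous = idx == list(range(idx[0], idx[-1] + 1))
    if not contiguous:
        warnings.warn(
            f"optimum range of {profile.condition_type} profile is "
            f"non-contiguous on the tested grid: {qualifying}",
            stacklevel=2,
        )
    return OptimumRange(
        low=qualifying[0],
        high=qualifying[-1],
        qualifying=tuple(qualifying),
        contiguous=contiguous,
    )
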