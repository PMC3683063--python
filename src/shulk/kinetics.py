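"""Monod growth kinetics: rate law, crossover analysis, and parameter fitting.

The Monod model relates a population's specific growth rate to the ambient
concentration of a limiting resource,

    mu(s) = mu_max * s / (K_s + s),

where ``mu_max`` (1/h) is the maximal rate approached at saturating resource
and ``K_s`` (g/L) is the half-saturation constant — the concentration at which
growth runs at half speed.  Two strains whose parameters trade off (one with
the higher ``mu_max``, the other with the lower ``K_s``) have rate curves that
cross at a single positive concentration ``s*``: above it the fast-but-sloppy
"exploiter" grows faster, below it the slow-but-thrifty "gleaner" does.  Such
a pair is called an sHULK pair (species-pair with high mu_max and low K_s),
and the crossover is what makes the outcome of batch-culture competition
depend on how much resource a culture cycle spends above versus below ``s*``.

This module also extracts doubling times from optical-density growth curves
(log-linear window regression) and fits Monod parameters to growth-rate
versus concentration designs by nonlinear least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MonodParams",
    "GrowthCurve",
    "RateConcentrationDesign",
    "GenerationTimeResult",
    "MonodFitResult",
    "PairClass",
    "monod_rate",
    "crossover_concentration",
    "classify_pair",
    "generation_time",
    "generation_time_replicates",
    "fit_monod",
    "NoExponentialPhaseError",
    "MonodFitError",
]

LN2 = math.log(2.0)


class NoExponentialPhaseError(ValueError):
    """Raised when no log-linear window of acceptable quality exists."""


class MonodFitError(RuntimeError):
    """Raised when the Monod nonlinear fit fails to converge."""


@dataclass(frozen=True)
class MonodParams:
    """Monod parameters for one population on one resource.

    Parameters
    ----------
    mu_max : float
        Maximal specific growth rate (1/h); must be positive and finite.
    K_s : float
        Half-saturation constant (g/L); must be positive and finite.
    """

    mu_max: float
    K_s: float

    def __post_init__(self) -> None:
        for name, v in (("mu_max", self.mu_max), ("K_s", self.K_s)):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    @classmethod
    def from_doubling_time(cls, doubling_min: float, K_s: float) -> "MonodParams":
        """Build parameters whose saturating rate matches a doubling time in minutes."""
        return cls(mu_max=LN2 / (doubling_min / 60.0), K_s=K_s)


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate well of an OD600 time series.

    ``times`` are in hours and strictly increasing; ``od`` holds the matching
    optical-density readings (>= 0).  At least five points are required.
    """

    times: np.ndarray
    od: np.ndarray
    replicate_id: str = ""
    condition: str = "anaerobic"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if t.size < 5:
            raise ValueError("growth curve needs at least 5 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("od values must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)


@dataclass(frozen=True)
class RateConcentrationDesign:
    """Growth rates measured across a resource-concentration series.

    ``concentrations`` may be dimensionless medium-strength fractions in (0, 1]
    or absolute g/L; ``rates`` are specific growth rates (1/h).  ``replicate``
    labels which replicate each point belongs to (optional).
    """

    concentrations: np.ndarray
    rates: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if s.shape != r.shape or s.ndim != 1:
            raise ValueError("concentrations and rates must be 1-D of equal length")
        if np.any(s <= 0):
            raise ValueError("concentrations must be positive")
        object.__setattr__(self, "concentrations", s)
        object.__setattr__(self, "rates", r)
        if self.replicate is not None:
            object.__setattr__(self, "replicate", np.asarray(self.replicate))

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.concentrations).size)


PairClass = Literal[
    "sHULK_a_exploiter", "sHULK_b_exploiter", "a_dominates", "b_dominates", "identical"
]


def monod_rate(s, params: MonodParams):
    """Specific growth rate mu(s) = mu_max*s/(K_s+s) at resource concentration ``s``.

    Accepts scalars or arrays; ``s`` must be non-negative.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("resource concentration must be non-negative")
    out = params.mu_max * s_arr / (params.K_s + s_arr)
    return float(out) if np.isscalar(s) or s_arr.ndim == 0 else out


def crossover_concentration(a: MonodParams, b: MonodParams) -> float | None:
    """Concentration s* at which two Monod curves intersect, or None.

    Setting mu_a(s) = mu_b(s) and solving gives

        s* = (mu_max_a * K_s_b - mu_max_b * K_s_a) / (mu_max_b - mu_max_a).

    A strictly positive, finite s* exists exactly when the pair trades off
    (one strain has the higher mu_max, the other the lower K_s).  Returns
    None when one strain is at least as fast at every positive concentration
    or the curves coincide.
    """
    dmu = b.mu_max - a.mu_max
    if dmu == 0.0:
        return None  # parallel at saturation: curves cross only at s=0 or never
    s_star = (a.mu_max * b.K_s - b.mu_max * a.K_s) / dmu
    if not math.isfinite(s_star) or s_star <= 0.0:
        return None
    return s_star


def classify_pair(a: MonodParams, b: MonodParams) -> PairClass:
    """Classify a two-strain pair by the geometry of their Monod curves.

    ``sHULK_a_exploiter`` means the curves cross and ``a`` is the high-mu_max
    member (wins at high concentration); likewise for ``b``.  A dominance
    label means one curve lies on or above the other at every s > 0.
    """
    if a.mu_max == b.mu_max and a.K_s == b.K_s:
        return "identical"
    s_star = crossover_concentration(a, b)
    if s_star is not None:
        return "sHULK_a_exploiter" if a.mu_max > b.mu_max else "sHULK_b_exploiter"
    # No interior crossing: sign of mu_a - mu_b is constant on s > 0.
    # Evaluate at a concentration where the curves certainly differ.
    probe = max(a.K_s, b.K_s)
    diff = monod_rate(probe, a) - monod_rate(probe, b)
    if diff == 0.0:  # equal at probe but not identical: use small-s slope mu_max/K_s
        diff = a.mu_max / a.K_s - b.mu_max / b.K_s
    return "a_dominates" if diff > 0 else "b_dominates"


@dataclass(frozen=True)
class GenerationTimeResult:
    """Doubling time extracted from one growth curve."""

    doubling_min: float
    window: tuple[float, float]  # time bounds (h) of the fitted window
    r_squared: float
    slope_per_h: float
    n_points: int


def _window_fit(t: np.ndarray, logod: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line through (t, logod); returns (slope, intercept, R^2)."""
    slope, intercept = np.polyfit(t, logod, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((logod - fitted) ** 2))
    ss_tot = float(np.sum((logod - logod.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), r2


def generation_time(
    curve: GrowthCurve,
    min_window: int = 5,
    r2_threshold: float = 0.99,
    floor_frac: float = 0.10,
    ceil_frac: float = 0.75,
) -> GenerationTimeResult:
    """Doubling time (minutes) from the mid-log window of an OD curve.

    The optical background (minimum of the first three readings) is
    subtracted and the curve is restricted to its mid-log band — readings
    between ``floor_frac`` and ``ceil_frac`` of the post-subtraction maximum
    — which keeps the fit away from both the background-dominated start
    (where subtraction distorts the log transform) and the plateau.  Every
    window of at least ``min_window`` consecutive points in the band is fit
    by least squares on log(OD); among windows with positive slope and
    R^2 >= ``r2_threshold`` the longest wins (ties broken by higher R^2),
    and the doubling time is ln2/slope converted to minutes.  The result is
    invariant to uniform OD scaling and to adding a constant background.

    Raises
    ------
    NoExponentialPhaseError
        If no qualifying window exists (e.g. a flat curve).
    """
    background = float(np.min(curve.od[:3]))
    y = curve.od - background
    ymax = float(y.max())
    if ymax <= 0:
        raise NoExponentialPhaseError("curve never rises above background")
    keep = (y >= floor_frac * ymax) & (y <= ceil_frac * ymax) & (y > 0)
    t, y = curve.times[keep], y[keep]
    if t.size < min_window:
        raise NoExponentialPhaseError("too few points in the mid-log band")
    logod = np.log(y)

    best: GenerationTimeResult | None = None
    n = t.size
    for i in range(0, n - min_window + 1):
        for j in range(i + min_window, n + 1):
            slope, _, r2 = _window_fit(t[i:j], logod[i:j])
            if slope <= 0 or r2 < r2_threshold:
                continue
            better = best is None or (j - i, r2) > (best.n_points,
                                                    best.r_squared)
            if better:
                best = GenerationTimeResult(
                    doubling_min=LN2 / slope * 60.0,
                    window=(float(t[i]), float(t[j - 1])),
                    r_squared=r2,
                    slope_per_h=slope,
                    n_points=j - i,
                )
    if best is None:
        raise NoExponentialPhaseError(
            f"no window of >= {min_window} points with positive slope and "
            f"R^2 >= {r2_threshold}"
        )
    return best


def generation_time_replicates(
    curves: Sequence[GrowthCurve], **kwargs
) -> tuple[float, float, list[GenerationTimeResult]]:
    """Mean doubling time (min) +/- standard error over replicate curves."""
    results = [generation_time(c, **kwargs) for c in curves]
    vals = np.array([r.doubling_min for r in results])
    se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
    return float(vals.mean()), se, results


@dataclass(frozen=True)
class MonodFitResult:
    """Nonlinear least-squares Monod fit with approximate standard errors."""

    params: MonodParams
    se_mu_max: float
    se_K_s: float
    rss: float
    n_obs: int
    flags: list[str] = field(default_factory=list)

    @property
    def ks_identifiable(self) -> bool:
        return "ks_unidentifiable" not in self.flags


def _monod_model(s, mu_max, K_s):
    return mu_max * s / (K_s + s)


def fit_monod(
    design: RateConcentrationDesign,
    n_restarts: int = 5,
    seed: int = 0,
) -> MonodFitResult:
    """Fit mu(s) = mu_max*s/(K_s+s) to a rate-versus-concentration design.

    Initialisation: mu_max0 = max observed rate; K_s0 = the concentration at
    which the observed rate is nearest mu_max0/2.  On convergence failure the
    fit is retried up to ``n_restarts`` times from multiplicatively jittered
    starts.  Parameters are bounded positive.

    A ``ks_unidentifiable`` flag is set when the design carries no curvature
    information (all rates essentially equal — a saturated design) or when the
    K_s standard error exceeds the estimate tenfold.
    """
    if design.n_distinct < 4:
        raise ValueError("need at least 4 distinct concentrations to fit Monod")
    s = design.concentrations
    r = design.rates
    if np.any(r <= 0):
        raise ValueError("rates must be positive")

    flags: list[str] = []
    spread = float(r.max() - r.min())
    if spread <= 1e-3 * float(r.mean()):
        flags.append("ks_unidentifiable")

    mu0 = float(r.max())
    k0 = float(s[np.argmin(np.abs(r - mu0 / 2.0))])
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            p0 = (mu0, k0)
        else:
            jitter = rng.lognormal(mean=0.0, sigma=0.5, size=2)
            p0 = (mu0 * jitter[0], k0 * jitter[1])
        try:
            popt, pcov = curve_fit(
                _monod_model, s, r, p0=p0,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError) as err:
            last_err = err
            continue
        perr = np.sqrt(np.diag(pcov))
        resid = r - _monod_model(s, *popt)
        if np.isfinite(perr[1]) and perr[1] > 10.0 * popt[1]:
            if "ks_unidentifiable" not in flags:
                flags.append("ks_unidentifiable")
        return MonodFitResult(
            params=MonodParams(mu_max=float(popt[0]), K_s=float(popt[1])),
            se_mu_max=float(perr[0]),
            se_K_s=float(perr[1]),
            rss=float(np.sum(resid**2)),
            n_obs=int(s.size),
            flags=flags,
        )
    raise MonodFitError(
        f"Monod fit failed after {n_restarts} restarts "
        f"(last start {p0}): {last_err}"
    )
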