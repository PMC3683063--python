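"""Decompose mixed marker-gene electropherograms into strain proportions.

When a sample contains several strains, direct Sanger sequencing of a marker
fragment (e.g. *mdh*) yields a trace that is a proportion-weighted
superposition of the pure strains' traces.  Given aligned intensity vectors —
one "unit spectrum" per pure strain plus the mixed trace — relative
abundances are recovered by constrained multivariate linear regression:
non-negative least squares of the mixed trace on the unit spectra, with the
coefficients renormalised to sum to one.  The R-squared and overall
regression p-value of the (unconstrained) multiple linear regression are
reported as fit diagnostics, and components under the method's empirical
detection limit (about 5% relative abundance) are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.optimize import nnls

__all__ = [
    "TraceMatrix",
    "UnmixResult",
    "unmix",
    "flag_detection",
    "mixed_base_call_check",
    "BaseCallComparison",
    "UnidentifiableError",
    "DETECTION_LIMIT",
]

# Empirical floor below which a component cannot be reliably reported.
DETECTION_LIMIT = 0.05

CONDITION_LIMIT = 1e6


class UnidentifiableError(ValueError):
    """Raised when the unit spectra are too collinear to separate."""


@dataclass(frozen=True)
class TraceMatrix:
    """Aligned unit spectra and a mixed trace.

    ``unit_spectra`` has one column per pure strain; ``mixed`` is the
    observed superposed trace on the same position grid.
    """

    positions: np.ndarray
    unit_spectra: np.ndarray  # (n_positions, n_strains)
    mixed: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions)
        U = np.asarray(self.unit_spectra, dtype=float)
        m = np.asarray(self.mixed, dtype=float)
        if U.ndim != 2:
            raise ValueError("unit_spectra must be a 2-D matrix")
        n_pos, n_strains = U.shape
        if pos.shape != (n_pos,) or m.shape != (n_pos,):
            raise ValueError("positions, unit spectra rows and mixed trace "
                             "must have equal length")
        if len(self.labels) != n_strains:
            raise ValueError("one label per unit-spectrum column required")
        if n_pos < n_strains + 2:
            raise ValueError("need at least 2 more positions than strains")
        if np.any(U < 0) or np.any(m < 0):
            raise ValueError("intensities must be non-negative")
        for i in range(n_strains):
            for j in range(i + 1, n_strains):
                if np.array_equal(U[:, i], U[:, j]):
                    raise ValueError(
                        f"unit spectra {self.labels[i]!r} and {self.labels[j]!r} "
                        "are identical"
                    )
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "unit_spectra", U)
        object.__setattr__(self, "mixed", m)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_strains(self) -> int:
        return self.unit_spectra.shape[1]


@dataclass(frozen=True)
class UnmixResult:
    labels: tuple[str, ...]
    proportions: np.ndarray  # non-negative, sums to 1
    r_squared: float
    p_value: float
    residual: np.ndarray
    below_detection: np.ndarray  # bool per strain
    detection_limit: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, map(float, self.proportions)))


def _normalise_columns(U: np.ndarray) -> np.ndarray:
    sums = U.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("each unit spectrum must have positive total intensity")
    return U / sums


def rolling_minimum_baseline(trace: np.ndarray, window: int = 51) -> np.ndarray:
    """Optional baseline correction: subtract a rolling minimum (off by default)."""
    from scipy.ndimage import minimum_filter1d

    baseline = minimum_filter1d(np.asarray(trace, dtype=float), size=window,
                                mode="nearest")
    return trace - baseline


def unmix(
    tm: TraceMatrix,
    detection_limit: float = DETECTION_LIMIT,
    constrained: bool = True,
) -> UnmixResult:
    """Estimate strain proportions from a mixed trace.

    Unit-spectrum columns are scaled to unit sum so coefficients read as
    signal fractions, then the mixed trace is regressed on them.  With
    ``constrained=True`` (default) the coefficients come from non-negative
    least squares and are renormalised to sum to one; the unconstrained
    ordinary-least-squares fit supplies R^2 and the overall regression
    p-value (F-test, no intercept) either way.

    Raises
    ------
    UnidentifiableError
        If the condition number of the normalised design exceeds 1e6.
    ValueError
        If the mixed trace is all zero.
    """
    if not np.any(tm.mixed > 0):
        raise ValueError("mixed trace is all zero")
    U = _normalise_columns(tm.unit_spectra)
    cond = np.linalg.cond(U)
    if cond > CONDITION_LIMIT:
        raise UnidentifiableError(
            f"unit spectra nearly collinear (condition number {cond:.3g} > "
            f"{CONDITION_LIMIT:.0e}); proportions are unidentifiable"
        )
    y = tm.mixed

    # Diagnostics from the unconstrained multiple linear regression.
    beta_ols, _, _, _ = np.linalg.lstsq(U, y, rcond=None)
    fitted_ols = U @ beta_ols
    ss_res = float(np.sum((y - fitted_ols) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    k = tm.n_strains
    dof = y.size - k
    if ss_res <= 0 or r2 >= 1.0:
        p_value = 0.0
        r2 = min(r2, 1.0)
    else:
        f_stat = (r2 / k) / ((1.0 - r2) / dof)
        p_value = float(sps.f.sf(f_stat, k, dof))

    if constrained:
        if np.all(beta_ols >= 0):
            # active set empty: the NNLS solution IS the OLS solution
            beta = beta_ols
        else:
            beta, _ = nnls(U, y)
    else:
        beta = np.clip(beta_ols, 0.0, None)
    total = beta.sum()
    if total <= 0:
        raise ValueError("regression assigned no signal to any strain")
    proportions = beta / total
    residual = y - U @ beta
    flags = proportions < detection_limit
    return UnmixResult(
        labels=tm.labels,
        proportions=proportions,
        r_squared=float(r2),
        p_value=p_value,
        residual=residual,
        below_detection=flags,
        detection_limit=detection_limit,
    )


def flag_detection(
    proportions: Sequence[float], threshold: float = DETECTION_LIMIT
) -> tuple[np.ndarray, np.ndarray]:
    """Flag components below the detection limit without altering their values.

    Returns ``(proportions, flags)``; a flagged value means "present below
    the level at which the trace method can quantify it", not zero.
    """
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    return p, p < threshold


@dataclass(frozen=True)
class BaseCallComparison:
    """Expected versus observed mixed-peak positions for a two-strain sample."""

    expected_positions: tuple[int, ...]  # where the two pure sequences differ
    observed_positions: tuple[int, ...]
    discordant: tuple[int, ...] = field(default=())

    @property
    def n_discordant(self) -> int:
        return len(self.discordant)


def mixed_base_call_check(
    seq_a: str, seq_b: str, mixed_positions: Sequence[int] = ()
) -> BaseCallComparison:
    """Compare observed mixed-peak positions with the sites where two strains differ.

    A sample containing two strains should show mixed base calls exactly at
    the positions (0-based) where the strains' marker sequences disagree.
    Returns those expected positions together with the symmetric difference
    against an observed mixed-position list.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    valid = set("ACGT")
    for name, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        bad = set(s.upper()) - valid
        if bad:
            raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    expected = tuple(
        i for i, (x, y) in enumerate(zip(seq_a.upper(), seq_b.upper())) if x != y
    )
    observed = tuple(sorted(set(int(i) for i in mixed_positions)))
    discordant = tuple(sorted(set(expected).symmetric_difference(observed)))
    return BaseCallComparison(expected, observed, discordant)
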