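"""Seeded generators for every input the pipeline consumes.

Each generator emulates one of the study's measurement types — triplicate
plate-reader growth curves, growth-rate-versus-concentration designs,
pure-strain and mixed electropherogram traces, and sampled competition
compositions — and returns the ground truth alongside the noisy data so
recovery tests are self-contained.  All randomness flows through a single
integer seed; identical configuration gives identical output.

Default noise levels: 1% multiplicative (lognormal) noise on OD readings and
rates, additive Gaussian noise at 1% of peak intensity on traces, and a
multinomial sampling depth of 200 for composition observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .batch import CompetitionSeries
from .kinetics import LN2, GrowthCurve, MonodParams, RateConcentrationDesign
from .unmix import DETECTION_LIMIT, TraceMatrix

__all__ = [
    "gen_growth_curves",
    "gen_rate_design",
    "gen_traces",
    "gen_competition_observations",
    "GrowthCurveSet",
    "TraceTruth",
]

OD_NOISE_SD = 0.01
TRACE_NOISE_SD = 0.01  # fraction of max intensity
SAMPLING_DEPTH = 200


@dataclass(frozen=True)
class GrowthCurveSet:
    """Replicate growth curves with the generating ground truth."""

    curves: tuple[GrowthCurve, ...]
    truth: dict = field(default_factory=dict)


def gen_growth_curves(
    doubling_min: float,
    n_replicates: int = 3,
    duration_h: float = 12.0,
    dt_min: float = 10.0,
    od0: float = 0.001,
    background: float = 0.05,
    plateau_od: float = 1.2,
    noise_sd: float = OD_NOISE_SD,
    seed: int = 0,
    condition: str = "anaerobic",
) -> GrowthCurveSet:
    """Triplicate-style OD600 curves from an exponential-then-plateau model.

    The noiseless signal is ``background + min(od0 * 2^(t/Td), plateau)``;
    multiplicative lognormal noise of standard deviation ``noise_sd`` is
    applied to the biological signal (not the optical background).
    """
    if doubling_min <= 0:
        raise ValueError("doubling time must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, dt_min / 60.0)
    signal = np.minimum(od0 * 2.0 ** (t * 60.0 / doubling_min), plateau_od)
    curves = []
    sigma = np.sqrt(np.log1p(noise_sd**2))  # lognormal sd ~ noise_sd
    for k in range(n_replicates):
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=t.size) \
            if noise_sd > 0 else 1.0
        od = background + signal * noise
        curves.append(GrowthCurve(times=t, od=od, replicate_id=f"rep{k+1}",
                                  condition=condition))
    truth = {"doubling_min": doubling_min, "mu_per_h": LN2 / (doubling_min / 60.0),
             "background": background, "od0": od0, "noise_sd": noise_sd,
             "seed": seed}
    return GrowthCurveSet(tuple(curves), truth)


def gen_rate_design(
    params: MonodParams,
    concentrations: Sequence[float] = (0.05, 0.1, 0.2, 0.4, 0.8),
    n_replicates: int = 3,
    noise_sd: float = OD_NOISE_SD,
    seed: int = 0,
) -> tuple[RateConcentrationDesign, dict]:
    """Growth-rate measurements across a concentration series.

    Rates are Monod-model values with multiplicative lognormal noise; the
    generating parameters are returned as ground truth.  A design with a
    single distinct concentration is flagged unusable in the truth dict.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    s = np.repeat(conc, n_replicates)
    rep = np.tile(np.arange(1, n_replicates + 1), conc.size)
    clean = params.mu_max * s / (params.K_s + s)
    if noise_sd > 0:
        sigma = np.sqrt(np.log1p(noise_sd**2))
        rates = clean * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma,
                                      size=s.size)
    else:
        rates = clean
    design = RateConcentrationDesign(concentrations=s, rates=rates,
                                     replicate=rep)
    truth = {"mu_max": params.mu_max, "K_s": params.K_s, "noise_sd": noise_sd,
             "seed": seed, "usable": int(np.unique(conc).size >= 4)}
    return design, truth


@dataclass(frozen=True)
class TraceTruth:
    proportions: tuple[float, ...]
    peak_positions: tuple[tuple[int, ...], ...]
    noise_sd: float
    seed: int


def _gaussian_peaks(length: int, centers: Sequence[int], width: float,
                    height: float = 100.0) -> np.ndarray:
    x = np.arange(length)
    y = np.zeros(length)
    for c in centers:
        y += height * np.exp(-0.5 * ((x - c) / width) ** 2)
    return y


def gen_traces(
    mixture: Sequence[float],
    length: int = 300,
    n_peaks: int = 8,
    peak_width: float = 3.0,
    noise_sd: float = TRACE_NOISE_SD,
    seed: int = 0,
) -> tuple[TraceMatrix, TraceTruth]:
    """Unit spectra plus a mixed trace with known mixing proportions.

    Each strain's unit spectrum is a sum of Gaussian peaks at strain-specific
    positions drawn without replacement from the position grid, so no two
    strains share an identical peak set.  The mixed trace is the
    proportion-weighted sum of unit spectra plus additive Gaussian noise with
    standard deviation ``noise_sd`` times the maximum mixed intensity.
    """
    props = np.asarray(list(mixture), dtype=float)
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("mixture proportions must be non-negative and sum to 1")
    n_strains = props.size
    rng = np.random.default_rng(seed)
    # Disjoint-ish peak sets: partition candidate centers between strains.
    margin = int(4 * peak_width)
    candidates = rng.permutation(np.arange(margin, length - margin))
    needed = n_strains * n_peaks
    if candidates.size < needed:
        raise ValueError("trace too short for the requested peak count")
    peak_sets = tuple(
        tuple(sorted(int(c) for c in candidates[i * n_peaks:(i + 1) * n_peaks]))
        for i in range(n_strains)
    )
    if len(set(peak_sets)) < n_strains:
        raise ValueError("degenerate identical peak sets")
    U = np.column_stack([
        _gaussian_peaks(length, centers, peak_width) for centers in peak_sets
    ])
    # Equalise total signal per strain so the mixing proportions are exactly
    # the signal fractions the decomposition estimates.
    U *= U.sum(axis=0).mean() / U.sum(axis=0)
    mixed_clean = U @ props
    if noise_sd > 0:
        mixed = mixed_clean + rng.normal(
            0.0, noise_sd * mixed_clean.max(), size=length)
        mixed = np.clip(mixed, 0.0, None)
    else:
        mixed = mixed_clean
    tm = TraceMatrix(
        positions=np.arange(length),
        unit_spectra=U,
        mixed=mixed,
        labels=tuple(f"strain{i+1}" for i in range(n_strains)),
    )
    return tm, TraceTruth(tuple(map(float, props)), peak_sets, noise_sd, seed)


def gen_competition_observations(
    series: CompetitionSeries,
    depth: int = SAMPLING_DEPTH,
    seed: int = 0,
    detection_limit: float = DETECTION_LIMIT,
) -> CompetitionSeries:
    """Sampled (noisy) version of a true composition series.

    At each index, draws a multinomial of size ``depth`` over the true
    fractions and renormalises — the counting noise of a finite measurement —
    then re-applies detection flags.  True zeroes stay zero.
    """
    if depth < 1:
        raise ValueError("depth must be at least 1")
    rng = np.random.default_rng(seed)
    true = series.fractions.to_numpy()
    obs = np.empty_like(true)
    for i in range(true.shape[0]):
        row = true[i]
        if np.any(~np.isfinite(row)):
            obs[i] = row
            continue
        counts = rng.multinomial(depth, row / row.sum())
        obs[i] = counts / depth
    frac = series.fractions.copy()
    frac.iloc[:, :] = obs
    flags = frac < detection_limit
    return CompetitionSeries(series.index, frac, flags, series.level,
                             series.index_name)
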