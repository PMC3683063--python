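"""Consumer-resource simulation of batch and serial-batch culture.

The engine behind the competition analyses: populations (strains of a focal
species plus background species) grow on one or more shared, substitutable
resources with Monod kinetics, closed by yield coefficients,

    dN_i/dt = [ sum_r mu_{i,r}(s_r) - d_i ] * N_i
    ds_r/dt = - sum_i mu_{i,r}(s_r) * N_i / Y_{i,r}
              + rho * sum_i d_i * N_i * w_{i,r}

where ``mu_{i,r}(s) = mu_max_{i,r} s / (K_{i,r} + s)``, ``Y_{i,r}`` is the
biomass yield on resource r (g/g), ``d_i`` a slow biomass turnover rate, and
``rho`` (``recycling_fraction``) the fraction of turned-over biomass returned
to the resource pools with composition weights ``w_{i,r}``.  With d = 0 and
rho = 0 the quantity ``s + sum_i N_i/Y_i`` is conserved on a single resource.

Serial transfer repeats a batch cycle: at each transfer the culture is
diluted into fresh medium (densities multiplied by the dilution factor,
resources reset), producing the pulsed high-to-low resource dynamics under
which a gleaner/exploiter (sHULK) pair's competitive balance depends on the
time each cycle spends above versus below the rate-crossover concentration.
Long-term stationary phase is the same model with no renewal: turnover plus
recycling holds the resource at a low quasi-steady level that favours the
low-K_s gleaner.

Simulated compositions are never censored; the ~5% detection floor of the
trace-based abundance measurements is applied only as reporting flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import MonodParams
from .unmix import DETECTION_LIMIT

__all__ = [
    "PopulationSpec",
    "Medium",
    "TransferRegime",
    "BatchTrajectory",
    "CompetitionSeries",
    "SerialResult",
    "SerialState",
    "SpikeEvent",
    "simulate_batch",
    "simulate_batch_euler",
    "simulate_serial",
    "simulate_stationary",
    "spike_species",
    "transfers_to_exclusion",
    "nutrient_timecourse",
    "composition",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when the ODE integration fails; carries the offending state."""


@dataclass(frozen=True)
class PopulationSpec:
    """One population (strain or background species) in the culture.

    ``monod`` maps resource id -> :class:`MonodParams`; ``yields`` maps the
    same resource ids to biomass yields Y (g biomass per g resource).
    ``recycle_weights`` distributes recycled turnover biomass over resources
    (defaults to uniform over the resources the population consumes).
    """

    id: str
    monod: Mapping[str, MonodParams]
    yields: Mapping[str, float]
    level: str = "strain"  # "strain" | "species"
    species: str = ""
    death_rate: float = 0.0
    init_density: float = 0.0
    recycle_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.level not in ("strain", "species"):
            raise ValueError("level must be 'strain' or 'species'")
        if not self.monod:
            raise ValueError(f"population {self.id!r} consumes no resource")
        if set(self.yields) != set(self.monod):
            raise ValueError("yields must cover exactly the consumed resources")
        if any(y <= 0 for y in self.yields.values()):
            raise ValueError("yields must be positive")
        if self.death_rate < 0:
            raise ValueError("death_rate must be non-negative")
        if self.init_density < 0:
            raise ValueError("init_density must be non-negative")
        if not self.species:
            object.__setattr__(self, "species", self.id)


@dataclass(frozen=True)
class Medium:
    """Fresh-medium recipe: base resource concentrations times a strength factor."""

    resources: Mapping[str, float]
    strength_fraction: float = 1.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.resources.values()):
            raise ValueError("resource concentrations must be non-negative")
        if not 0.0 < self.strength_fraction <= 2.0:
            raise ValueError("strength_fraction must lie in (0, 2]")

    @property
    def resource_ids(self) -> tuple[str, ...]:
        return tuple(self.resources)

    def initial_concentrations(self) -> np.ndarray:
        return np.array(
            [self.resources[r] * self.strength_fraction for r in self.resources]
        )


@dataclass(frozen=True)
class TransferRegime:
    """Serial-transfer schedule: cycle length, carryover dilution, cycle count."""

    period_h: float
    dilution_factor: float = 0.01
    n_transfers: int = 10
    sampling: str = "per_transfer"  # or "per_day"

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise ValueError("period must be positive")
        if not 0.0 < self.dilution_factor < 1.0:
            raise ValueError("dilution_factor must lie in (0, 1)")
        if self.n_transfers < 1:
            raise ValueError("need at least one transfer")
        if self.sampling not in ("per_transfer", "per_day"):
            raise ValueError("sampling must be 'per_transfer' or 'per_day'")


@dataclass(frozen=True)
class BatchTrajectory:
    """Continuous-time state of one culture cycle."""

    times: np.ndarray  # (T,) hours
    densities: np.ndarray  # (T, n_pops) g/L
    resources: np.ndarray  # (T, n_resources) g/L
    population_ids: tuple[str, ...]
    resource_ids: tuple[str, ...]

    def final_densities(self) -> np.ndarray:
        return self.densities[-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.densities, columns=list(self.population_ids))
        for j, r in enumerate(self.resource_ids):
            df[f"resource:{r}"] = self.resources[:, j]
        df.insert(0, "time_h", self.times)
        return df


@dataclass(frozen=True)
class CompetitionSeries:
    """Relative abundances over transfers (or days) at one taxonomic level."""

    index: np.ndarray  # transfer number or day
    fractions: pd.DataFrame  # rows match index, one column per population
    below_detection: pd.DataFrame
    level: str
    index_name: str = "transfer"

    def tidy(self) -> pd.DataFrame:
        """Long-form table: index, population, level, fraction, below_detection."""
        frac = self.fractions.copy()
        frac[self.index_name] = self.index
        long = frac.melt(id_vars=self.index_name, var_name="population",
                         value_name="fraction")
        flags = self.below_detection.copy()
        flags[self.index_name] = self.index
        flong = flags.melt(id_vars=self.index_name, var_name="population",
                           value_name="below_detection")
        out = long.merge(flong, on=[self.index_name, "population"])
        out["level"] = self.level
        return out


class _ModelArrays:
    """Vectorised parameter arrays for the ODE right-hand side."""

    def __init__(self, populations: Sequence[PopulationSpec],
                 resource_ids: Sequence[str]):
        self.pop_ids = tuple(p.id for p in populations)
        if len(set(self.pop_ids)) != len(self.pop_ids):
            raise ValueError("population ids must be unique")
        self.resource_ids = tuple(resource_ids)
        P, R = len(populations), len(resource_ids)
        self.mu_max = np.zeros((P, R))
        self.K = np.ones((P, R))
        self.inv_yield = np.zeros((P, R))
        self.w = np.zeros((P, R))
        self.d = np.array([p.death_rate for p in populations])
        for i, p in enumerate(populations):
            unknown = set(p.monod) - set(resource_ids)
            if unknown:
                raise ValueError(
                    f"population {p.id!r} consumes resources {sorted(unknown)} "
                    "absent from the medium"
                )
            for r, params in p.monod.items():
                j = self.resource_ids.index(r)
                self.mu_max[i, j] = params.mu_max
                self.K[i, j] = params.K_s
                self.inv_yield[i, j] = 1.0 / p.yields[r]
            if p.recycle_weights is not None:
                total = sum(p.recycle_weights.values())
                for r, wv in p.recycle_weights.items():
                    self.w[i, self.resource_ids.index(r)] = wv / total
            else:
                consumed = [self.resource_ids.index(r) for r in p.monod]
                self.w[i, consumed] = 1.0 / len(consumed)

    def rates(self, s: np.ndarray) -> np.ndarray:
        """Per-population, per-resource Monod rates at concentrations ``s``."""
        s_pos = np.maximum(s, 0.0)
        return self.mu_max * s_pos / (self.K + s_pos)

    def rhs(self, n: np.ndarray, s: np.ndarray, rho: float
            ) -> tuple[np.ndarray, np.ndarray]:
        n_pos = np.maximum(n, 0.0)
        mu = self.rates(s)  # (P, R)
        growth = mu.sum(axis=1)
        dn = (growth - self.d) * n_pos
        uptake = (mu * self.inv_yield).T @ n_pos  # (R,)
        recycled = rho * (self.w.T @ (self.d * n_pos))
        ds = -uptake + recycled
        return dn, ds


def _integrate(
    arrays: _ModelArrays,
    n0: np.ndarray,
    s0: np.ndarray,
    duration: float,
    rho: float,
    n_points: int,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    P = n0.size

    def fun(_t, y):
        dn, ds = arrays.rhs(y[:P], y[P:], rho)
        return np.concatenate([dn, ds])

    t_eval = np.linspace(0.0, duration, n_points)
    sol = solve_ivp(fun, (0.0, duration), np.concatenate([n0, s0]),
                    method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise SimulationError(
            f"integration failed: {sol.message}; last state {sol.y[:, -1]!r}"
        )
    y = sol.y.T
    # Numerical undershoot below zero is clipped in the reported trajectory.
    return sol.t, np.clip(y[:, :P], 0.0, None), np.clip(y[:, P:], 0.0, None)


def simulate_batch(
    populations: Sequence[PopulationSpec],
    medium: Medium,
    duration: float,
    recycling_fraction: float = 0.0,
    n_points: int = 201,
    init_densities: np.ndarray | None = None,
    init_resources: np.ndarray | None = None,
) -> BatchTrajectory:
    """Integrate one batch-culture cycle of ``duration`` hours.

    ``init_densities``/``init_resources`` override the specs' initial state
    (used by the serial-transfer loop to carry state between cycles).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0.0 <= recycling_fraction < 1.0:
        raise ValueError("recycling_fraction must lie in [0, 1)")
    rids = medium.resource_ids
    s0 = medium.initial_concentrations() if init_resources is None \
        else np.asarray(init_resources, dtype=float)
    if not populations:
        t = np.linspace(0.0, duration, n_points)
        return BatchTrajectory(t, np.zeros((n_points, 0)),
                               np.tile(s0, (n_points, 1)), (), rids)
    arrays = _ModelArrays(populations, rids)
    n0 = np.array([p.init_density for p in populations]) \
        if init_densities is None else np.asarray(init_densities, dtype=float)
    t, n, s = _integrate(arrays, n0, s0, duration, recycling_fraction, n_points)
    return BatchTrajectory(t, n, s, arrays.pop_ids, rids)


def simulate_batch_euler(
    populations: Sequence[PopulationSpec],
    medium: Medium,
    duration: float,
    recycling_fraction: float = 0.0,
    dt: float = 1e-3,
    init_densities: np.ndarray | None = None,
    init_resources: np.ndarray | None = None,
    record_every: int = 1000,
) -> BatchTrajectory:
    """Fixed-step forward-Euler reference integration of the same model.

    A deliberately simple independent integration path used to validate the
    adaptive solver; state is clipped at zero after each step.
    """
    rids = medium.resource_ids
    arrays = _ModelArrays(populations, rids)
    n = np.array([p.init_density for p in populations], dtype=float) \
        if init_densities is None else np.asarray(init_densities, dtype=float).copy()
    s = medium.initial_concentrations() if init_resources is None \
        else np.asarray(init_resources, dtype=float).copy()
    n_steps = int(round(duration / dt))
    times, dens, res = [0.0], [n.copy()], [s.copy()]
    for step in range(1, n_steps + 1):
        dn, ds = arrays.rhs(n, s, recycling_fraction)
        n = np.maximum(n + dt * dn, 0.0)
        s = np.maximum(s + dt * ds, 0.0)
        if step % record_every == 0 or step == n_steps:
            times.append(step * dt)
            dens.append(n.copy())
            res.append(s.copy())
    return BatchTrajectory(np.array(times), np.vstack(dens), np.vstack(res),
                           arrays.pop_ids, rids)


def composition(
    densities: np.ndarray,
    populations: Sequence[PopulationSpec],
    level: str,
) -> pd.DataFrame:
    """Relative abundances at ``level`` from absolute densities.

    ``level='strain'``: fractions among strain-level populations of the focal
    species (the species to which the strain populations belong).
    ``level='species'``: strains are aggregated into their species and
    fractions are of the whole community.

    ``densities`` may be (P,) or (T, P); returns a DataFrame with one column
    per reported population.
    """
    dens = np.atleast_2d(np.asarray(densities, dtype=float))
    if level == "strain":
        idx = [i for i, p in enumerate(populations) if p.level == "strain"]
        if not idx:
            raise ValueError("no strain-level populations present")
        species = {populations[i].species for i in idx}
        if len(species) > 1:
            raise ValueError(
                f"strain-level populations span several species {sorted(species)}; "
                "strain fractions are defined within one focal species"
            )
        sub = dens[:, idx]
        cols = [populations[i].id for i in idx]
    elif level == "species":
        names: list[str] = []
        for p in populations:
            if p.species not in names:
                names.append(p.species)
        sub = np.zeros((dens.shape[0], len(names)))
        for i, p in enumerate(populations):
            sub[:, names.index(p.species)] += dens[:, i]
        cols = names
    else:
        raise ValueError("level must be 'strain' or 'species'")
    totals = sub.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, sub / totals, np.nan)
    return pd.DataFrame(frac, columns=cols)


def _series_from_states(
    index: np.ndarray,
    states: np.ndarray,
    populations: Sequence[PopulationSpec],
    level: str,
    detection_limit: float,
    index_name: str,
) -> CompetitionSeries:
    frac = composition(states, populations, level)
    flags = frac < detection_limit
    return CompetitionSeries(np.asarray(index), frac, flags, level, index_name)


@dataclass(frozen=True)
class SerialState:
    """Snapshot of a serial-transfer run, resumable by :func:`simulate_serial`."""

    populations: tuple[PopulationSpec, ...]
    densities: np.ndarray  # end-of-cycle densities, pre-dilution
    medium: Medium
    regime: TransferRegime
    recycling_fraction: float
    transfers_done: int


@dataclass(frozen=True)
class SpikeEvent:
    """Add a species at the start of cycle ``at_transfer`` (1-based).

    The dose is ``dose_ratio`` times the current total density of the focal
    (strain-level) species, mirroring a 10:1 volume spike of a dense culture.
    """

    at_transfer: int
    spec: PopulationSpec
    dose_ratio: float = 10.0

    def __post_init__(self) -> None:
        if self.dose_ratio < 0:
            raise ValueError("dose_ratio must be non-negative")


@dataclass(frozen=True)
class SerialResult:
    """End-of-cycle states of a serial-transfer competition."""

    transfer_index: np.ndarray
    times_h: np.ndarray
    densities: np.ndarray  # (n_transfers, P) at each cycle end
    populations: tuple[PopulationSpec, ...]
    trajectories: tuple[BatchTrajectory, ...]
    state: SerialState
    detection_limit: float = DETECTION_LIMIT

    def strain_series(self) -> CompetitionSeries:
        return _series_from_states(self.transfer_index, self.densities,
                                   self.populations, "strain",
                                   self.detection_limit, "transfer")

    def species_series(self) -> CompetitionSeries:
        return _series_from_states(self.transfer_index, self.densities,
                                   self.populations, "species",
                                   self.detection_limit, "transfer")


def _dilute_and_spike(
    populations: list[PopulationSpec],
    densities: np.ndarray,
    medium: Medium,
    dilution: float,
    events: Sequence[SpikeEvent],
    next_transfer: int,
) -> tuple[list[PopulationSpec], np.ndarray]:
    densities = densities * dilution
    for ev in events:
        if ev.at_transfer != next_transfer:
            continue
        focal = sum(
            densities[i] for i, p in enumerate(populations) if p.level == "strain"
        )
        dose = ev.dose_ratio * focal
        ids = [p.id for p in populations]
        if ev.spec.id in ids:
            densities[ids.index(ev.spec.id)] += dose
        else:
            populations = populations + [ev.spec]
            densities = np.append(densities, dose)
    return populations, densities


def simulate_serial(
    populations: Sequence[PopulationSpec],
    medium: Medium,
    regime: TransferRegime,
    recycling_fraction: float = 0.0,
    events: Sequence[SpikeEvent] = (),
    keep_trajectories: bool = False,
    points_per_cycle: int = 51,
    detection_limit: float = DETECTION_LIMIT,
    _resume: SerialState | None = None,
) -> SerialResult:
    """Run a serial-transfer competition.

    Each cycle integrates one batch of ``regime.period_h`` hours; at the
    transfer the culture is diluted by ``regime.dilution_factor`` into fresh
    medium (resources reset, never interpolated across the discontinuity).
    Spike events fire at the start of their cycle, after dilution.
    Compositions are recorded at each cycle end.
    """
    pops = list(populations)
    if _resume is not None:
        dens = _resume.densities * regime.dilution_factor
        t0 = _resume.transfers_done
    else:
        dens = np.array([p.init_density for p in pops], dtype=float)
        t0 = 0
    idx, times, states, trajs = [], [], [], []
    for k in range(1, regime.n_transfers + 1):
        transfer = t0 + k
        # Cycle 1 starts from the given densities (resume pre-dilutes above);
        # later cycles are diluted into fresh medium first.
        dil = regime.dilution_factor if k > 1 else 1.0
        pops, dens = _dilute_and_spike(pops, dens, medium, dil, events,
                                       transfer)
        traj = simulate_batch(pops, medium, regime.period_h,
                              recycling_fraction, n_points=points_per_cycle,
                              init_densities=dens,
                              init_resources=medium.initial_concentrations())
        dens = traj.final_densities().copy()
        idx.append(transfer)
        times.append(transfer * regime.period_h)
        states.append(dens.copy())
        if keep_trajectories:
            trajs.append(traj)
    P = len(pops)
    padded = np.zeros((len(states), P))
    for row, st in enumerate(states):
        padded[row, :st.size] = st
    state = SerialState(tuple(pops), dens, medium, regime,
                        recycling_fraction, t0 + regime.n_transfers)
    return SerialResult(np.array(idx), np.array(times, dtype=float), padded,
                        tuple(pops), tuple(trajs), state, detection_limit)


def spike_species(
    state: SerialState,
    species: PopulationSpec,
    dose_ratio: float = 10.0,
    n_transfers: int | None = None,
    **kwargs,
) -> SerialResult:
    """Continue a serial run after spiking in a species.

    The spike is applied at the start of the next cycle (after the routine
    dilution into fresh medium) at ``dose_ratio`` times the focal species'
    total density; a zero dose continues the run unchanged.
    """
    if dose_ratio < 0:
        raise ValueError("dose_ratio must be non-negative")
    regime = state.regime if n_transfers is None else replace(
        state.regime, n_transfers=n_transfers)
    event = SpikeEvent(at_transfer=state.transfers_done + 1, spec=species,
                       dose_ratio=dose_ratio)
    return simulate_serial(state.populations, state.medium, regime,
                           state.recycling_fraction, events=[event],
                           _resume=state, **kwargs)


def simulate_stationary(
    populations: Sequence[PopulationSpec],
    medium: Medium,
    duration_days: float,
    recycling_fraction: float = 0.0,
    sample_every_days: float = 2.0,
    detection_limit: float = DETECTION_LIMIT,
    n_points: int = 1001,
) -> tuple[CompetitionSeries, BatchTrajectory]:
    """One un-renewed batch followed for ``duration_days``, sampled periodically.

    With biomass turnover (d > 0) and partial recycling the resource settles
    at a low quasi-steady concentration, the regime in which the low-K_s
    gleaner out-grows the exploiter.
    """
    traj = simulate_batch(populations, medium, duration_days * 24.0,
                          recycling_fraction, n_points=n_points)
    sample_days = np.arange(sample_every_days, duration_days + 1e-9,
                            sample_every_days)
    states = np.vstack([
        traj.densities[np.argmin(np.abs(traj.times - d * 24.0))]
        for d in sample_days
    ])
    series = _series_from_states(sample_days, states, populations, "strain",
                                 detection_limit, "day")
    return series, traj


def transfers_to_exclusion(
    series: CompetitionSeries,
    focal: str,
    threshold: float = DETECTION_LIMIT,
) -> int | float | None:
    """First index at which ``focal`` drops below ``threshold`` for good.

    Returns the index value (transfer number or day) of the first sample at
    which the focal population's fraction is below the threshold and never
    rises back above it; None if that never happens.
    """
    if focal not in series.fractions.columns:
        raise KeyError(f"unknown focal population {focal!r}")
    below = (series.fractions[focal] < threshold).to_numpy()
    if not below.any():
        return None
    # last position where the focal is at/above threshold
    above = np.nonzero(~below)[0]
    first_gone = 0 if above.size == 0 else above[-1] + 1
    if first_gone >= below.size:
        return None
    return series.index[first_gone].item()


def nutrient_timecourse(
    setups: Mapping[str, Sequence[PopulationSpec]],
    medium: Medium,
    sample_times: Sequence[float] = (6.0, 12.0, 24.0, 48.0),
    recycling_fraction: float = 0.0,
) -> pd.DataFrame:
    """Residual resource concentrations at fixed sampling times per culture setup.

    Emulates timed nutrient assays of monocultures and co-cultures: each named
    setup is grown as one batch and the resource pools are read off at the
    sampling times.  Returns a tidy frame (setup, time_h, resource,
    concentration).
    """
    sample_times = sorted(float(t) for t in sample_times)
    if not sample_times or sample_times[0] <= 0:
        raise ValueError("sample times must be positive")
    horizon = sample_times[-1]
    rows = []
    for name, pops in setups.items():
        traj = simulate_batch(list(pops), medium, horizon, recycling_fraction,
                              n_points=int(horizon * 20) + 1)
        for t in sample_times:
            i = int(np.argmin(np.abs(traj.times - t)))
            for j, r in enumerate(traj.resource_ids):
                rows.append({"setup": name, "time_h": t, "resource": r,
                             "concentration": float(traj.resources[i, j])})
    return pd.DataFrame(rows)
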