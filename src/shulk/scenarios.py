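"""Named competition scenarios for the gut strain-pair study conditions.

The focal pair is a calibrated gleaner/exploiter (sHULK) pair of *E. coli*
strains: EDM106 (gleaner — lower maximal rate, much lower half-saturation
constant on peptone) versus EDM530 (exploiter — higher maximal rate, higher
K_s).  Their anaerobic maximal rates come from the measured doubling times
(56.50 and 49.03 min); the K_s values on peptone are illustrative — chosen so
the rate-crossover concentration s* (~5 g/L) sits between the 10%-strength
and full-strength peptone pools — since only the ordering (EDM530 higher
mu_max, EDM106 lower K_s) is experimentally constrained.

Background species: a fast proteolytic peptone depleter standing in for
*C. perfringens* (very high maximal rate with rapid biomass turnover whose
recycled material feeds the peptone pool) and slow, weakly competing
stand-ins for *B. thetaiotaomicron* and *B. longum*.

Shipped scenarios:

- ``control_pair``        focal pair alone, daily transfers, rich medium
- ``background_flip``     pair plus the full background community from day 0
- ``background_no_flip``  pair plus only the slow background species
- ``spike_reversal``      control run spiked at day 12 with the fast species
- ``spike_inert``         same but spiking the slow species
- ``dilution_series``     pair alone across medium strengths
- ``peptone_vs_glucose``  strength series on peptone vs on glucose (strains
                          near-identical on glucose)
- ``stationary_phase``    un-renewed batch followed for 16 days
- ``isocline_worked``     carrying-capacity isocline analysis of the
                          coexisting pair EDM106/EDM116
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .batch import (
    CompetitionSeries,
    Medium,
    PopulationSpec,
    SerialResult,
    SpikeEvent,
    TransferRegime,
    simulate_serial,
    simulate_stationary,
    spike_species,
    transfers_to_exclusion,
)
from .kinetics import MonodParams
from .lv import (
    LVSystem,
    classify_equilibrium,
    competition_coefficients,
    equilibrium_point,
    expected_mixture_capacity,
    simulate_lv,
)

__all__ = [
    "GLEANER",
    "EXPLOITER",
    "COEXISTER",
    "PEPTONE_RICH_G_PER_L",
    "default_strain_pair",
    "default_background",
    "rich_medium",
    "default_regime",
    "DEFAULT_RECYCLING",
    "ScenarioOutcome",
    "SCENARIOS",
    "run_named_scenario",
    "isocline_report",
    "CAPACITY_EDM106",
    "CAPACITY_EDM116",
    "CAPACITY_COCULTURE",
    "COCULTURE_P1",
]

# Focal strain ids (gleaner / exploiter / the strain that coexists with the
# gleaner in one- and two-day regimes).
GLEANER = "EDM106"
EXPLOITER = "EDM530"
COEXISTER = "EDM116"

#: peptone pool of the full-strength rich broth (g/L)
PEPTONE_RICH_G_PER_L = 15.0
#: glucose pool of the full-strength rich broth (g/L)
GLUCOSE_RICH_G_PER_L = 5.0

DEFAULT_RECYCLING = 0.5
DEFAULT_DEATH_RATE = 0.01  # 1/h, slow stationary-phase biomass turnover
DEFAULT_YIELD = 0.3  # g biomass per g peptone
STRAIN_INIT = 0.005  # g/L inoculum per strain

# Measured anaerobic doubling times (min) used to set mu_max = ln2/Td.
DOUBLING_MIN = {GLEANER: 56.50, COEXISTER: 50.97, EXPLOITER: 49.03}
# Illustrative half-saturation constants on peptone (g/L); orderings are the
# experimentally constrained part (gleaner lowest).
K_S_PEPTONE = {GLEANER: 0.3, COEXISTER: 0.55, EXPLOITER: 1.0}

# Carrying-capacity measurements for the coexisting pair (dry weight g/30ml)
# and the co-culture's strain-1 (EDM106) proportion.
CAPACITY_EDM106 = 19.9
CAPACITY_EDM116 = 21.6
CAPACITY_COCULTURE = 21.8
COCULTURE_P1 = 0.55


def _strain(strain_id: str, resource: str = "peptone") -> PopulationSpec:
    return PopulationSpec(
        id=strain_id,
        monod={resource: MonodParams.from_doubling_time(
            DOUBLING_MIN[strain_id], K_S_PEPTONE[strain_id])},
        yields={resource: DEFAULT_YIELD},
        level="strain",
        species="E. coli",
        death_rate=DEFAULT_DEATH_RATE,
        init_density=STRAIN_INIT,
    )


def default_strain_pair() -> list[PopulationSpec]:
    """The calibrated gleaner/exploiter pair on peptone."""
    return [_strain(GLEANER), _strain(EXPLOITER)]


def fast_background_species(init_density: float = 1e-6) -> PopulationSpec:
    """Aggressive proteolytic peptone consumer (*C. perfringens* stand-in).

    Fast, wasteful (low-yield) growth plus rapid biomass turnover whose
    recycled material re-enters the peptone pool — the live-fast strategy by
    which this species rapidly strips the medium early in a cycle yet keeps a
    low peptone supply trickling afterwards, lengthening the low-resource
    phase in which the gleaner out-grows the exploiter.
    """
    return PopulationSpec(
        id="C. perfringens",
        monod={"peptone": MonodParams(mu_max=2.0, K_s=2.0)},
        yields={"peptone": 0.3},
        level="species",
        death_rate=0.1,
        init_density=init_density,
    )


def slow_background_species(init_density: float = 1e-3) -> list[PopulationSpec]:
    """Weak competitors on peptone (*B. thetaiotaomicron*, *B. longum* stand-ins)."""
    return [
        PopulationSpec(
            id="B. thetaiotaomicron",
            monod={"peptone": MonodParams(mu_max=0.30, K_s=5.0)},
            yields={"peptone": 0.6},
            level="species",
            death_rate=DEFAULT_DEATH_RATE,
            init_density=init_density,
        ),
        PopulationSpec(
            id="B. longum",
            monod={"peptone": MonodParams(mu_max=0.25, K_s=4.0)},
            yields={"peptone": 0.5},
            level="species",
            death_rate=DEFAULT_DEATH_RATE,
            init_density=init_density,
        ),
    ]


def default_background() -> list[PopulationSpec]:
    return [fast_background_species()] + slow_background_species()


def glucose_strain_pair() -> list[PopulationSpec]:
    """The same pair on glucose, where their kinetics are nearly identical.

    The exploiter keeps a slight edge at every concentration, so glucose-only
    media produce the same winner at all strengths — no competitive reversal.
    """
    gleaner = PopulationSpec(
        id=GLEANER,
        monod={"glucose": MonodParams(mu_max=0.84, K_s=0.5)},
        yields={"glucose": 0.4},
        level="strain", species="E. coli",
        death_rate=DEFAULT_DEATH_RATE, init_density=STRAIN_INIT,
    )
    exploiter = PopulationSpec(
        id=EXPLOITER,
        monod={"glucose": MonodParams(mu_max=0.85, K_s=0.5)},
        yields={"glucose": 0.4},
        level="strain", species="E. coli",
        death_rate=DEFAULT_DEATH_RATE, init_density=STRAIN_INIT,
    )
    return [gleaner, exploiter]


def rich_medium(strength_fraction: float = 1.0,
                resource: str = "peptone") -> Medium:
    base = {"peptone": PEPTONE_RICH_G_PER_L, "glucose": GLUCOSE_RICH_G_PER_L}
    return Medium(resources={resource: base[resource]},
                  strength_fraction=strength_fraction)


def default_regime(period_h: float = 24.0, n_transfers: int = 20,
                   dilution_factor: float = 0.01) -> TransferRegime:
    return TransferRegime(period_h=period_h, dilution_factor=dilution_factor,
                          n_transfers=n_transfers)


@dataclass
class ScenarioOutcome:
    """Uniform result wrapper: series per level plus scenario-specific extras."""

    name: str
    strain_series: CompetitionSeries | None = None
    species_series: CompetitionSeries | None = None
    extras: dict = field(default_factory=dict)

    def winner(self) -> str | None:
        """Strain with the larger final fraction, if strain series present."""
        if self.strain_series is None:
            return None
        last = self.strain_series.fractions.iloc[-1]
        return str(last.idxmax())


def _serial_outcome(name: str, result: SerialResult) -> ScenarioOutcome:
    return ScenarioOutcome(
        name=name,
        strain_series=result.strain_series(),
        species_series=result.species_series(),
        extras={"result": result},
    )


def run_control_pair(period_h: float = 24.0, n_transfers: int = 20,
                     strength: float = 1.0) -> ScenarioOutcome:
    """Focal pair alone in (by default full-strength) rich medium."""
    result = simulate_serial(
        default_strain_pair(), rich_medium(strength),
        default_regime(period_h=period_h, n_transfers=n_transfers),
        recycling_fraction=DEFAULT_RECYCLING,
    )
    return _serial_outcome("control_pair", result)


def run_background_flip(n_transfers: int = 30) -> ScenarioOutcome:
    """Pair plus the full background community; the fast depleter's rise to
    dominance flips the strain competition toward the gleaner."""
    pops = default_strain_pair() + default_background()
    result = simulate_serial(pops, rich_medium(), default_regime(
        n_transfers=n_transfers), recycling_fraction=DEFAULT_RECYCLING)
    return _serial_outcome("background_flip", result)


def run_background_no_flip(n_transfers: int = 30) -> ScenarioOutcome:
    """Pair plus only the slow background species; no reversal."""
    pops = default_strain_pair() + slow_background_species()
    result = simulate_serial(pops, rich_medium(), default_regime(
        n_transfers=n_transfers), recycling_fraction=DEFAULT_RECYCLING)
    return _serial_outcome("background_no_flip", result)


def run_spike(species: str = "fast", spike_day: int = 12,
              n_continue: int = 18, dose_ratio: float = 10.0
              ) -> ScenarioOutcome:
    """Run the control pair to ``spike_day``, then spike a background species.

    ``species='fast'`` spikes the aggressive depleter (reverses the strain
    trajectories); ``'slow'`` spikes the weak competitor (no reversal).
    """
    base = simulate_serial(
        default_strain_pair(), rich_medium(),
        default_regime(n_transfers=spike_day),
        recycling_fraction=DEFAULT_RECYCLING,
    )
    spec = fast_background_species() if species == "fast" \
        else slow_background_species()[0]
    cont = spike_species(base.state, spec, dose_ratio=dose_ratio,
                         n_transfers=n_continue)
    name = "spike_reversal" if species == "fast" else "spike_inert"
    out = _serial_outcome(name, cont)
    out.extras["pre_spike"] = base
    out.extras["spiked_species"] = spec.id
    return out


def run_dilution_series(strengths: tuple[float, ...] = (0.9, 0.5, 0.1),
                        n_transfers: int = 25) -> dict[float, ScenarioOutcome]:
    """Pair alone across medium strengths; strong medium favours the
    exploiter, dilute medium the gleaner."""
    out = {}
    for f in strengths:
        result = simulate_serial(
            default_strain_pair(), rich_medium(f),
            default_regime(n_transfers=n_transfers),
            recycling_fraction=DEFAULT_RECYCLING,
        )
        out[f] = _serial_outcome(f"dilution_series[{f}]", result)
    return out


def run_peptone_vs_glucose(strengths: tuple[float, ...] = (0.9, 0.1),
                           n_transfers: int = 25
                           ) -> dict[str, dict[float, ScenarioOutcome]]:
    """Strength series with peptone-divergent vs glucose-identical kinetics.

    The winner flips with strength on peptone but not on glucose, localising
    the context dependence to the resource on which the pair trades off.
    """
    out: dict[str, dict[float, ScenarioOutcome]] = {"peptone": {}, "glucose": {}}
    for f in strengths:
        res_p = simulate_serial(
            default_strain_pair(), rich_medium(f, "peptone"),
            default_regime(n_transfers=n_transfers),
            recycling_fraction=DEFAULT_RECYCLING,
        )
        out["peptone"][f] = _serial_outcome(f"peptone[{f}]", res_p)
        res_g = simulate_serial(
            glucose_strain_pair(), rich_medium(f, "glucose"),
            default_regime(n_transfers=n_transfers),
            recycling_fraction=DEFAULT_RECYCLING,
        )
        out["glucose"][f] = _serial_outcome(f"glucose[{f}]", res_g)
    return out


def run_stationary_phase(duration_days: float = 16.0) -> ScenarioOutcome:
    """Un-renewed batch: after resource exhaustion, turnover + recycling keep
    the culture at low resource levels where the gleaner slowly overtakes."""
    series, traj = simulate_stationary(
        default_strain_pair(), rich_medium(), duration_days,
        recycling_fraction=DEFAULT_RECYCLING,
    )
    return ScenarioOutcome("stationary_phase", strain_series=series,
                           extras={"trajectory": traj})


def run_transfer_period_sweep(
    periods_days: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0),
    max_transfers: int = 120,
) -> pd.DataFrame:
    """Transfers until the gleaner is excluded, per transfer period.

    Longer cycles spend more time in starvation where the gleaner gains, so
    exclusion takes more transfers — the positive period/exclusion-time
    relationship characteristic of the sHULK pair.
    """
    rows = []
    for days in periods_days:
        result = simulate_serial(
            default_strain_pair(), rich_medium(),
            default_regime(period_h=days * 24.0, n_transfers=max_transfers),
            recycling_fraction=DEFAULT_RECYCLING,
        )
        n = transfers_to_exclusion(result.strain_series(), GLEANER)
        rows.append({"period_days": days, "transfers_to_exclusion": n})
    return pd.DataFrame(rows)


def isocline_report(K1: float = CAPACITY_EDM106, K2: float = CAPACITY_EDM116,
                    K_co: float = CAPACITY_COCULTURE, p1: float = COCULTURE_P1,
                    r1: float = 1.0, r2: float = 1.0) -> dict:
    """Full carrying-capacity isocline analysis of a coexisting pair.

    Derives the competition coefficients from the monoculture and co-culture
    capacities, classifies the equilibrium, and verifies convergence of the
    Lotka-Volterra dynamics from four interior starting points.
    """
    a12, a21, warnings = competition_coefficients(K1, K2, K_co, p1)
    sys = LVSystem(K1=K1, K2=K2, alpha12=a12, alpha21=a21, r1=r1, r2=r2)
    eq = equilibrium_point(sys)
    cls = classify_equilibrium(sys)
    corners = [(0.1 * K1, 0.1 * K2), (0.9 * K1, 0.1 * K2),
               (0.1 * K1, 0.9 * K2), (0.9 * K1, 0.9 * K2)]
    final_states = []
    for c in corners:
        _, traj = simulate_lv(sys, c, duration=2000.0)
        final_states.append(tuple(traj[-1]))
    return {
        "alpha12": a12,
        "alpha21": a21,
        "warnings": warnings,
        "equilibrium": eq,
        "classification": cls,
        "expected_mixture_capacity": expected_mixture_capacity(K1, K2, p1),
        "observed_coculture_capacity": K_co,
        "convergence_starts": corners,
        "convergence_finals": final_states,
        "system": sys,
    }


SCENARIOS: Mapping[str, Callable[[], object]] = {
    "control_pair": run_control_pair,
    "background_flip": run_background_flip,
    "background_no_flip": run_background_no_flip,
    "spike_reversal": lambda: run_spike("fast"),
    "spike_inert": lambda: run_spike("slow"),
    "dilution_series": run_dilution_series,
    "peptone_vs_glucose": run_peptone_vs_glucose,
    "stationary_phase": run_stationary_phase,
    "transfer_period_sweep": run_transfer_period_sweep,
    "isocline_worked": isocline_report,
}


def run_named_scenario(name: str):
    """Run one of the shipped scenarios by name."""
    try:
        fn = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIOS)}"
        ) from None
    return fn()
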