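"""Consumer-resource batch/serial simulator: conservation, oracle, transfers."""

import math

import numpy as np
import pandas as pd
import pytest

from shulk.batch import (
    CompetitionSeries,
    Medium,
    PopulationSpec,
    TransferRegime,
    nutrient_timecourse,
    simulate_batch,
    simulate_batch_euler,
    simulate_serial,
    simulate_stationary,
    spike_species,
    transfers_to_exclusion,
)
from shulk.kinetics import MonodParams


def pop(pid, mu, K, Y=0.5, d=0.0, init=0.01, level="strain",
        species="E. coli", resource="s"):
    return PopulationSpec(
        id=pid, monod={resource: MonodParams(mu, K)}, yields={resource: Y},
        level=level, species=species, death_rate=d, init_density=init)


def shulk_pops(d=0.0, init=0.01):
    """Exploiter (high mu_max) and gleaner (low K_s) on one resource."""
    return [pop("exploiter", 1.0, 1.0, d=d, init=init),
            pop("gleaner", 0.7, 0.2, d=d, init=init)]


MEDIUM = Medium(resources={"s": 5.0})


class TestSimulateBatch:
    def test_mass_balance_forces_final_density(self):
        """With d=0 and no recycling, all consumed resource becomes biomass/Y."""
        p = pop("solo", 1.0, 0.5, Y=0.5, init=0.01)
        medium = Medium(resources={"s": 1.0})  # growth potential s0*Y = 0.5
        traj = simulate_batch([p], medium, duration=48.0)
        assert traj.final_densities()[0] == pytest.approx(0.51, abs=1e-4)

    def test_conserved_quantity_along_trajectory(self):
        pops = shulk_pops()
        traj = simulate_batch(pops, MEDIUM, duration=24.0)
        invariant = traj.resources[:, 0] + traj.densities[:, 0] / 0.5 \
            + traj.densities[:, 1] / 0.5
        assert np.max(np.abs(invariant - invariant[0])) / invariant[0] < 1e-6

    def test_no_populations_leave_resources_constant(self):
        traj = simulate_batch([], MEDIUM, duration=10.0)
        assert np.all(traj.resources == 5.0)

    def test_exploiter_gains_share_in_rich_batch(self):
        traj = simulate_batch(shulk_pops(), MEDIUM, duration=24.0)
        final = traj.final_densities()
        share = final[0] / final.sum()
        assert share > 0.5  # started at 0.5

    def test_adaptive_matches_euler_oracle(self):
        """Fixed-step Euler (dt=1e-3 h) and the adaptive solver agree."""
        adaptive = simulate_batch(shulk_pops(), MEDIUM, duration=24.0)
        euler = simulate_batch_euler(shulk_pops(), MEDIUM, duration=24.0,
                                     dt=1e-3)
        ref = euler.final_densities()
        assert np.allclose(adaptive.final_densities(), ref, rtol=5e-3)

    def test_non_negative_state(self):
        traj = simulate_batch(shulk_pops(d=0.05), MEDIUM, duration=100.0,
                              recycling_fraction=0.3)
        assert np.all(traj.densities >= 0)
        assert np.all(traj.resources >= 0)

    def test_unknown_resource_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            simulate_batch([pop("x", 1.0, 1.0, resource="ghost")], MEDIUM, 1.0)


class TestSimulateSerial:
    REGIME = TransferRegime(period_h=24.0, dilution_factor=0.01, n_transfers=12)

    def test_single_strain_has_unit_relative_abundance(self):
        res = simulate_serial([pop("solo", 1.0, 0.5)], MEDIUM, self.REGIME)
        frac = res.strain_series().fractions
        assert np.allclose(frac["solo"], 1.0)

    def test_periodic_steady_state_within_ten_transfers(self):
        res = simulate_serial([pop("solo", 1.0, 0.5)], MEDIUM, self.REGIME)
        dens = res.densities[:, 0]
        assert abs(dens[-1] - dens[-2]) / dens[-1] < 1e-3
        assert abs(dens[9] - dens[10]) / dens[10] < 1e-3

    def test_exploiter_fixes_in_short_rich_cycles(self):
        res = simulate_serial(shulk_pops(), MEDIUM,
                              TransferRegime(12.0, 0.01, 15))
        frac = res.strain_series().fractions["exploiter"].to_numpy()
        assert np.all(np.diff(frac) > -1e-12)  # monotone rise
        assert frac[-1] > 0.99

    def test_starvation_heavy_cycles_favour_gleaner(self):
        """When the whole cycle runs below the rate-crossover concentration
        (dilute medium, long post-depletion phase sustained by turnover and
        recycling), the per-transfer balance tips to the low-K_s strain."""
        pops = shulk_pops(d=0.01)
        dilute = Medium(resources={"s": 1.0})  # below s* = 5/3 for this pair
        res = simulate_serial(pops, dilute, TransferRegime(96.0, 0.01, 6),
                              recycling_fraction=0.5)
        frac = res.strain_series().fractions["gleaner"].to_numpy()
        assert frac[-1] > frac[0]
        assert np.all(np.diff(frac) > 0)

    def test_serial_cycle_matches_euler_oracle(self):
        pops = shulk_pops(d=0.01)
        res = simulate_serial(pops, MEDIUM, TransferRegime(24.0, 0.01, 2),
                              recycling_fraction=0.5, keep_trajectories=True)
        # re-integrate the second cycle with Euler from the diluted state
        start = res.trajectories[0].final_densities() * 0.01
        euler = simulate_batch_euler(pops, MEDIUM, 24.0,
                                     recycling_fraction=0.5, dt=1e-3,
                                     init_densities=start)
        assert np.allclose(res.densities[1], euler.final_densities(),
                           rtol=5e-3)


class TestTransfersToExclusion:
    @staticmethod
    def series(fractions):
        arr = np.asarray(fractions, dtype=float)
        frac = pd.DataFrame({"a": arr, "b": 1.0 - arr})
        return CompetitionSeries(np.arange(1, arr.size + 1), frac,
                                 frac < 0.05, "strain")

    def test_first_permanent_drop_is_reported(self):
        s = self.series([0.5, 0.4, 0.3, 0.2, 0.1, 0.06, 0.04, 0.03, 0.02])
        assert transfers_to_exclusion(s, "a") == 7

    def test_transient_drop_does_not_count(self):
        s = self.series([0.5, 0.04, 0.3, 0.2, 0.04, 0.03])
        assert transfers_to_exclusion(s, "a") == 5

    def test_persistent_strain_never_excluded(self):
        s = self.series([0.5] * 8)
        assert transfers_to_exclusion(s, "a") is None

    def test_unknown_focal_rejected(self):
        with pytest.raises(KeyError):
            transfers_to_exclusion(self.series([0.5]* 5), "nobody")


class TestStationaryAndSpike:
    def test_composition_frozen_without_turnover(self):
        series, traj = simulate_stationary(shulk_pops(), MEDIUM,
                                           duration_days=8.0)
        frac = series.fractions.to_numpy()
        assert np.allclose(frac[1:], frac[1], atol=1e-6)

    def test_post_exhaustion_decay_matches_closed_form(self):
        """Alone with death and no recycling, N(t) = N_peak * exp(-d t)."""
        d = 0.02
        p = pop("exploiter", 1.0, 1.0, d=d, init=0.01)
        _, traj = simulate_stationary([p], MEDIUM, duration_days=10.0)
        dens = traj.densities[:, 0]
        i_peak = int(np.argmax(dens))
        t_peak = traj.times[i_peak]
        expected = dens[i_peak] * np.exp(-d * (traj.times[i_peak:] - t_peak))
        assert np.allclose(dens[i_peak:], expected, rtol=5e-3)

    def test_gleaner_overtakes_in_long_stationary_phase(self):
        pops = shulk_pops(d=0.01)
        series, _ = simulate_stationary(pops, MEDIUM, duration_days=16.0,
                                        recycling_fraction=0.5)
        final = series.fractions.iloc[-1]
        assert final["gleaner"] > final["exploiter"]

    def test_zero_dose_spike_changes_nothing(self):
        pops = shulk_pops(d=0.01)
        regime = TransferRegime(24.0, 0.01, 4)
        base = simulate_serial(pops, MEDIUM, regime, recycling_fraction=0.3)
        intruder = pop("intruder", 1.5, 2.0, level="species",
                       species="intruder")
        cont = spike_species(base.state, intruder, dose_ratio=0.0,
                             n_transfers=3)
        ref = simulate_serial(pops, MEDIUM, TransferRegime(24.0, 0.01, 7),
                              recycling_fraction=0.3)
        assert np.allclose(cont.densities[-1][:2], ref.densities[-1],
                           rtol=1e-6)

    def test_negative_dose_rejected(self):
        pops = shulk_pops()
        base = simulate_serial(pops, MEDIUM, TransferRegime(24.0, 0.01, 2))
        with pytest.raises(ValueError):
            spike_species(base.state, pop("x", 1.0, 1.0), dose_ratio=-1.0)


class TestNutrientTimecourse:
    def test_no_populations_stay_at_initial_concentration(self):
        df = nutrient_timecourse({"blank": []}, MEDIUM)
        assert np.allclose(df["concentration"], 5.0)

    def test_exploiter_depletes_faster_early_gleaner_deeper_late(self):
        """The exploiter strips a rich pool faster while concentrations are
        high; the gleaner scavenges to a lower residual by the end."""
        setups = {
            "gleaner": [pop("g", 0.7, 0.2, d=0.01, init=1e-6)],
            "exploiter": [pop("e", 1.0, 1.0, d=0.01, init=1e-6)],
        }
        medium = Medium(resources={"s": 15.0})
        df = nutrient_timecourse(setups, medium, sample_times=(6, 12, 48),
                                 recycling_fraction=0.5)
        wide = df.pivot(index="time_h", columns="setup",
                        values="concentration")
        assert wide.loc[6.0, "exploiter"] < wide.loc[6.0, "gleaner"]
        assert wide.loc[12.0, "exploiter"] < wide.loc[12.0, "gleaner"]
        assert wide.loc[48.0, "gleaner"] < wide.loc[48.0, "exploiter"]

    def test_invalid_sample_times_rejected(self):
        with pytest.raises(ValueError):
            nutrient_timecourse({"x": []}, MEDIUM, sample_times=())


class TestSpecValidation:
    def test_yields_must_cover_resources(self):
        with pytest.raises(ValueError):
            PopulationSpec(id="x", monod={"s": MonodParams(1, 1)},
                           yields={"other": 0.5})

    def test_medium_strength_bounds(self):
        with pytest.raises(ValueError):
            Medium(resources={"s": 1.0}, strength_fraction=2.5)
        Medium(resources={"s": 1.0}, strength_fraction=2.0)  # 200% broth ok

    def test_regime_bounds(self):
        with pytest.raises(ValueError):
            TransferRegime(period_h=24.0, dilution_factor=1.0)
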