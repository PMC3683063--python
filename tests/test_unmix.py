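"""Electropherogram mixture decomposition and mixed base-call checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shulk.synth import gen_traces
from shulk.unmix import (
    TraceMatrix,
    UnidentifiableError,
    flag_detection,
    mixed_base_call_check,
    unmix,
)


def make_tm(U, mixed, labels=None):
    U = np.asarray(U, dtype=float)
    return TraceMatrix(
        positions=np.arange(U.shape[0]),
        unit_spectra=U,
        mixed=np.asarray(mixed, dtype=float),
        labels=tuple(labels or (f"s{i}" for i in range(U.shape[1]))),
    )


class TestUnmix:
    def test_pure_strain_identified_exactly(self):
        tm, truth = gen_traces(mixture=(1.0, 0.0), noise_sd=0.0, seed=2)
        res = unmix(tm)
        assert res.proportions[0] == pytest.approx(1.0, abs=1e-10)
        assert res.proportions[1] == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("mixture", [(0.84, 0.16), (0.5, 0.5),
                                         (0.6, 0.3, 0.1)])
    def test_noiseless_mixture_recovered_to_float_precision(self, mixture):
        tm, _ = gen_traces(mixture=mixture, noise_sd=0.0, seed=5)
        res = unmix(tm)
        assert np.max(np.abs(res.proportions - np.array(mixture))) < 1e-10
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_minority_strain_recovered_under_noise(self):
        """The worked two-strain fecal-sample case: an 84/16 mixture with 1%
        noise is decomposed to within 0.02 with a strong regression fit."""
        tm, truth = gen_traces(mixture=(0.84, 0.16), noise_sd=0.01, seed=11)
        res = unmix(tm)
        assert res.proportions[0] == pytest.approx(0.84, abs=0.02)
        assert res.proportions[1] == pytest.approx(0.16, abs=0.02)
        assert res.r_squared >= 0.97
        assert res.p_value < 1e-4
        assert not res.below_detection.any()

    def test_proportions_normalised_and_non_negative(self):
        tm, _ = gen_traces(mixture=(0.7, 0.2, 0.1), noise_sd=0.05, seed=8)
        res = unmix(tm)
        assert np.all(res.proportions >= 0)
        assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_collinear_unit_spectra_unidentifiable(self):
        base = np.exp(-0.5 * ((np.arange(50) - 20) / 3.0) ** 2)
        U = np.column_stack([base, base * (1 + 1e-9)])
        tm = make_tm(U, base)
        with pytest.raises(UnidentifiableError):
            unmix(tm)

    def test_identical_columns_rejected_at_construction(self):
        base = np.exp(-0.5 * ((np.arange(50) - 20) / 3.0) ** 2)
        with pytest.raises(ValueError, match="identical"):
            make_tm(np.column_stack([base, base]), base)

    def test_all_zero_mixed_trace_rejected(self):
        tm, _ = gen_traces(mixture=(0.5, 0.5), noise_sd=0.0, seed=3)
        zero = TraceMatrix(tm.positions, tm.unit_spectra,
                           np.zeros_like(tm.mixed), tm.labels)
        with pytest.raises(ValueError, match="zero"):
            unmix(zero)

    def test_permutation_equivariance(self):
        tm, _ = gen_traces(mixture=(0.6, 0.3, 0.1), noise_sd=0.01, seed=4)
        res = unmix(tm)
        perm = [2, 0, 1]
        tm_p = TraceMatrix(tm.positions, tm.unit_spectra[:, perm],
                           tm.mixed, tuple(tm.labels[i] for i in perm))
        res_p = unmix(tm_p)
        assert np.allclose(res_p.proportions, res.proportions[perm], atol=1e-9)

    def test_error_grows_with_noise(self):
        """Median recovery error increases monotonically with trace noise."""
        med = []
        for sd in (0.005, 0.01, 0.02, 0.05):
            errs = []
            for seed in range(50):
                tm, _ = gen_traces(mixture=(0.84, 0.16), noise_sd=sd,
                                   seed=1000 + seed)
                res = unmix(tm)
                errs.append(abs(res.proportions[0] - 0.84))
            med.append(np.median(errs))
        assert all(a <= b + 1e-12 for a, b in zip(med, med[1:]))

    def test_detection_floor_documented_at_five_percent(self):
        """Median absolute error when the true minor fraction sits exactly at
        the 5% reporting floor (reported as a property, not a fixed value)."""
        errs = []
        for seed in range(30):
            tm, _ = gen_traces(mixture=(0.95, 0.05), noise_sd=0.01,
                               seed=2000 + seed)
            res = unmix(tm)
            errs.append(abs(res.proportions[1] - 0.05))
        assert np.median(errs) < 0.05  # resolvable, but flagged near the limit


class TestFlagDetection:
    def test_minor_component_flagged(self):
        p, flags = flag_detection([0.97, 0.03])
        assert list(flags) == [False, True]
        assert p[1] == pytest.approx(0.03)  # value preserved, never zeroed

    def test_balanced_mixture_unflagged(self):
        _, flags = flag_detection([0.5, 0.5])
        assert not flags.any()

    def test_worked_mixture_unflagged(self):
        _, flags = flag_detection([0.84, 0.16])
        assert not flags.any()

    def test_non_normalised_input_rejected(self):
        with pytest.raises(ValueError):
            flag_detection([0.5, 0.1])


class TestMixedBaseCallCheck:
    def test_identical_sequences_show_no_mixed_positions(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=600))
        cmp = mixed_base_call_check(seq, seq)
        assert cmp.expected_positions == ()

    def test_constructed_seven_site_pair(self, rng):
        """Two strain sequences engineered to differ at exactly 7 sites, the
        number of mixed peaks expected from their co-occurrence."""
        seq = list("".join(rng.choice(list("ACGT"), size=600)))
        swap = {"A": "G", "G": "A", "C": "T", "T": "C"}
        sites = sorted(rng.choice(600, size=7, replace=False).tolist())
        other = list(seq)
        for i in sites:
            other[i] = swap[other[i]]
        cmp = mixed_base_call_check("".join(seq), "".join(other), sites)
        assert cmp.expected_positions == tuple(sites)
        assert cmp.n_discordant == 0

    def test_matches_position_scan_oracle(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=200))
        b = "".join(rng.choice(list("ACGT"), size=200))
        oracle = tuple(i for i in range(200) if a[i] != b[i])
        assert mixed_base_call_check(a, b).expected_positions == oracle

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mixed_base_call_check("ACGT", "ACG")

    def test_discordance_counts_symmetric_difference(self):
        cmp = mixed_base_call_check("AAAA", "AATA", mixed_positions=[1, 2])
        assert cmp.expected_positions == (2,)
        assert set(cmp.discordant) == {1}


@given(st.integers(0, 2**31 - 1))
def test_proportions_always_simplex(seed):
    tm, _ = gen_traces(mixture=(0.7, 0.3), noise_sd=0.02, seed=seed)
    res = unmix(tm)
    assert np.all(res.proportions >= 0)
    assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)
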