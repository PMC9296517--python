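"""Sequential-scheme forward model: validation, Bateman closed form, signal."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from conftest import ode_occupancies
from rhodocycle import (
    DifferenceSpectrum,
    IntermediateState,
    SequentialScheme,
    concentrations,
    expand_biphasic,
    forward_signal,
)


def chain(*lifetimes):
    return SequentialScheme(
        intermediates=tuple(
            IntermediateState(f"S{i}", (tau,)) for i, tau in enumerate(lifetimes)
        )
    )


class TestSchemeValidation:
    def test_rejects_nonpositive_lifetime(self):
        with pytest.raises(ValueError, match="positive"):
            IntermediateState("X", (0.0,))

    def test_rejects_three_lifetimes(self):
        with pytest.raises(ValueError, match="1 or 2"):
            IntermediateState("X", (1.0, 2.0, 3.0), (0.3, 0.3, 0.4))

    def test_biphasic_needs_fractions_summing_to_one(self):
        with pytest.raises(ValueError, match="fractions"):
            IntermediateState("X", (1.0, 2.0))
        with pytest.raises(ValueError, match="sum"):
            IntermediateState("X", (1.0, 2.0), (0.5, 0.6))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SequentialScheme(
                intermediates=(
                    IntermediateState("A", (1.0,)),
                    IntermediateState("A", (2.0,)),
                )
            )

    def test_json_round_trip(self, tmp_path):
        scheme = SequentialScheme(
            intermediates=(
                IntermediateState("I", (1.7e-6, 13e-6), (0.42, 0.58)),
                IntermediateState("II", (118e-6,)),
            )
        )
        path = tmp_path / "scheme.json"
        scheme.to_json(path)
        assert SequentialScheme.from_json(path) == scheme


class TestExpandBiphasic:
    def test_monophasic_chain_is_identity(self):
        scheme = chain(1e-6, 1e-3, 1.0)
        expanded = expand_biphasic(scheme)
        assert all(len(stage) == 1 for stage in expanded.stages)
        assert expanded.mapping == {"S0": ("S0",), "S1": ("S1",), "S2": ("S2",)}

    def test_biphasic_state_splits_with_entry_fractions(self):
        # the slowest measured SacR intermediate: 98.4/384 ms at 56/44%
        scheme = SequentialScheme(
            intermediates=(
                IntermediateState("V", (98.4e-3, 384e-3), (0.56, 0.44)),
            )
        )
        (stage,) = expand_biphasic(scheme).stages
        assert [s.label for s in stage] == ["V_a", "V_b"]
        assert [s.entry_fraction for s in stage] == [0.56, 0.44]
        np.testing.assert_allclose(
            [1.0 / s.rate for s in stage], [98.4e-3, 384e-3]
        )

    def test_equal_lifetime_biphasic_matches_monophasic(self):
        tau = 3.7e-4
        biphasic = SequentialScheme(
            intermediates=(
                IntermediateState("A", (tau, tau), (0.5, 0.5)),
                IntermediateState("B", (5e-3,)),
            )
        )
        mono = SequentialScheme(
            intermediates=(
                IntermediateState("A", (tau,)),
                IntermediateState("B", (5e-3,)),
            )
        )
        t = np.geomspace(1e-6, 0.1, 60)
        occ_b, rec_b = concentrations(biphasic, t)
        occ_m, rec_m = concentrations(mono, t)
        np.testing.assert_allclose(occ_b, occ_m, atol=1e-9)
        np.testing.assert_allclose(rec_b, rec_m, atol=1e-9)


class TestConcentrations:
    def test_initial_condition(self):
        occ, rec = concentrations(chain(1e-3, 1e-2), [0.0])
        np.testing.assert_allclose(occ[:, 0], [1.0, 0.0])
        assert rec[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_state_chain_matches_ode(self):
        scheme = chain(10e-6, 1e-3)
        t = np.geomspace(1e-6, 10e-3, 50)
        occ, _ = concentrations(scheme, t)
        oracle = ode_occupancies(scheme, t)
        np.testing.assert_allclose(occ, oracle, rtol=1e-8, atol=1e-10)

    def test_conservation_and_monotone_recovery(self):
        scheme = SequentialScheme(
            intermediates=(
                IntermediateState("I", (1.7e-6, 13e-6), (0.42, 0.58)),
                IntermediateState("II", (118e-6,)),
                IntermediateState("V", (98.4e-3, 384e-3), (0.56, 0.44)),
            )
        )
        t = np.geomspace(1e-7, 30.0, 300)
        occ, rec = concentrations(scheme, t)
        np.testing.assert_allclose(occ.sum(axis=0) + rec, 1.0, atol=1e-9)
        assert np.all(occ >= -1e-12) and np.all(occ <= 1 + 1e-12)
        assert np.all(np.diff(rec) >= -1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            concentrations(chain(1e-3), [-1.0, 0.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        lifetimes=st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=7
        ),
        data=st.data(),
    )
    def test_random_chains_match_ode_oracle(self, lifetimes, data):
        """Closed-form Bateman occupancies agree with stiff ODE integration
        for random chains with optional biphasic states."""
        states = []
        for i, tau in enumerate(lifetimes):
            if data.draw(st.booleans()):
                ratio = data.draw(st.floats(min_value=1.5, max_value=50.0))
                frac = data.draw(st.floats(min_value=0.1, max_value=0.9))
                states.append(
                    IntermediateState(f"S{i}", (tau, tau * ratio), (frac, 1 - frac))
                )
            else:
                states.append(IntermediateState(f"S{i}", (tau,)))
        scheme = SequentialScheme(intermediates=tuple(states))
        # closed form and ODE are compared on generically separated rates;
        # exactly degenerate rates are regularised and lose ~1e-7 accuracy
        rates = sorted(1.0 / tau for s in states for tau in s.lifetimes)
        assume(
            all(b / a > 1.0 + 1e-4 for a, b in zip(rates, rates[1:]))
        )
        t = np.geomspace(1e-7, 10.0, 25)
        occ, rec = concentrations(scheme, t)
        oracle = ode_occupancies(scheme, t)
        np.testing.assert_allclose(occ, oracle, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(occ.sum(axis=0) + rec, 1.0, atol=1e-9)


class TestForwardSignal:
    def setup_method(self):
        self.scheme = chain(10e-6, 1e-3, 50e-3)
        self.wl = np.array([406.0, 561.0, 638.0])
        self.t = np.geomspace(1e-6, 1.0, 80)

    def spectra(self, matrix):
        return DifferenceSpectrum(
            wavelengths=self.wl,
            delta_epsilon=matrix,
            labels=tuple(s.label for s in self.scheme.intermediates),
        )

    def test_zero_spectra_give_zero_signal(self):
        data = forward_signal(
            self.scheme, self.spectra(np.zeros((3, 3))), self.wl, self.t
        )
        np.testing.assert_array_equal(data.delta_A, 0.0)

    def test_linearity_in_delta_epsilon(self):
        de = np.array([[1.0, -0.5, 0.2], [0.3, 0.7, -1.0], [0.0, 0.4, 0.9]])
        one = forward_signal(self.scheme, self.spectra(de), self.wl, self.t)
        two = forward_signal(self.scheme, self.spectra(2 * de), self.wl, self.t)
        np.testing.assert_allclose(two.delta_A, 2 * one.delta_A, rtol=1e-12)

    def test_single_state_probe_tracks_occupancy(self):
        # M-like state visible only at the blue probe
        de = np.zeros((3, 3))
        de[1, 0] = 1.0  # second state, 406 nm
        data = forward_signal(self.scheme, self.spectra(de), self.wl, self.t)
        oracle = ode_occupancies(self.scheme, self.t)
        np.testing.assert_allclose(data.delta_A[0], oracle[1], rtol=1e-8,
                                   atol=1e-10)
        np.testing.assert_array_equal(data.delta_A[1:], 0.0)

    def test_signal_recovers_to_zero(self):
        de = np.array([[1.0, -0.5, 0.2], [0.3, 0.7, -1.0], [0.0, 0.4, 0.9]])
        data = forward_signal(self.scheme, self.spectra(de), self.wl,
                              np.array([1e-6, 1.0, 100.0]))
        np.testing.assert_allclose(data.delta_A[:, -1], 0.0, atol=1e-10)

    def test_unknown_wavelength_rejected(self):
        with pytest.raises(ValueError, match="not on the spectrum grid"):
            forward_signal(
                self.scheme, self.spectra(np.zeros((3, 3))), [500.0], self.t
            )


def test_transient_dataset_csv_round_trip(tmp_path):
    from rhodocycle import TransientDataset

    rng = np.random.default_rng(0)
    data = TransientDataset(
        wavelengths=[406.0, 561.0],
        times=np.geomspace(1e-6, 1.0, 20),
        delta_A=rng.normal(size=(2, 20)),
    )
    path = tmp_path / "traces.csv"
    data.to_csv(path)
    back = TransientDataset.from_csv(path)
    np.testing.assert_allclose(back.delta_A, data.delta_A, rtol=1e-8)
    np.testing.assert_allclose(back.times, data.times, rtol=1e-8)
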