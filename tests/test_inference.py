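"""DAS -> EADS transformation, biphasic merging, spectroscopic labelling."""

import numpy as np
import pytest

from rhodocycle import (
    GeneratorConfig,
    PhotocycleResult,
    das_to_eads,
    fit_multiexponential,
    gen_photocycle,
    infer_photocycle,
    label_intermediates,
    merge_biphasic,
    sacr_scheme,
    sacr_spectra,
)
from rhodocycle.inference import bateman_coefficients, refine_scheme
from rhodocycle.kinetics import (
    IntermediateState,
    SequentialScheme,
    concentrations,
)


def make_fit(taus, das, times, wavelengths):
    """A MultiExpFit-shaped object built directly from known components."""
    from rhodocycle.globalfit import MultiExpFit

    taus = np.asarray(taus, float)
    das = np.atleast_2d(np.asarray(das, float))
    n_wl = das.shape[0]
    return MultiExpFit(
        taus=taus,
        das=das,
        offset=None,
        rss=0.0,
        n_params=taus.size * (1 + n_wl),
        n_points=times.size * n_wl,
        converged=True,
        wavelengths=np.asarray(wavelengths, float),
        times=np.asarray(times, float),
    )


class TestDasToEads:
    def test_single_component_eads_equals_das(self):
        times = np.geomspace(1e-5, 1e-2, 40)
        fit = make_fit([1e-3], [[0.7], [-0.3]], times, [406.0, 561.0])
        result = das_to_eads(fit)
        np.testing.assert_allclose(result.eads, fit.das)

    def test_two_state_relation_and_occupancy_oracle(self):
        """EADS1 = DAS1 + DAS2 and EADS2 = DAS2 (1 - tau1/tau2), verified by
        least-squares projection onto the chain occupancies."""
        times = np.geomspace(1e-6, 1e-1, 200)
        tau1, tau2 = 1e-5, 1e-2  # tau1 << tau2
        das = np.array([[1.0, -0.5], [0.2, 0.9]])
        fit = make_fit([tau1, tau2], das, times, [406.0, 561.0])
        result = das_to_eads(fit)
        np.testing.assert_allclose(
            result.eads[:, 0], das[:, 0] + das[:, 1], rtol=1e-9
        )
        np.testing.assert_allclose(
            result.eads[:, 1], das[:, 1] * (1.0 - tau1 / tau2), rtol=1e-9
        )
        # independent oracle: regress the DAS signal on Bateman occupancies
        chain = SequentialScheme(
            intermediates=(
                IntermediateState("1", (tau1,)),
                IntermediateState("2", (tau2,)),
            )
        )
        occ, _ = concentrations(chain, times)
        E = np.exp(-times[:, None] / fit.taus[None, :])
        signal = das @ E.T
        oracle, *_ = np.linalg.lstsq(occ.T, signal.T, rcond=None)
        np.testing.assert_allclose(result.eads, oracle.T, rtol=1e-6, atol=1e-12)

    def test_signal_preservation(self, sacr_fit):
        """(scheme, EADS) and (taus, DAS) reconstructions agree everywhere."""
        result = das_to_eads(sacr_fit)
        np.testing.assert_allclose(
            result.reconstruct(), sacr_fit.model(), atol=1e-8
        )

    def test_duplicate_taus_rejected(self):
        times = np.geomspace(1e-5, 1e-2, 40)
        fit = make_fit([1e-3, 1e-3], [[0.5, 0.5]], times, [406.0])
        with pytest.raises(ValueError, match="duplicate"):
            das_to_eads(fit)

    def test_bateman_coefficients_reconstruct_occupancies(self):
        taus = np.array([1e-5, 1e-3, 5e-2])
        B = bateman_coefficients(taus)
        times = np.geomspace(1e-6, 1.0, 50)
        chain = SequentialScheme(
            intermediates=tuple(
                IntermediateState(str(i), (tau,)) for i, tau in enumerate(taus)
            )
        )
        occ, _ = concentrations(chain, times)
        E = np.exp(-times[:, None] / taus[None, :])
        np.testing.assert_allclose(occ, B @ E.T, rtol=1e-9, atol=1e-12)


class TestRoundTrip:
    def test_zero_noise_recovers_generating_spectra(self):
        """generate (no noise) -> fit 7 -> EADS -> merge 5 recovers the
        ground-truth difference spectra within 0.5% everywhere."""
        config = GeneratorConfig(
            seed=0, scenario="sacr_photocycle", overrides={"noise_frac": 0.0}
        )
        data, scheme, spectra = gen_photocycle(config)
        fit = fit_multiexponential(data, 7, restarts=8)
        merged = merge_biphasic(das_to_eads(fit), 5)
        scale = np.max(np.abs(spectra.delta_epsilon))
        np.testing.assert_allclose(
            merged.eads, spectra.delta_epsilon.T, atol=0.005 * scale
        )

    def test_end_to_end_lifetime_recovery(self):
        """1% noise, 200 points: all five state lifetimes within +/-3
        measured S.D. and fractions within +/-10 points in >=90% of 20 seeds
        (acceptance-grade parameter recovery)."""
        bands = [
            (1.7e-6, 3 * 0.3e-6), (13e-6, 3 * 1.8e-6), (118e-6, 3 * 2e-6),
            (1.6e-3, 3 * 0.1e-3), (23.5e-3, 3 * 1.0e-3),
            (98.4e-3, 3 * 6.4e-3), (384e-3, 3 * 18e-3),
        ]
        hits = 0
        for seed in range(1, 21):
            data, _, _ = gen_photocycle(
                GeneratorConfig(seed=seed, scenario="sacr_photocycle")
            )
            fit = fit_multiexponential(data, 7, restarts=8)
            result = refine_scheme(merge_biphasic(das_to_eads(fit), 5), data)
            states = result.scheme.intermediates
            lifetimes = [t for s in states for t in s.lifetimes]
            ok = all(
                abs(val - mid) <= tol for val, (mid, tol) in zip(lifetimes, bands)
            )
            ok &= abs(states[0].fractions[0] - 0.42) <= 0.10
            ok &= abs(states[4].fractions[0] - 0.56) <= 0.10
            hits += ok
        assert hits >= 18  # >= 90% of 20 seeds


class TestMergeBiphasic:
    def test_identical_adjacent_eads_are_merged(self):
        times = np.geomspace(1e-6, 1e-1, 150)
        taus = [1e-5, 5e-5, 1e-2]
        # components 1,2 share a spectrum; component 3 is orthogonal
        eads = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        B = bateman_coefficients(np.array(taus))
        das = eads @ B
        fit = make_fit(taus, das, times, [406.0, 561.0])
        merged = merge_biphasic(das_to_eads(fit), 2)
        assert merged.diagnostics["merged_pairs"] == [0]
        state = merged.scheme.intermediates[0]
        assert state.biphasic
        assert sum(state.fractions) == pytest.approx(1.0, abs=1e-3)

    def test_sacr_merges_first_and_last_pairs(self, sacr_fit):
        """Double-exponential decays belong to the first (I) and last (V)
        intermediates of the measured photocycle."""
        merged = merge_biphasic(das_to_eads(sacr_fit), 5)
        assert merged.diagnostics["merged_pairs"] == [0, 5]
        assert merged.scheme.intermediates[0].biphasic
        assert merged.scheme.intermediates[4].biphasic

    def test_fraction_percentages_normalised(self, sacr_fit):
        merged = merge_biphasic(das_to_eads(sacr_fit), 5)
        for state in merged.scheme.intermediates:
            if state.biphasic:
                assert 100.0 * sum(state.fractions) == pytest.approx(100.0,
                                                                     abs=0.1)

    def test_impossible_merge_count_rejected(self, sacr_fit):
        result = das_to_eads(sacr_fit)
        with pytest.raises(ValueError, match="disjoint"):
            merge_biphasic(result, 3)  # 4 merges on 7 components
        with pytest.raises(ValueError, match="nothing to merge"):
            merge_biphasic(result, 7)


class TestLabels:
    def result_with_eads(self, eads, taus=None):
        eads = np.asarray(eads, float)
        n = eads.shape[1]
        taus = np.geomspace(1e-5, 1e-1, n) if taus is None else taus
        scheme = SequentialScheme(
            intermediates=tuple(
                IntermediateState(f"S{i}", (tau,)) for i, tau in enumerate(taus)
            )
        )
        return PhotocycleResult(
            scheme=scheme,
            eads=eads,
            wavelengths=np.array([406.0, 561.0, 638.0]),
            times=np.geomspace(1e-6, 1.0, 10),
        )

    def test_blue_positive_state_is_M(self):
        result = self.result_with_eads([[1.0], [-0.2], [0.0]])
        assert label_intermediates(result).labels == ["M"]

    def test_two_red_positive_states_are_K_then_O(self):
        eads = np.array([[0.0, 0.0], [-0.3, -0.2], [1.0, 0.8]])
        result = self.result_with_eads(eads)
        assert label_intermediates(result).labels == ["K", "O"]

    def test_all_zero_state_warns_and_gets_ordinal(self):
        eads = np.array([[1.0, 0.0], [-0.2, 0.0], [0.0, 0.0]])
        result = self.result_with_eads(eads)
        with pytest.warns(UserWarning, match="all-zero"):
            labels = label_intermediates(result).labels
        assert labels == ["M", "II"]

    def test_missing_convention_wavelength_rejected(self):
        result = self.result_with_eads([[1.0], [-0.2], [0.0]])
        with pytest.raises(ValueError, match="absent"):
            label_intermediates(result, {"blue": 406.0, "bleach": 561.0,
                                         "red": 700.0})

    def test_sacr_pipeline_labels(self, sacr_fit, sacr_dataset):
        data, _, _ = sacr_dataset
        result = infer_photocycle(sacr_fit, max_states=5, data=data)
        # K-like rise, L before the blue-shifted M, red-absorbing late states
        assert result.labels[0] == "K"
        assert result.labels[1] == "L"
        assert result.labels[2] == "M"
        assert set(result.labels[3:]) <= {"O", "IV", "V"}
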