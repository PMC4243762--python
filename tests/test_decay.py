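"""TCSPC decay model, simulation, fitting and mean lifetime."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probekit import datasets
from probekit.decay import (
    DecayComponent,
    DecayHistogram,
    decay_model,
    fit_decay,
    gaussian_irf,
    mean_lifetime,
    select_model,
    simulate_decay,
)


class TestDecayModel:
    def test_normalized_at_origin(self):
        assert decay_model([DecayComponent(1.0, 2.0)], 0.0) == pytest.approx(1.0)

    def test_single_exponential_closed_form(self):
        assert decay_model([DecayComponent(1.0, 2.0)], 2.0) == pytest.approx(np.exp(-1))

    def test_two_component_direct_evaluation(self):
        comps = [DecayComponent(0.6, 5.8), DecayComponent(0.4, 0.5)]
        expected = 0.6 * np.exp(-1 / 5.8) + 0.4 * np.exp(-1 / 0.5)
        assert decay_model(comps, 1.0) == pytest.approx(expected)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            decay_model([DecayComponent(1.0, 2.0)], -0.1)

    def test_unnormalized_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            decay_model([DecayComponent(0.5, 2.0), DecayComponent(0.6, 1.0)], 0.0)


class TestMeanLifetime:
    @pytest.mark.parametrize(
        "alphas,taus,expected",
        [
            ((0.56, 0.44), (6.18, 0.53), 5.82),  # gel-phase DPPC
            ((0.64, 0.36), (3.42, 0.64), 3.16),  # fluid POPC
            ((1.0,), (4.35,), 4.35),  # single-exponential
        ],
    )
    def test_printed_values(self, alphas, taus, expected):
        comps = [DecayComponent(a, t) for a, t in zip(alphas, taus)]
        assert round(mean_lifetime(comps), 2) == pytest.approx(expected)

    def test_all_printed_two_component_rows(self):
        """Every published two-component fit reproduces its printed <tau>."""
        for row in datasets.LIPID_LIFETIMES:
            if row.two_component:
                got = mean_lifetime(row.components())
                assert got == pytest.approx(row.mean_tau, abs=0.02), row

    @settings(derandomize=True)
    @given(
        a1=st.floats(0.05, 0.95),
        t1=st.floats(0.1, 10),
        t2=st.floats(0.1, 10),
    )
    def test_bounded_by_component_lifetimes(self, a1, t1, t2):
        comps = [DecayComponent(a1, t1), DecayComponent(1 - a1, t2)]
        mt = mean_lifetime(comps)
        assert min(t1, t2) - 1e-12 <= mt <= max(t1, t2) + 1e-12

    def test_empty_components_rejected(self):
        with pytest.raises(ValueError):
            mean_lifetime([])


class TestSimulateDecay:
    def test_seed_determinism(self, dppc_components):
        h1 = simulate_decay(dppc_components, 100_000, seed=7)
        h2 = simulate_decay(dppc_components, 100_000, seed=7)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_noiseless_log_slope(self):
        """Noiseless single-exponential expectation regresses to slope -1/tau."""
        h = simulate_decay([DecayComponent(1.0, 2.0)], 10**6, poisson=False)
        sel = h.counts > 1
        slope = np.polyfit(h.bin_centers[sel], np.log(h.counts[sel]), 1)[0]
        assert slope == pytest.approx(-0.5, rel=0.01)

    def test_delta_irf_matches_no_irf(self, dppc_components):
        """A delta IRF is the identity of convolution."""
        plain = simulate_decay(dppc_components, 10**6, poisson=False)
        delta = np.zeros(2000)
        delta[0] = 1.0
        with_irf = simulate_decay(dppc_components, 10**6, irf=delta, poisson=False)
        np.testing.assert_allclose(with_irf.counts, plain.counts, rtol=1e-9)

    def test_mismatched_irf_rejected(self, dppc_components):
        with pytest.raises(ValueError):
            simulate_decay(dppc_components, 1000, n_bins=100, irf=np.ones(50))


class TestFitDecay:
    def test_noiseless_single_exponential_exact(self):
        h = simulate_decay([DecayComponent(1.0, 3.0)], 10**6, poisson=False)
        fit = fit_decay(h, 1)
        assert fit.components[0].tau == pytest.approx(3.0, abs=1e-6)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_two_component_recovery_with_irf(self, dppc_components):
        centers = (np.arange(2000) + 0.5) * 0.025
        irf = gaussian_irf(centers, center=2.0, fwhm=0.5, area=1e5)
        h = simulate_decay(dppc_components, 10**6, irf=irf, seed=11)
        fit = fit_decay(h, 2)
        taus = [c.tau for c in fit.components]
        alphas = [c.alpha for c in fit.components]
        assert taus[0] == pytest.approx(6.18, rel=0.05)
        assert taus[1] == pytest.approx(0.53, rel=0.10)
        assert alphas[0] == pytest.approx(0.56, abs=0.05)

    def test_scale_invariance_on_noiseless_histogram(self, dppc_components):
        h = simulate_decay(dppc_components, 10**6, poisson=False)
        scaled = DecayHistogram(h.bin_centers, h.counts * 7.3)
        f1, f2 = fit_decay(h, 2), fit_decay(scaled, 2)
        for c1, c2 in zip(f1.components, f2.components):
            assert c2.tau == pytest.approx(c1.tau, rel=1e-3)
            assert c2.alpha == pytest.approx(c1.alpha, abs=1e-3)

    def test_components_sorted_descending(self, dppc_components):
        h = simulate_decay(dppc_components, 10**6, seed=3)
        fit = fit_decay(h, 2)
        assert fit.components[0].tau > fit.components[1].tau
        assert sum(c.alpha for c in fit.components) == pytest.approx(1.0)

    def test_more_than_two_components_unsupported(self, dppc_components):
        h = simulate_decay(dppc_components, 10**5, seed=0)
        with pytest.raises(ValueError):
            fit_decay(h, 3)

    def test_overfit_single_exponential_flagged_degenerate(self):
        """2-component fit of truly 1-exp data: vanishing amplitude or tau pair."""
        h = simulate_decay([DecayComponent(1.0, 3.0)], 10**6, seed=5)
        fit = fit_decay(h, 2)
        a_min = min(c.alpha for c in fit.components)
        tau_ratio = fit.components[0].tau / fit.components[1].tau
        assert a_min < 0.05 or tau_ratio < 1.5


class TestSelectModel:
    def test_single_exponential_selects_one(self):
        h = simulate_decay([DecayComponent(1.0, 3.0)], 10**6, seed=2)
        n, _ = select_model(h)
        assert n == 1

    def test_well_separated_two_component_selects_two(self, dppc_components):
        h = simulate_decay(dppc_components, 10**6, seed=2)
        n, _ = select_model(h)
        assert n == 2

    def test_infinite_threshold_always_one(self, dppc_components):
        h = simulate_decay(dppc_components, 10**6, seed=2)
        n, _ = select_model(h, chi2_improvement_threshold=np.inf)
        assert n == 1
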