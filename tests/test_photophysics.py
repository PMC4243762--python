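"""GP, quantum yield, rate constants, brightness, GP-theta correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probekit import datasets
from probekit.photophysics import (
    EmissionSpectrum,
    QuantumYieldSample,
    UndefinedGPError,
    brightness,
    compute_gp,
    confidence_band,
    gp_from_spectrum,
    gp_relaxation_correlation,
    quantum_yield,
    rate_constants,
    round_half_up,
)


class TestComputeGP:
    @pytest.mark.parametrize(
        "i440,i490,expected",
        [(5.0, 5.0, 0.0), (1.0, 0.0, 1.0), (0.0, 1.0, -1.0), (3.0, 1.0, 0.5)],
    )
    def test_closed_form(self, i440, i490, expected):
        assert compute_gp(i440, i490) == pytest.approx(expected)

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedGPError):
            compute_gp(0.0, 0.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_gp(-1.0, 2.0)

    @settings(derandomize=True)
    @given(
        a=st.floats(0, 1e6, allow_nan=False),
        b=st.floats(0, 1e6, allow_nan=False),
    )
    def test_bounded_and_antisymmetric(self, a, b):
        if a + b == 0:
            return
        gp = compute_gp(a, b)
        assert -1.0 <= gp <= 1.0
        assert compute_gp(b, a) == pytest.approx(-gp)


class TestGPFromSpectrum:
    def test_flat_spectrum_gives_zero(self, flat_spectrum):
        assert gp_from_spectrum(flat_spectrum) == pytest.approx(0.0)
        assert gp_from_spectrum(flat_spectrum, bandwidth=10.0) == pytest.approx(0.0)

    def test_single_band_at_440(self):
        lam = np.arange(370.0, 601.0, 1.0)
        inten = np.where(np.abs(lam - 440.0) <= 2, 100.0, 0.0)
        spec = EmissionSpectrum(lam, inten)
        assert gp_from_spectrum(spec) == pytest.approx(1.0)

    def test_two_band_matches_hand_integration(self):
        # independent oracle: evaluate the generated band shapes directly
        lam = np.arange(370.0, 601.0, 1.0)
        band = lambda c, s: np.exp(-0.5 * ((lam - c) / s) ** 2)
        inten = 0.7 * band(440.0, 20.0) + 0.3 * band(490.0, 20.0)
        spec = EmissionSpectrum(lam, inten)
        i440 = float(np.interp(440.0, lam, inten))
        i490 = float(np.interp(490.0, lam, inten))
        assert gp_from_spectrum(spec) == pytest.approx(compute_gp(i440, i490))
        # band mode against trapezoid integration of the same arrays
        sel = lambda c: (lam >= c - 5) & (lam <= c + 5)
        ia = np.trapezoid(inten[sel(440.0)], lam[sel(440.0)])
        ib = np.trapezoid(inten[sel(490.0)], lam[sel(490.0)])
        assert gp_from_spectrum(spec, bandwidth=10.0) == pytest.approx(
            compute_gp(ia, ib), abs=1e-9
        )

    def test_center_outside_range_raises(self, flat_spectrum):
        with pytest.raises(ValueError):
            gp_from_spectrum(flat_spectrum, centers=(300.0, 490.0))


class TestQuantumYield:
    def test_identity_against_reference(self):
        ref = QuantumYieldSample(150.0, 0.03, 1.426)
        assert quantum_yield(ref, ref, 0.97) == pytest.approx(0.97)

    def test_linear_in_area(self):
        ref = QuantumYieldSample(100.0, 0.02, 1.40)
        doubled = QuantumYieldSample(200.0, 0.02, 1.40)
        assert quantum_yield(doubled, ref, 0.5) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        sample = QuantumYieldSample(100.0, 0.02, 1.45)
        ref = QuantumYieldSample(200.0, 0.04, 1.43)
        expected = (100 / 200) * (0.04 / 0.02) * (1.45 / 1.43) ** 2 * 0.97
        assert quantum_yield(sample, ref, 0.97) == pytest.approx(expected)

    @settings(derandomize=True)
    @given(c=st.floats(0.1, 10.0))
    def test_homogeneity(self, c):
        ref = QuantumYieldSample(100.0, 0.02, 1.4)
        base = QuantumYieldSample(50.0, 0.01, 1.35)
        scaled_area = QuantumYieldSample(50.0 * c, 0.01, 1.35)
        scaled_od = QuantumYieldSample(50.0, 0.01 * c, 1.35)
        phi = quantum_yield(base, ref, 0.9)
        assert quantum_yield(scaled_area, ref, 0.9) == pytest.approx(c * phi)
        assert quantum_yield(scaled_od, ref, 0.9) == pytest.approx(phi / c)


class TestRateConstants:
    @pytest.mark.parametrize(
        "phi,tau,kr,knr",
        [(0.61, 2.78, 0.22, 0.14), (1.0, 2.0, 0.5, 0.0), (0.16, 1.26, 0.13, 0.67)],
    )
    def test_printed_values(self, phi, tau, kr, knr):
        got_kr, got_knr = rate_constants(phi, tau)
        assert round_half_up(got_kr, 2) == pytest.approx(kr)
        assert round_half_up(got_knr, 2) == pytest.approx(knr)

    @settings(derandomize=True)
    @given(phi=st.floats(0, 1), tau=st.floats(0.01, 100))
    def test_rates_sum_to_inverse_lifetime(self, phi, tau):
        kr, knr = rate_constants(phi, tau)
        assert kr + knr == pytest.approx(1.0 / tau, rel=1e-12)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValueError):
            rate_constants(0.5, 0.0)

    def test_all_printed_solvent_rates_within_rounding(self):
        for row in datasets.SOLVENT_PHOTOPHYSICS:
            kr, knr = rate_constants(row.phi, row.tau)
            assert round_half_up(kr, 2) == pytest.approx(row.kr, abs=0.0101), row
            assert round_half_up(knr, 2) == pytest.approx(row.knr, abs=0.0101), row


class TestBrightness:
    def test_printed_values(self):
        for name, probe in datasets.PROBES.items():
            assert brightness(probe.epsilon_360, probe.phi) == datasets.PRINTED_BRIGHTNESS[name]

    def test_zero_yield(self):
        assert brightness(19500.0, 0.0) == 0


class TestCorrelation:
    def test_exact_line(self):
        x = np.arange(1.0, 7.0)
        for slope in (0.1, -0.1):
            pairs = np.column_stack([x, slope * x + 0.05])
            res = gp_relaxation_correlation(pairs)
            assert res.pearson_r == pytest.approx(1.0 if slope > 0 else -1.0)
            assert res.slope == pytest.approx(slope)

    def test_slope_recovered_within_3_se(self):
        rng = np.random.default_rng(42)
        x = np.linspace(1.0, 8.0, 12)
        true_slope = 0.06
        y = true_slope * x - 0.1 + rng.normal(0, 0.02, x.size)
        res = gp_relaxation_correlation(np.column_stack([x, y]))
        assert abs(res.slope - true_slope) <= 3 * res.stderr

    def test_confidence_band_positive_width(self):
        rng = np.random.default_rng(0)
        x = np.linspace(1, 8, 10)
        pairs = np.column_stack([x, 0.05 * x + rng.normal(0, 0.01, 10)])
        fit_vals, half = confidence_band(pairs, np.array([2.0, 5.0]))
        assert np.all(half > 0) and fit_vals.shape == (2,)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            gp_relaxation_correlation([(1.0, 0.1), (2.0, 0.2)])
        with pytest.raises(ValueError):
            gp_relaxation_correlation([(1.0, 0.1), (1.0, 0.2), (1.0, 0.3)])


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.215, 2) == pytest.approx(0.22)
    assert round_half_up(118.95, 0) == pytest.approx(119.0)
    assert round_half_up(-0.215, 2) == pytest.approx(-0.22)
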