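"""Generator determinism, invariants and round trips."""

import numpy as np
import pytest

from probekit.anisotropy import steady_state_anisotropy
from probekit.photophysics import gp_from_spectrum
from probekit.solvents import SOLVENTS, SolventSpec, mixture_dielectric
from probekit.synthetic import (
    SceneSpec,
    SpectrumModel,
    gen_insertion_trace,
    gen_polarized,
    gen_scene,
    gen_spectrum,
    gen_thermal_scan,
    ict_weight,
)


class TestGenSpectrum:
    def test_pure_le_gives_positive_gp(self):
        spec = gen_spectrum(SOLVENTS["chloroform"], weight_override=0.0)
        assert gp_from_spectrum(spec) > 0

    def test_pure_ict_gives_negative_gp(self):
        spec = gen_spectrum(SOLVENTS["chloroform"], weight_override=1.0)
        assert gp_from_spectrum(spec) < 0

    def test_gp_decreases_along_epsilon_ladder(self):
        """Dioxane/water ladder, protic flag off: GP strictly decreasing."""
        gps = []
        for eps in np.linspace(2.2, 60.0, 12):
            solvent = SolventSpec("mix", eps, 1.40, "polar-aprotic")
            gps.append(gp_from_spectrum(gen_spectrum(solvent)))
        assert np.all(np.diff(gps) < 0)

    def test_calibration_brackets_solvent_pattern(self):
        nonpolar = gp_from_spectrum(gen_spectrum(SOLVENTS["chloroform"]))
        protic = gp_from_spectrum(gen_spectrum(SOLVENTS["ethanol"]))
        assert nonpolar > 0.4
        assert protic < -0.2

    def test_seed_determinism_with_noise(self):
        model = SpectrumModel(noise_sigma=5.0)
        s1 = gen_spectrum(SOLVENTS["acetone"], model, seed=9)
        s2 = gen_spectrum(SOLVENTS["acetone"], model, seed=9)
        np.testing.assert_array_equal(s1.intensities, s2.intensities)

    def test_ict_weight_bounds(self):
        assert 0.0 <= ict_weight(80.1, True) <= 1.0
        assert ict_weight(2.2, False) < ict_weight(60.0, False)


class TestGenPolarized:
    def test_zero_anisotropy_means_equal_vv_vh_at_unit_g(self):
        p = gen_polarized(0.0, 1e4, g_true=1.0)
        assert p.ivv == pytest.approx(p.ivh)

    def test_noiseless_round_trip_to_machine_precision(self):
        for r_true in (-0.1, 0.05, 0.25, 0.39):
            for g_true in (0.8, 1.0, 1.2):
                p = gen_polarized(r_true, 1e6, g_true=g_true)
                assert steady_state_anisotropy(p) == pytest.approx(r_true, abs=1e-12)

    def test_poisson_sampling_error(self):
        """At 10^6 total counts the recovered r stays within +/-0.005."""
        errs = [
            steady_state_anisotropy(
                gen_polarized(0.25, 1e6, g_true=0.9, seed=s, poisson=True)
            )
            - 0.25
            for s in range(20)
        ]
        assert np.max(np.abs(errs)) <= 0.005

    def test_out_of_range_r_rejected(self):
        with pytest.raises(ValueError):
            gen_polarized(1.0, 1e4)


class TestGenScans:
    def test_noiseless_scan_exact_sigmoid(self):
        from probekit.scans import boltzmann

        scan = gen_thermal_scan(tm=41.0, width=1.5, upper=0.55, lower=-0.1,
                                noise_sigma=0.0)
        np.testing.assert_allclose(
            scan.values, boltzmann(scan.temperatures, 41.0, 1.5, 0.55, -0.1)
        )

    def test_grid_is_10_to_60_by_2(self):
        scan = gen_thermal_scan()
        assert scan.temperatures[0] == 10.0
        assert scan.temperatures[-1] == 60.0
        assert np.all(np.diff(scan.temperatures) == 2.0)

    def test_trace_half_rise_at_t_half(self):
        trace = gen_insertion_trace(imax=100.0, t_half=10.0, noise_frac=0.0)
        idx = np.argmin(np.abs(trace.times - 10.0))
        assert trace.intensities[idx] == pytest.approx(50.0)

    def test_slow_inserter_still_rising_at_40_min(self):
        """t_half = 12 min emulates slow probe insertion."""
        trace = gen_insertion_trace(imax=100.0, t_half=12.0, noise_frac=0.0)
        i40 = trace.intensities[np.argmin(np.abs(trace.times - 40.0))]
        i60 = trace.intensities[-1]
        assert i60 > i40 > 0.5 * i60  # rising but well past half-saturation

    def test_trace_seed_determinism(self):
        t1 = gen_insertion_trace(noise_frac=0.05, seed=3)
        t2 = gen_insertion_trace(noise_frac=0.05, seed=3)
        np.testing.assert_array_equal(t1.intensities, t2.intensities)

    def test_plateau_reached_when_duration_exceeds_4_t_half(self):
        trace = gen_insertion_trace(imax=100.0, t_half=10.0, duration=60.0,
                                    noise_frac=0.0)
        assert trace.intensities[-1] >= 0.8 * 100.0


class TestGenScene:
    def test_single_region_zero_gp(self):
        from probekit.imaging import gp_map

        spec = SceneSpec(
            labels=np.zeros((16, 16), dtype=int),
            region_gp={0: 0.0},
            region_intensity={0: 10_000.0},
            seed=0,
        )
        gpm = gp_map(gen_scene(spec), min_total_intensity=100.0)
        assert np.nanmean(gpm.gp) == pytest.approx(0.0, abs=0.02)

    def test_zero_intensity_background_masked(self):
        from probekit.imaging import gp_map

        labels = np.zeros((16, 16), dtype=int)
        labels[:, 8:] = 1
        spec = SceneSpec(labels, {0: 0.3, 1: 0.0}, {0: 5000.0, 1: 0.0}, seed=1)
        gpm = gp_map(gen_scene(spec), min_total_intensity=1.0)
        assert not gpm.mask[:, 8:].any()
        assert gpm.mask[:, :8].all()

    def test_scene_seed_determinism(self):
        spec = SceneSpec(np.zeros((8, 8), dtype=int), {0: 0.2}, {0: 1000.0}, seed=5)
        s1, s2 = gen_scene(spec), gen_scene(spec)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)

    def test_invalid_region_gp_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(np.zeros((4, 4), dtype=int), {0: 1.5}, {0: 100.0})


def test_full_synthetic_study_runs_quickly(tmp_path):
    """7 solvents x 4 probes + lipid scenarios pass through every stage."""
    from probekit.io import RunConfig, run_pipeline

    report = run_pipeline(RunConfig(out_dir=str(tmp_path / "study"), seed=11))
    assert set(report) == {"solvents", "decay", "anisotropy", "scans", "imaging"}
    assert report["solvents"]["n_rows"] == 28
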