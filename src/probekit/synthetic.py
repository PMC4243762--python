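"""Synthetic-data generators standing in for the instruments.

Every generator is deterministic given its seed and produces objects that
satisfy the invariants of the analysis types they feed:

* two-band (LE/ICT) emission spectra whose band weights shift with solvent
  dielectric constant and protic character (spectrofluorimeter),
* Poisson-noised multi-exponential decays with IRF (TCSPC — see
  :func:`probekit.decay.simulate_decay`),
* polarized-intensity quadruples for a chosen true anisotropy and G-factor,
* sigmoidal GP(T)/r(T) melting scans and hyperbolic insertion traces,
* multi-channel image scenes with regions of distinct GP (two-photon
  microscope).

The epsilon-to-ICT-weight map is an affine calibration with a protic
offset, chosen so that a nonpolar solvent gives GP around +0.5 and a
protic solvent with epsilon > 20 gives GP below -0.2 — the qualitative
pattern of laurdan-family probes in pure solvents.  Its coefficients are
package constants, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anisotropy import PolarizedIntensities
from .imaging import SpectralStack
from .photophysics import EmissionSpectrum
from .scans import KineticTrace, ThermalScan, boltzmann, one_site_binding
from .solvents import SolventSpec

__all__ = [
    "SpectrumModel",
    "SceneSpec",
    "ict_weight",
    "gen_spectrum",
    "gen_polarized",
    "gen_thermal_scan",
    "gen_insertion_trace",
    "gen_scene",
    "two_region_scene",
]

# ICT-weight calibration constants (dimensionless): w = A + B*eps (+ protic bonus)
_W_OFFSET = 0.14
_W_SLOPE = 0.004  # per unit dielectric constant
_W_PROTIC = 0.55


@dataclass(frozen=True)
class SpectrumModel:
    """Two-Gaussian emission model: LE band near 440 nm, ICT band near 490 nm."""

    le_center: float = 440.0
    ict_center: float = 490.0
    le_width: float = 25.0  # Gaussian sigma, nm
    ict_width: float = 25.0
    amplitude: float = 1000.0
    noise_sigma: float = 0.0  # additive Gaussian noise, a.u.

    def __post_init__(self) -> None:
        if not (370.0 <= self.le_center <= 600.0 and 370.0 <= self.ict_center <= 600.0):
            raise ValueError("band centers must lie within 370-600 nm")
        if self.le_width <= 0 or self.ict_width <= 0:
            raise ValueError("band widths must be positive")


def ict_weight(epsilon: float, protic: bool) -> float:
    """Fraction of emission in the solvent-relaxed ICT band, in [0, 1].

    Affine in the dielectric constant with an additive protic bonus
    (hydrogen-bonding solvents red-shift far more than epsilon alone
    predicts).
    """
    return float(np.clip(_W_OFFSET + _W_SLOPE * epsilon + (_W_PROTIC if protic else 0.0), 0.0, 1.0))


def gen_spectrum(
    solvent: SolventSpec,
    model: SpectrumModel = SpectrumModel(),
    seed: int | None = None,
    weight_override: float | None = None,
    grid: np.ndarray | None = None,
) -> EmissionSpectrum:
    """Synthetic emission spectrum of a solvatochromic probe in a solvent.

    weight_override forces the ICT weight (0 = pure LE, 1 = pure ICT),
    bypassing the solvent map; useful for limit tests.
    """
    w = ict_weight(solvent.epsilon, solvent.protic) if weight_override is None else weight_override
    if not 0.0 <= w <= 1.0:
        raise ValueError("ICT weight must lie in [0, 1]")
    lam = np.arange(370.0, 600.0 + 1e-9, 1.0) if grid is None else np.asarray(grid, float)
    le = np.exp(-0.5 * ((lam - model.le_center) / model.le_width) ** 2)
    ict = np.exp(-0.5 * ((lam - model.ict_center) / model.ict_width) ** 2)
    intensity = model.amplitude * ((1.0 - w) * le + w * ict)
    if model.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, model.noise_sigma, lam.shape)
    intensity = np.clip(intensity, 0.0, None)
    return EmissionSpectrum(
        wavelengths=lam,
        intensities=intensity,
        excitation=360.0,
        sample_meta=f"synthetic: {solvent.name} (eps={solvent.epsilon})",
    )


def gen_polarized(
    r_true: float,
    total_intensity: float,
    g_true: float = 1.0,
    seed: int | None = None,
    poisson: bool = False,
) -> PolarizedIntensities:
    """Polarized-intensity quadruple for a chosen true anisotropy.

    Solves the anisotropy equation exactly: with D = Ivv + 2 G Ivh set to
    total_intensity, Ivv = D(1 + 2r)/3 and G*Ivh = D(1 - r)/3.  The
    horizontal-excitation pair encodes the instrument bias g_true.
    Optional Poisson noise treats the four intensities as photon counts.
    """
    if not -0.5 < r_true < 1.0:
        raise ValueError("r_true must lie in (-0.5, 1)")
    if total_intensity <= 0 or g_true <= 0:
        raise ValueError("total intensity and G must be positive")
    ivv = total_intensity * (1.0 + 2.0 * r_true) / 3.0
    ivh = total_intensity * (1.0 - r_true) / (3.0 * g_true)
    ihh = total_intensity / 4.0  # arbitrary reference level for the G pair
    ihv = g_true * ihh
    vals = np.array([ivv, ivh, ihv, ihh])
    if poisson:
        rng = np.random.default_rng(seed)
        vals = rng.poisson(vals).astype(float)
    return PolarizedIntensities(*vals)


def gen_thermal_scan(
    tm: float = 41.0,
    width: float = 1.5,
    upper: float = 0.55,
    lower: float = -0.10,
    t_min: float = 10.0,
    t_max: float = 60.0,
    step: float = 2.0,
    noise_sigma: float = 0.01,
    seed: int | None = None,
    quantity: str = "GP",
) -> ThermalScan:
    """Sigmoidal melting scan on the standard 10-60 degC grid (2 degC steps).

    Defaults emulate a DPPC bilayer (Tm = 41 degC) probed by GP: high
    plateau in the gel (So) phase, steep descent at the melting transition.
    upper == lower gives a flat (no-transition) scan.
    """
    temps = np.arange(t_min, t_max + 1e-9, step)
    values = boltzmann(temps, tm, width, upper, lower)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, temps.shape)
    return ThermalScan(temperatures=temps, values=values, quantity=quantity)


def gen_insertion_trace(
    imax: float = 100.0,
    t_half: float = 4.5,
    duration: float = 60.0,
    step: float = 1.0,
    noise_frac: float = 0.0,
    seed: int | None = None,
) -> KineticTrace:
    """Hyperbolic probe-insertion trace sampled each `step` minutes.

    Defaults emulate fast-inserting probes (half-insertion ~4.5 min);
    slow inserters use t_half of 10-15 min.  Multiplicative Gaussian noise
    of fractional size noise_frac.
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    times = np.arange(0.0, duration + 1e-9, step)
    values = one_site_binding(times, imax, t_half)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + rng.normal(0.0, noise_frac, times.shape))
    return KineticTrace(times=times, intensities=np.clip(values, 0.0, None))


#: Fixed template emission spectrum used to fill non-GP channels of a scene
#: (normalized two-band shape of an intermediate-polarity environment).
_TEMPLATE_CENTERS = np.arange(420.0, 600.0 + 1e-9, 10.0)


def _template_weights() -> np.ndarray:
    le = np.exp(-0.5 * ((_TEMPLATE_CENTERS - 440.0) / 25.0) ** 2)
    ict = np.exp(-0.5 * ((_TEMPLATE_CENTERS - 490.0) / 25.0) ** 2)
    shape = 0.5 * le + 0.5 * ict
    return shape / shape.sum()


@dataclass
class SceneSpec:
    """A labeled scene: per-region true GP and mean total (440+490) intensity."""

    labels: np.ndarray  # integer region labels, (H, W)
    region_gp: dict[int, float]
    region_intensity: dict[int, float]  # expected I440 + I490 per pixel
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        for lab in np.unique(self.labels):
            if int(lab) not in self.region_gp or int(lab) not in self.region_intensity:
                raise ValueError(f"region {lab} missing GP or intensity")
        for lab, gp in self.region_gp.items():
            if not -1.0 <= gp <= 1.0:
                raise ValueError(f"region {lab} GP outside [-1, 1]")
        for lab, inten in self.region_intensity.items():
            if inten < 0:
                raise ValueError(f"region {lab} intensity negative")


def gen_scene(spec: SceneSpec) -> SpectralStack:
    """Synthetic two-photon spectral stack (420-600 nm, 10 nm channels).

    The 440 and 490 nm channel expectations invert the GP equation for each
    region's true GP at its mean intensity: I440 = I(1+GP)/2 and
    I490 = I(1-GP)/2.  All other channels follow a fixed template spectrum
    scaled to the region intensity.  All channels are Poisson-sampled.
    """
    h, w = spec.labels.shape
    centers = _TEMPLATE_CENTERS
    tmpl = _template_weights()
    expected = np.zeros((centers.size, h, w))
    i440 = int(np.argmin(np.abs(centers - 440.0)))
    i490 = int(np.argmin(np.abs(centers - 490.0)))
    for lab in np.unique(spec.labels):
        lab = int(lab)
        where = spec.labels == lab
        inten = spec.region_intensity[lab]
        gp = spec.region_gp[lab]
        for ch in range(centers.size):
            expected[ch][where] = inten * tmpl[ch]
        expected[i440][where] = inten * (1.0 + gp) / 2.0
        expected[i490][where] = inten * (1.0 - gp) / 2.0
    rng = np.random.default_rng(spec.seed)
    pixels = rng.poisson(expected).astype(float)
    return SpectralStack(channel_centers=centers, pixels=pixels)


def two_region_scene(
    shape: tuple[int, int] = (64, 64),
    gp_left: float = 0.4,
    gp_right: float = -0.2,
    intensity: float = 10_000.0,
    seed: int | None = None,
) -> tuple[SceneSpec, SpectralStack]:
    """Convenience scene: left/right halves with distinct GP, equal intensity."""
    labels = np.zeros(shape, dtype=int)
    labels[:, shape[1] // 2 :] = 1
    spec = SceneSpec(
        labels=labels,
        region_gp={0: gp_left, 1: gp_right},
        region_intensity={0: intensity, 1: intensity},
        seed=seed,
    )
    return spec, gen_scene(spec)
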