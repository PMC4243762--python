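"""Scalar photophysical quantities for solvatochromic membrane probes.

Generalized polarization (GP), relative quantum yield against a standard,
radiative/non-radiative de-excitation rate constants, molecular brightness,
and the correlation of GP with rotational relaxation time across lipid
environments.

GP is the normalized two-channel emission ratio

    GP = (I440 - I490) / (I440 + I490)

where 440 nm reads the locally-excited (LE) band and 490 nm the
solvent-relaxed charge-transfer (ICT) band.  GP near +1 means a dehydrated,
apolar probe environment (ordered bilayer); negative GP means a hydrated,
polar one (disordered bilayer or protic solvent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ProbeRecord",
    "EmissionSpectrum",
    "QuantumYieldSample",
    "CorrelationResult",
    "UndefinedGPError",
    "compute_gp",
    "gp_from_spectrum",
    "quantum_yield",
    "rate_constants",
    "brightness",
    "gp_relaxation_correlation",
    "confidence_band",
    "round_half_up",
]


class UndefinedGPError(ValueError):
    """Both GP channels are zero: the ratio is undefined."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's builtin ``round`` uses banker's rounding (0.215 -> 0.21);
    published tables round half up (0.215 -> 0.22).  A small epsilon makes
    decimal ties land on the intended side despite binary representation
    (0.215 is stored as 0.21499...).
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5 + 1e-9) / factor, x)


@dataclass(frozen=True)
class ProbeRecord:
    """Identity and basic photophysics of one probe.

    epsilon_360 is the molar extinction coefficient at 360 nm (M^-1 cm^-1),
    phi the fluorescence quantum yield; both measured in chloroform.
    """

    name: str
    formula: str
    molecular_weight: float
    epsilon_360: float
    phi: float

    def __post_init__(self) -> None:
        if self.epsilon_360 <= 0:
            raise ValueError("epsilon_360 must be positive")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")


@dataclass
class EmissionSpectrum:
    """Wavelength-indexed emission intensities.

    Wavelengths in nm, strictly ascending; intensities in arbitrary units,
    non-negative.  Default acquisition covers 370-600 nm with 360 nm
    excitation.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation: float = 360.0
    sample_meta: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if self.wavelengths.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def intensity_at(self, wavelength: float) -> float:
        """Linearly interpolated intensity at a single wavelength."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not lo <= wavelength <= hi:
            raise ValueError(
                f"wavelength {wavelength} nm outside spectral range [{lo}, {hi}]"
            )
        return float(np.interp(wavelength, self.wavelengths, self.intensities))

    def band_integral(self, center: float, bandwidth: float) -> float:
        """Trapezoid integral of intensity over [center - bw/2, center + bw/2]."""
        lo, hi = center - bandwidth / 2.0, center + bandwidth / 2.0
        if lo < self.wavelengths[0] or hi > self.wavelengths[-1]:
            raise ValueError(
                f"band [{lo}, {hi}] nm outside spectral range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}]"
            )
        inside = (self.wavelengths > lo) & (self.wavelengths < hi)
        grid = np.concatenate(([lo], self.wavelengths[inside], [hi]))
        vals = np.interp(grid, self.wavelengths, self.intensities)
        return float(np.trapezoid(vals, grid))


@dataclass(frozen=True)
class QuantumYieldSample:
    """One relative-quantum-yield measurement.

    area_s: integrated emission intensity (a.u.); od: optical density at
    the excitation wavelength (kept <= 0.05 to avoid inner-filter effects);
    n: solvent refractive index.
    """

    area_s: float
    od: float
    n: float

    def __post_init__(self) -> None:
        if self.area_s <= 0:
            raise ValueError("integrated area must be positive")
        if self.od <= 0:
            raise ValueError("optical density must be positive")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")


def compute_gp(i440: float, i490: float) -> float:
    """Generalized polarization (I440 - I490)/(I440 + I490), in [-1, 1]."""
    if i440 < 0 or i490 < 0:
        raise ValueError("channel intensities must be non-negative")
    total = i440 + i490
    if total == 0:
        raise UndefinedGPError("GP undefined: both channel intensities are zero")
    return (i440 - i490) / total


def gp_from_spectrum(
    spec: EmissionSpectrum,
    centers: tuple[float, float] = (440.0, 490.0),
    bandwidth: float = 0.0,
) -> float:
    """GP from an emission spectrum.

    bandwidth = 0 reads point intensities (linear interpolation) at the two
    centers, the spectrofluorimeter convention; bandwidth > 0 integrates
    each channel over center +/- bandwidth/2, the spectral-imaging
    convention (10 nm channels).
    """
    if bandwidth < 0:
        raise ValueError("bandwidth must be non-negative")
    c_a, c_b = centers
    if bandwidth == 0:
        i_a, i_b = spec.intensity_at(c_a), spec.intensity_at(c_b)
    else:
        i_a = spec.band_integral(c_a, bandwidth)
        i_b = spec.band_integral(c_b, bandwidth)
    return compute_gp(i_a, i_b)


def quantum_yield(
    sample: QuantumYieldSample,
    reference: QuantumYieldSample,
    phi_ref: float,
) -> float:
    """Relative quantum yield against a standard of known yield.

    phi = (S/S_r) * (OD_r/OD) * (n/n_r)^2 * phi_r

    with S the integrated emission area, OD the optical density at the
    excitation wavelength and n the solvent refractive index (subscript r:
    the reference standard, e.g. POPOP with phi = 0.97 in cyclohexane).
    """
    if not 0 <= phi_ref <= 1:
        raise ValueError("phi_ref must lie in [0, 1]")
    return (
        (sample.area_s / reference.area_s)
        * (reference.od / sample.od)
        * (sample.n / reference.n) ** 2
        * phi_ref
    )


def rate_constants(phi: float, tau: float) -> tuple[float, float]:
    """Radiative and non-radiative de-excitation rate constants (ns^-1).

    kr = phi/tau and knr = (1 - phi)/tau, so kr + knr = 1/tau exactly.
    """
    if tau <= 0:
        raise ValueError("lifetime must be positive")
    if not 0 <= phi <= 1:
        raise ValueError("quantum yield must lie in [0, 1]")
    return phi / tau, (1.0 - phi) / tau


def brightness(epsilon: float, phi: float, round_to: int = 100) -> int:
    """Molecular brightness epsilon * phi, rounded to the nearest round_to."""
    if epsilon <= 0:
        raise ValueError("extinction coefficient must be positive")
    if not 0 <= phi <= 1:
        raise ValueError("quantum yield must lie in [0, 1]")
    if round_to < 1:
        raise ValueError("round_to must be a positive integer")
    return int(round_half_up(epsilon * phi / round_to) * round_to)


@dataclass(frozen=True)
class CorrelationResult:
    """OLS line of GP on rotational relaxation time, with Pearson r."""

    pearson_r: float
    slope: float
    intercept: float
    stderr: float
    n: int


def gp_relaxation_correlation(
    pairs: list[tuple[float, float]] | np.ndarray,
) -> CorrelationResult:
    """Correlate GP with rotational relaxation time across environments.

    Ordinary least squares of GP (y) on relaxation time theta (x, ns),
    unweighted.  A strong positive correlation indicates that hydration
    (GP) and rotational order (theta) change together across the bilayer
    compositions probed.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (relaxation_time, GP) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance on one axis")
    res = stats.linregress(x, y)
    return CorrelationResult(
        pearson_r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        n=arr.shape[0],
    )


def confidence_band(
    pairs: list[tuple[float, float]] | np.ndarray,
    x_eval: np.ndarray,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """OLS confidence band for the regression mean at points x_eval.

    Standard prediction formula: half-width =
    t_{1-a/2, n-2} * s * sqrt(1/n + (x - xbar)^2 / Sxx).
    Returns (fitted values, half-widths).
    """
    arr = np.asarray(pairs, dtype=float)
    fit = gp_relaxation_correlation(arr)
    x, y = arr[:, 0], arr[:, 1]
    n = len(x)
    yhat = fit.slope * x + fit.intercept
    s2 = np.sum((y - yhat) ** 2) / (n - 2)
    sxx = np.sum((x - x.mean()) ** 2)
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 2)
    x_eval = np.asarray(x_eval, dtype=float)
    half = tcrit * np.sqrt(s2 * (1.0 / n + (x_eval - x.mean()) ** 2 / sxx))
    return fit.slope * x_eval + fit.intercept, half
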