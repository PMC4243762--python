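"""TCSPC fluorescence decay analysis.

Forward model, Poisson simulation, weighted least-squares fitting of one-
or two-exponential decays with optional instrument-response (IRF)
reconvolution, model selection, and the intensity-weighted mean lifetime

    <tau> = sum_i alpha_i tau_i^2 / sum_i alpha_i tau_i

where alpha_i are normalized pre-exponential amplitudes (sum alpha_i = 1)
and tau_i the component lifetimes in ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DecayComponent",
    "DecayHistogram",
    "DecayFit",
    "FitFailureError",
    "decay_model",
    "mean_lifetime",
    "gaussian_irf",
    "simulate_decay",
    "fit_decay",
    "select_model",
]

_ALPHA_TOL = 1e-9


class FitFailureError(RuntimeError):
    """Least-squares fit did not converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class DecayComponent:
    """One exponential decay component: normalized amplitude and lifetime (ns)."""

    alpha: float
    tau: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _check_components(components: Sequence[DecayComponent]) -> None:
    if len(components) == 0:
        raise ValueError("component list is empty")
    total = sum(c.alpha for c in components)
    if abs(total - 1.0) > _ALPHA_TOL:
        raise ValueError(f"amplitudes must sum to 1 (got {total})")


@dataclass
class DecayHistogram:
    """TCSPC counts per uniform time bin, with an optional IRF histogram."""

    bin_centers: np.ndarray
    counts: np.ndarray
    irf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_centers.ndim != 1 or self.bin_centers.size < 2:
            raise ValueError("need at least two bins")
        widths = np.diff(self.bin_centers)
        if not np.all(widths > 0):
            raise ValueError("bin centers must be ascending")
        if not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("bins must be uniformly spaced")
        if self.counts.shape != self.bin_centers.shape:
            raise ValueError("counts length must match bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.irf is not None:
            self.irf = np.asarray(self.irf, dtype=float)
            if self.irf.shape != self.bin_centers.shape:
                raise ValueError("IRF must be on the same bins as the decay")
            if np.any(self.irf < 0):
                raise ValueError("IRF counts must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass
class DecayFit:
    """Result of a multi-exponential fit.

    Components are sorted by descending lifetime; chi2 is the reduced
    chi-square with Neyman weights (variance = max(count, 1)).
    """

    components: list[DecayComponent]
    chi2: float
    mean_tau: float
    n_components: int
    scale: float
    window: tuple[int, int]
    success: bool
    message: str = ""

    def __post_init__(self) -> None:
        _check_components(self.components)
        taus = [c.tau for c in self.components]
        if not min(taus) - 1e-9 <= self.mean_tau <= max(taus) + 1e-9:
            raise ValueError("mean lifetime must lie between component lifetimes")


def decay_model(components: Sequence[DecayComponent], t) -> np.ndarray | float:
    """Amplitude-normalized decay I(t) = sum_i alpha_i exp(-t/tau_i)."""
    _check_components(components)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.zeros_like(t_arr)
    for c in components:
        out = out + c.alpha * np.exp(-t_arr / c.tau)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def mean_lifetime(components: Sequence[DecayComponent]) -> float:
    """Intensity-weighted mean lifetime sum(a t^2)/sum(a t), in ns."""
    _check_components(components)
    num = sum(c.alpha * c.tau**2 for c in components)
    den = sum(c.alpha * c.tau for c in components)
    return num / den


def gaussian_irf(
    bin_centers: np.ndarray, center: float, fwhm: float, area: float = 1.0
) -> np.ndarray:
    """Gaussian instrument response sampled on the histogram bins."""
    if fwhm <= 0:
        raise ValueError("FWHM must be positive")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = np.asarray(bin_centers, dtype=float)
    g = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return area * g / g.sum()


def _expected_shape(
    components: Sequence[DecayComponent],
    bin_centers: np.ndarray,
    irf: np.ndarray | None,
) -> np.ndarray:
    """Model decay on the bin grid, convolved with the (normalized) IRF."""
    t0 = bin_centers - bin_centers[0]  # model clock starts at the first bin
    shape = decay_model(components, t0)
    if irf is not None and np.any(irf > 0):
        kern = irf / irf.sum()
        shape = np.convolve(kern, shape)[: len(shape)]
    return shape


def simulate_decay(
    components: Sequence[DecayComponent],
    total_counts: int,
    n_bins: int = 2000,
    bin_width: float = 0.025,
    irf: np.ndarray | None = None,
    seed: int | None = None,
    poisson: bool = True,
) -> DecayHistogram:
    """Simulate a TCSPC histogram.

    The expected curve is the normalized multi-exponential model, convolved
    with the IRF when one is given (discrete linear convolution), scaled to
    total_counts and Poisson-sampled per bin.  poisson=False returns the
    noiseless expectation (useful for exact-recovery tests).
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    bin_centers = (np.arange(n_bins) + 0.5) * bin_width
    if irf is not None:
        irf = np.asarray(irf, dtype=float)
        if irf.shape != bin_centers.shape:
            raise ValueError("IRF length must match the number of bins")
    expected = _expected_shape(components, bin_centers, irf)
    expected = expected * (total_counts / expected.sum())
    if poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return DecayHistogram(bin_centers=bin_centers, counts=counts, irf=irf)


def _initial_taus(t: np.ndarray, y: np.ndarray, n_components: int) -> list[float]:
    """Deterministic starts: log-linear slopes of a two-segment split."""
    logy = np.log(np.maximum(y, 1.0))
    if n_components == 1:
        slope = np.polyfit(t, logy, 1)[0]
        return [max(-1.0 / slope, 1e-3) if slope < 0 else float(t[-1] - t[0])]
    mid = len(t) // 2
    taus = []
    for sl in (slice(mid, None), slice(0, mid)):  # tail first: longest tau
        if len(t[sl]) >= 2:
            slope = np.polyfit(t[sl], logy[sl], 1)[0]
        else:
            slope = -1.0
        taus.append(max(-1.0 / slope, 1e-3) if slope < 0 else float(t[-1] - t[0]))
    # keep starts distinct so the optimizer can separate the components
    if taus[0] / max(taus[1], 1e-9) < 2.0:
        taus[1] = taus[0] / 5.0
    return taus


def _default_window(hist: DecayHistogram) -> tuple[int, int]:
    nonzero = np.nonzero(hist.counts >= 1)[0]
    if nonzero.size == 0:
        raise ValueError("histogram is empty")
    stop = int(nonzero[-1]) + 1
    if hist.irf is not None:
        start = 0  # reconvolution fits the rising edge too
    else:
        start = int(np.argmax(hist.counts))
    return start, stop


def fit_decay(
    hist: DecayHistogram,
    n_components: int = 1,
    fit_window: tuple[int, int] | None = None,
) -> DecayFit:
    """Weighted least-squares multi-exponential fit of a TCSPC histogram.

    Neyman weights (variance = max(count, 1)); IRF reconvolution when the
    histogram carries an IRF, tail fit from the peak bin otherwise.
    Amplitudes are renormalized to sum to 1 and components sorted by
    descending lifetime.  Supports 1 or 2 components, matching standard
    single/double-exponential decay tables.
    """
    if n_components not in (1, 2):
        raise ValueError("only 1- or 2-component fits are supported")
    start, stop = fit_window if fit_window is not None else _default_window(hist)
    t = hist.bin_centers[start:stop]
    y = hist.counts[start:stop]
    n_free = 2 * n_components  # taus + (amplitude fraction or scale)
    if np.count_nonzero(y) < 10 * n_free:
        raise ValueError("too few non-empty bins for a stable fit")
    sigma = np.sqrt(np.maximum(y, 1.0))

    irf = hist.irf
    full_t = hist.bin_centers

    def model_counts(params: np.ndarray) -> np.ndarray:
        if n_components == 1:
            comps = [DecayComponent(1.0, np.exp(params[0]))]
            log_a = params[1]
        else:
            f = params[2]
            comps = [
                DecayComponent(max(f, 1e-12), np.exp(params[0])),
                DecayComponent(max(1.0 - f, 1e-12), np.exp(params[1])),
            ]
            log_a = params[3]
        shape = _expected_shape(comps, full_t, irf)
        return np.exp(log_a) * shape[start:stop]

    def residuals(params: np.ndarray) -> np.ndarray:
        return (model_counts(params) - y) / sigma

    taus0 = _initial_taus(t, y, n_components)
    a0 = np.log(max(y.max(), 1.0))
    if n_components == 1:
        x0 = np.array([np.log(taus0[0]), a0])
        lb = np.array([np.log(1e-3), a0 - 30])
        ub = np.array([np.log(1e4), a0 + 30])
    else:
        x0 = np.array([np.log(taus0[0]), np.log(taus0[1]), 0.5, a0])
        lb = np.array([np.log(1e-3), np.log(1e-3), 1e-6, a0 - 30])
        ub = np.array([np.log(1e4), np.log(1e4), 1.0 - 1e-6, a0 + 30])

    res = least_squares(residuals, x0, bounds=(lb, ub), method="trf", xtol=1e-12)
    if not res.success:
        raise FitFailureError(f"decay fit did not converge: {res.message}", res.x)

    if n_components == 1:
        comps = [DecayComponent(1.0, float(np.exp(res.x[0])))]
        scale = float(np.exp(res.x[1]))
    else:
        f = float(np.clip(res.x[2], 1e-12, 1 - 1e-12))
        comps = [
            DecayComponent(f, float(np.exp(res.x[0]))),
            DecayComponent(1.0 - f, float(np.exp(res.x[1]))),
        ]
        scale = float(np.exp(res.x[3]))
    comps.sort(key=lambda c: c.tau, reverse=True)
    dof = max(len(y) - len(res.x), 1)
    chi2 = float(np.sum(res.fun**2) / dof)
    return DecayFit(
        components=comps,
        chi2=chi2,
        mean_tau=mean_lifetime(comps),
        n_components=n_components,
        scale=scale,
        window=(start, stop),
        success=True,
        message=str(res.message),
    )


def select_model(
    hist: DecayHistogram,
    max_components: int = 2,
    chi2_improvement_threshold: float = 0.10,
) -> tuple[int, dict[int, DecayFit]]:
    """Pick the number of exponential components by reduced-chi2 improvement.

    Fits 1..max_components and accepts each larger model only when it
    improves the reduced chi-square by more than the relative threshold
    (default 10%).  Returns the chosen order and all fits.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    fits: dict[int, DecayFit] = {}
    chosen = 1
    fits[1] = fit_decay(hist, 1)
    for n in range(2, max_components + 1):
        fits[n] = fit_decay(hist, n)
        prev = fits[chosen].chi2
        if prev > 0 and (prev - fits[n].chi2) / prev > chi2_improvement_threshold:
            chosen = n
    return chosen, fits
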