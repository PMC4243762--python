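"""Temperature scans and insertion kinetics.

Melting-transition detection fits a descending Boltzmann sigmoid to GP(T)
or r(T) series:

    v(T) = lower + (upper - lower) / (1 + exp((T - Tm)/w))

so v -> upper below the transition and -> lower above it; Tm is the
midpoint (melting temperature, deg C) and w the transition width.

Probe-insertion kinetics into vesicles follow a one-site binding hyperbola
through the origin, I(t) = Imax * t / (t_half + t), whose parameter t_half
is the time at which half the fluorophores have inserted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ThermalScan",
    "TransitionFit",
    "KineticTrace",
    "InsertionFit",
    "boltzmann",
    "fit_transition",
    "one_site_binding",
    "fit_insertion",
]


@dataclass
class ThermalScan:
    """A GP or anisotropy series over an ascending temperature grid (deg C)."""

    temperatures: np.ndarray
    values: np.ndarray
    quantity: str = "GP"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.size < 6:
            raise ValueError("a thermal scan needs at least 6 points")
        if self.temperatures.shape != self.values.shape:
            raise ValueError("temperatures and values must have equal length")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly ascending")
        if self.quantity not in ("GP", "anisotropy"):
            raise ValueError("quantity must be 'GP' or 'anisotropy'")


@dataclass
class TransitionFit:
    """Fitted melting transition; detected=False means no credible transition."""

    tm: float
    width: float
    upper_plateau: float
    lower_plateau: float
    detected: bool
    rmse: float
    message: str = ""


@dataclass
class KineticTrace:
    """Fluorescence intensity vs time (minutes) after probe injection."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.size < 5:
            raise ValueError("a kinetic trace needs at least 5 points")
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")


@dataclass
class InsertionFit:
    """One-site binding fit: plateau intensity and half-insertion time (min)."""

    imax: float
    t_half: float
    imax_stderr: float
    t_half_stderr: float
    rmse: float
    poorly_constrained: bool

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValueError("t_half must be positive")


def boltzmann(t, tm, width, upper, lower):
    """Descending Boltzmann sigmoid in temperature."""
    z = np.clip((np.asarray(t) - tm) / width, -500.0, 500.0)
    return lower + (upper - lower) / (1.0 + np.exp(z))


def fit_transition(scan: ThermalScan) -> TransitionFit:
    """Fit a descending Boltzmann sigmoid to a thermal scan.

    A transition is 'detected' only when (i) the fitted amplitude exceeds
    three times the residual RMSE, (ii) Tm lies strictly inside the scanned
    range, and (iii) the fitted width is at least half the grid step —
    a narrower "transition" falls between measured temperatures and is a
    noise artifact, not a resolved melting event.  Non-convergence returns
    detected=False with diagnostics rather than raising, since flat scans
    are an expected input.
    """
    t, v = scan.temperatures, scan.values
    upper0 = float(v[:3].mean())
    lower0 = float(v[-3:].mean())
    slopes = np.diff(v) / np.diff(t)
    tm0 = float(t[:-1][np.argmin(slopes)] + np.diff(t)[np.argmin(slopes)] / 2.0)
    width0 = max((t[-1] - t[0]) / 20.0, 0.5)
    try:
        popt, _ = curve_fit(
            boltzmann,
            t,
            v,
            p0=[tm0, width0, upper0, lower0],
            bounds=([t[0] - 50, 1e-3, -np.inf, -np.inf], [t[-1] + 50, 100, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        resid = v - v.mean()
        return TransitionFit(
            tm=float("nan"),
            width=float("nan"),
            upper_plateau=upper0,
            lower_plateau=lower0,
            detected=False,
            rmse=float(np.sqrt(np.mean(resid**2))),
            message=f"fit failed: {exc}",
        )
    tm, width, upper, lower = (float(x) for x in popt)
    resid = v - boltzmann(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    amplitude = upper - lower
    interior = t[0] < tm < t[-1]
    resolved = width >= 0.5 * float(np.median(np.diff(t)))
    detected = bool(amplitude > 3.0 * rmse and amplitude > 0 and interior and resolved)
    return TransitionFit(
        tm=tm,
        width=width,
        upper_plateau=upper,
        lower_plateau=lower,
        detected=detected,
        rmse=rmse,
    )


def one_site_binding(t, imax, t_half):
    """Rectangular hyperbola through the origin, I(t_half) = Imax/2."""
    t = np.asarray(t, dtype=float)
    return imax * t / (t_half + t)


def fit_insertion(trace: KineticTrace) -> InsertionFit:
    """Fit one-site binding insertion kinetics.

    Raises on a monotonically decreasing trace (no insertion signal).
    The fit is flagged poorly_constrained when the relative standard error
    of t_half exceeds 50% — typically because the trace samples only the
    plateau, far beyond the half-rise.
    """
    t, y = trace.times, trace.intensities
    overall_slope = np.polyfit(t, y, 1)[0]
    if overall_slope < 0 and np.all(np.diff(y) <= 0):
        raise RuntimeError("monotonically decreasing trace: no insertion to fit")
    imax0 = float(y.max())
    half = imax0 / 2.0
    above = np.nonzero(y >= half)[0]
    t_half0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else max(t[-1] / 4, 1e-3)
    popt, pcov = curve_fit(
        one_site_binding,
        t,
        y,
        p0=[imax0, t_half0],
        bounds=([0, 1e-9], [np.inf, np.inf]),
        maxfev=20000,
    )
    imax, t_half = (float(x) for x in popt)
    perr = np.sqrt(np.diag(pcov))
    resid = y - one_site_binding(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    rel_err = float(perr[1]) / t_half if t_half > 0 else np.inf
    return InsertionFit(
        imax=imax,
        t_half=t_half,
        imax_stderr=float(perr[0]),
        t_half_stderr=float(perr[1]),
        rmse=rmse,
        poorly_constrained=bool(not np.isfinite(rel_err) or rel_err > 0.5),
    )
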