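"""Steady-state fluorescence anisotropy and rotational relaxation.

Anisotropy is computed from the four polarizer-combination intensities with
the detection-arm bias corrected by the G-factor:

    r = (Ivv - G*Ivh) / (Ivv + 2*G*Ivh),     G = Ihv / Ihh

Subscripts: first letter = excitation polarizer, second = emission polarizer
(v vertical, h horizontal).  The rotational relaxation time follows from the
Perrin-Weber relation r0/r = 1 + tau/theta, with r0 the fundamental
(frozen-rotor) anisotropy and tau the (mean) fluorescence lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PolarizedIntensities",
    "AnisotropyResult",
    "g_factor",
    "steady_state_anisotropy",
    "anisotropy_result",
    "rotational_relaxation_time",
]

#: Theoretical one-photon limit for collinear absorption/emission dipoles.
DEFAULT_R0 = 0.4

#: Anisotropies outside this range are mathematically possible but flag a
#: measurement problem (scatter, misaligned polarizers).
PHYSICAL_RANGE = (-0.2, 0.4)


@dataclass(frozen=True)
class PolarizedIntensities:
    """The four polarizer-combination intensities (all non-negative)."""

    ivv: float
    ivh: float
    ihv: float
    ihh: float

    def __post_init__(self) -> None:
        for name in ("ivv", "ivh", "ihv", "ihh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class AnisotropyResult:
    g: float
    r: float
    in_physical_range: bool


def g_factor(ihv: float, ihh: float) -> float:
    """Detection-arm polarization correction G = Ihv/Ihh."""
    if ihh <= 0:
        raise ZeroDivisionError("Ihh must be positive to compute the G-factor")
    if ihv < 0:
        raise ValueError("Ihv must be non-negative")
    return ihv / ihh


def steady_state_anisotropy(p: PolarizedIntensities, g: float | None = None) -> float:
    """G-corrected steady-state anisotropy r = (Ivv - G Ivh)/(Ivv + 2 G Ivh).

    When g is not given it is computed from the horizontal-excitation pair.
    """
    if g is None:
        g = g_factor(p.ihv, p.ihh)
    denom = p.ivv + 2.0 * g * p.ivh
    if denom <= 0:
        raise ZeroDivisionError("anisotropy undefined: Ivv + 2 G Ivh is zero")
    return (p.ivv - g * p.ivh) / denom


def anisotropy_result(p: PolarizedIntensities, g: float | None = None) -> AnisotropyResult:
    """Anisotropy with the G-factor used and a physical-range flag."""
    g_val = g_factor(p.ihv, p.ihh) if g is None else g
    r = steady_state_anisotropy(p, g_val)
    lo, hi = PHYSICAL_RANGE
    return AnisotropyResult(g=g_val, r=r, in_physical_range=lo <= r <= hi)


def rotational_relaxation_time(r: float, tau: float, r0: float = DEFAULT_R0) -> float:
    """Perrin-Weber rotational relaxation time theta = tau * r / (r0 - r), ns.

    Larger theta means slower rotation, i.e. a more ordered/viscous probe
    environment.  tau should be the intensity-weighted mean fluorescence
    lifetime of the same sample.
    """
    if tau <= 0:
        raise ValueError("lifetime must be positive")
    if r <= 0:
        raise ValueError("anisotropy must be positive for a finite relaxation time")
    if r >= r0:
        raise ValueError("immobile limit: r >= r0 gives an infinite relaxation time")
    return tau * r / (r0 - r)
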