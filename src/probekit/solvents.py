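"""Solvent polarity models.

Dioxane/water dielectric mixing (linear in molar fraction), the
Lippert-Mataga orientational polarizability

    df = (eps - 1)/(2 eps + 1) - (n^2 - 1)/(2 n^2 + 1)

Stokes shifts in wavenumbers, and the Lippert plot regression of Stokes
shift on df.  A linear Lippert plot with a common slope across probes means
the probes share the same sensitivity to solvent polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SolventSpec",
    "LippertPoint",
    "LippertFit",
    "SOLVENTS",
    "DIOXANE_EPSILON",
    "WATER_EPSILON",
    "mixture_dielectric",
    "mole_fraction_for_epsilon",
    "stokes_shift_cm",
    "orientational_polarizability",
    "lippert_fit",
]

#: Dielectric constants of the mixing endpoints at 20 deg C.
DIOXANE_EPSILON = 2.2
WATER_EPSILON = 80.1

_CLASSES = ("nonpolar", "polar-aprotic", "polar-protic")


@dataclass(frozen=True)
class SolventSpec:
    """A solvent: dielectric constant, refractive index and polarity class."""

    name: str
    epsilon: float
    n: float
    solvent_class: str

    def __post_init__(self) -> None:
        if self.epsilon < 1:
            raise ValueError("dielectric constant must be >= 1")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.solvent_class not in _CLASSES:
            raise ValueError(f"solvent_class must be one of {_CLASSES}")

    @property
    def protic(self) -> bool:
        return self.solvent_class == "polar-protic"


# Dielectric constants at 20 deg C; refractive indices (n_D20) from standard
# physical-chemistry tables.
SOLVENTS: dict[str, SolventSpec] = {
    s.name: s
    for s in [
        SolventSpec("chloroform", 4.8, 1.446, "nonpolar"),
        SolventSpec("dichloromethane", 9.1, 1.424, "polar-aprotic"),
        SolventSpec("acetone", 21.0, 1.359, "polar-aprotic"),
        SolventSpec("acetonitrile", 37.5, 1.344, "polar-aprotic"),
        SolventSpec("dimethylformamide", 38.0, 1.430, "polar-aprotic"),
        SolventSpec("ethanol", 24.6, 1.361, "polar-protic"),
        SolventSpec("methanol", 33.0, 1.328, "polar-protic"),
        SolventSpec("dioxane", DIOXANE_EPSILON, 1.422, "nonpolar"),
        SolventSpec("water", WATER_EPSILON, 1.333, "polar-protic"),
    ]
}


def mixture_dielectric(
    x_dioxane: float,
    eps_nonpolar: float = DIOXANE_EPSILON,
    eps_polar: float = WATER_EPSILON,
) -> float:
    """Dielectric constant of a dioxane/water mixture, linear in molar fraction."""
    if not 0.0 <= x_dioxane <= 1.0:
        raise ValueError("molar fraction must lie in [0, 1]")
    return x_dioxane * eps_nonpolar + (1.0 - x_dioxane) * eps_polar


def mole_fraction_for_epsilon(
    target: float,
    eps_nonpolar: float = DIOXANE_EPSILON,
    eps_polar: float = WATER_EPSILON,
) -> float:
    """Dioxane molar fraction giving a target dielectric constant (exact inverse)."""
    lo, hi = min(eps_nonpolar, eps_polar), max(eps_nonpolar, eps_polar)
    if not lo <= target <= hi:
        raise ValueError(f"target epsilon must lie in [{lo}, {hi}]")
    return (target - eps_polar) / (eps_nonpolar - eps_polar)


def stokes_shift_cm(lambda_abs: float, lambda_em: float) -> float:
    """Stokes shift 10^7 (1/l_abs - 1/l_em) in cm^-1, wavelengths in nm."""
    if lambda_abs <= 0 or lambda_em <= 0:
        raise ValueError("wavelengths must be positive")
    return 1e7 * (1.0 / lambda_abs - 1.0 / lambda_em)


def orientational_polarizability(epsilon: float, n: float) -> float:
    """Lippert-Mataga df; zero when eps = n^2 (no permanent-dipole reorientation)."""
    if epsilon < 1:
        raise ValueError("dielectric constant must be >= 1")
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    return (epsilon - 1.0) / (2.0 * epsilon + 1.0) - (n**2 - 1.0) / (2.0 * n**2 + 1.0)


@dataclass(frozen=True)
class LippertPoint:
    """One solvent on the Lippert plot: (df, Stokes shift in cm^-1)."""

    delta_f: float
    stokes_shift: float


@dataclass(frozen=True)
class LippertFit:
    slope: float  # cm^-1 per unit df
    intercept: float  # cm^-1
    r_squared: float
    n: int


def lippert_fit(points: list[LippertPoint]) -> LippertFit:
    """OLS Lippert regression of Stokes shift on orientational polarizability."""
    if len(points) < 3:
        raise ValueError("need at least 3 Lippert points")
    x = np.array([p.delta_f for p in points])
    y = np.array([p.stokes_shift for p in points])
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all points share one delta_f")
    res = stats.linregress(x, y)
    return LippertFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(points),
    )
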