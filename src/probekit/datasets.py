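"""Published characterization measurements for the laurdan probe family.

Three reference tables, transcribed from the printed characterization of
laurdan, M-laurdan, MoC-laurdan and C-laurdan:

* ``PROBES`` — identity, molar extinction coefficient at 360 nm, quantum
  yield and printed brightness (all measured in chloroform).
* ``SOLVENT_PHOTOPHYSICS`` — quantum yield, lifetime, de-excitation rate
  constants and GP for each probe in seven pure solvents.
* ``LIPID_LIFETIMES`` — one/two-component TCSPC fits (chi2, amplitudes in
  percent, lifetimes in ns, intensity-weighted mean lifetime) for each probe
  in twelve lipid environments at 20 and 50 degC.

These tables are inputs for reproduction checks: e.g. recomputing kr/knr
from (phi, tau) or the mean lifetime from (alpha_i, tau_i) must give back
the printed values to the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass

from .decay import DecayComponent
from .photophysics import ProbeRecord

__all__ = [
    "PROBES",
    "PRINTED_BRIGHTNESS",
    "SOLVENT_PHOTOPHYSICS",
    "SolventPhotophysicsRow",
    "LIPID_LIFETIMES",
    "LipidLifetimeRow",
]

PROBES: dict[str, ProbeRecord] = {
    "laurdan": ProbeRecord("laurdan", "C24H35NO", 353.55, 19500.0, 0.61),
    "M-laurdan": ProbeRecord("M-laurdan", "C23H33NO", 339.52, 14100.0, 0.58),
    "MoC-laurdan": ProbeRecord("MoC-laurdan", "C26H37NO3", 411.59, 11100.0, 0.48),
    "C-laurdan": ProbeRecord("C-laurdan", "C25H35NO3", 397.56, 12200.0, 0.56),
}

#: Printed brightness (epsilon * phi in chloroform, rounded to nearest 100).
PRINTED_BRIGHTNESS: dict[str, int] = {
    "laurdan": 11900,
    "M-laurdan": 8200,
    "MoC-laurdan": 5300,
    "C-laurdan": 6800,
}


@dataclass(frozen=True)
class SolventPhotophysicsRow:
    probe: str
    solvent: str
    epsilon: float  # solvent dielectric constant
    phi: float  # quantum yield
    chi2: float  # goodness of the lifetime fit
    tau: float  # ns
    kr: float  # printed radiative rate, ns^-1
    knr: float  # printed non-radiative rate, ns^-1
    gp: float


# fmt: off
SOLVENT_PHOTOPHYSICS: list[SolventPhotophysicsRow] = [SolventPhotophysicsRow(*row) for row in [
    # laurdan
    ("laurdan", "chloroform",        4.8, 0.61, 1.53, 2.78, 0.22, 0.14,  0.48),
    ("laurdan", "dichloromethane",   9.1, 0.67, 1.99, 2.97, 0.23, 0.11,  0.48),
    ("laurdan", "acetone",          21.0, 0.61, 1.53, 2.94, 0.21, 0.13,  0.40),
    ("laurdan", "acetonitrile",     37.5, 0.63, 1.82, 3.11, 0.20, 0.12,  0.16),
    ("laurdan", "dimethylformamide",38.0, 0.67, 1.81, 3.19, 0.21, 0.10,  0.04),
    ("laurdan", "ethanol",          24.6, 0.68, 1.81, 3.05, 0.22, 0.10, -0.72),
    ("laurdan", "methanol",         33.0, 0.53, 1.80, 2.64, 0.20, 0.18, -0.85),
    # MoC-laurdan
    ("MoC-laurdan", "chloroform",        4.8, 0.48, 3.03, 2.30, 0.21, 0.23,  0.72),
    ("MoC-laurdan", "dichloromethane",   9.1, 0.45, 4.62, 2.38, 0.19, 0.23,  0.73),
    ("MoC-laurdan", "acetone",          21.0, 0.41, 1.81, 2.36, 0.17, 0.25,  0.71),
    ("MoC-laurdan", "acetonitrile",     37.5, 0.48, 1.50, 2.83, 0.17, 0.18,  0.61),
    ("MoC-laurdan", "dimethylformamide",38.0, 0.53, 1.46, 3.03, 0.17, 0.16,  0.54),
    ("MoC-laurdan", "ethanol",          24.6, 0.45, 1.77, 3.10, 0.15, 0.18, -0.20),
    ("MoC-laurdan", "methanol",         33.0, 0.40, 1.93, 3.05, 0.13, 0.20, -0.44),
    # M-laurdan
    ("M-laurdan", "chloroform",        4.8, 0.58, 6.74, 1.95, 0.30, 0.22,  0.68),
    ("M-laurdan", "dichloromethane",   9.1, 0.48, 2.70, 1.95, 0.25, 0.27,  0.74),
    ("M-laurdan", "acetone",          21.0, 0.46, 4.99, 2.06, 0.22, 0.26,  0.70),
    ("M-laurdan", "acetonitrile",     37.5, 0.55, 1.63, 2.66, 0.21, 0.17,  0.60),
    ("M-laurdan", "dimethylformamide",38.0, 0.62, 1.68, 2.83, 0.22, 0.13,  0.51),
    ("M-laurdan", "ethanol",          24.6, 0.55, 2.48, 2.85, 0.19, 0.16, -0.20),
    ("M-laurdan", "methanol",         33.0, 0.38, 2.38, 2.38, 0.16, 0.26, -0.48),
    # C-laurdan
    ("C-laurdan", "chloroform",        4.8, 0.56, 2.50, 2.46, 0.23, 0.18,  0.67),
    ("C-laurdan", "dichloromethane",   9.1, 0.60, 1.87, 2.36, 0.25, 0.17,  0.72),
    ("C-laurdan", "acetone",          21.0, 0.13, 1.87, 2.29, 0.05, 0.38,  0.57),
    ("C-laurdan", "acetonitrile",     37.5, 0.10, 2.43, 2.27, 0.04, 0.40,  0.43),
    ("C-laurdan", "dimethylformamide",38.0, 0.07, 2.31, 2.52, 0.03, 0.37,  0.32),
    ("C-laurdan", "ethanol",          24.6, 0.17, 2.72, 1.46, 0.12, 0.57, -0.61),
    ("C-laurdan", "methanol",         33.0, 0.16, 4.45, 1.26, 0.13, 0.67, -0.74),
]]
# fmt: on


@dataclass(frozen=True)
class LipidLifetimeRow:
    """One TCSPC fit: amplitudes as fractions; alpha2/tau2 None for 1-exp fits."""

    probe: str
    sample: str
    temperature_c: float
    chi2: float
    alpha1: float
    tau1: float
    alpha2: float | None
    tau2: float | None
    mean_tau: float  # printed intensity-weighted mean lifetime, ns

    @property
    def two_component(self) -> bool:
        return self.alpha2 is not None

    def components(self) -> list[DecayComponent]:
        comps = [DecayComponent(self.alpha1, self.tau1)]
        if self.two_component:
            comps.append(DecayComponent(self.alpha2, self.tau2))
        return comps


def _rows(probe: str, temp: float, entries) -> list[LipidLifetimeRow]:
    out = []
    for sample, chi2, a1, t1, a2, t2, mt in entries:
        out.append(
            LipidLifetimeRow(
                probe,
                sample,
                temp,
                chi2,
                a1 / 100.0,
                t1,
                None if a2 is None else a2 / 100.0,
                t2,
                mt,
            )
        )
    return out


# fmt: off
LIPID_LIFETIMES: list[LipidLifetimeRow] = (
    _rows("laurdan", 20.0, [
        ("DPPC",                  4.43,  56, 6.18,  44, 0.53, 5.82),
        ("PSM",                   1.29,  57, 4.96,  43, 2.50, 4.28),
        ("BSM",                   1.55,  67, 4.25,  33, 1.96, 3.82),
        ("DPPC/chol (6:4)",       4.53,  60, 5.75,  40, 0.61, 5.41),
        ("PSM/chol (2:1)",        3.31,  69, 5.58,  31, 0.61, 5.34),
        ("BSM/chol (2:1)",        1.50,  90, 4.73,  10, 2.52, 4.61),
        ("POPC/chol (2:1)",       1.45, 100, 4.35, None, None, 4.35),
        ("DOPC/BSM/chol (1:1:1)", 1.49,  94, 4.42,   6, 2.05, 4.36),
        ("DOPC/PSM/chol (1:1:1)", 1.73,  81, 4.43,  19, 0.70, 4.30),
        ("DOPC/chol (2:1)",       1.49, 100, 3.75, None, None, 3.75),
        ("DOPC",                  1.50,  79, 3.23,  21, 1.44, 3.04),
        ("POPC",                  2.69,  79, 3.28,  21, 0.43, 3.19),
    ])
    + _rows("laurdan", 50.0, [
        ("DPPC",                  4.26, 100, 2.89, None, None, 2.89),
        ("PSM",                   1.84,  78, 3.15,  22, 1.06, 2.97),
        ("BSM",                   2.15,  68, 2.79,  32, 1.03, 2.53),
        ("DPPC/chol (6:4)",       2.03, 100, 4.03, None, None, 4.03),
        ("PSM/chol (2:1)",        1.56, 100, 3.68, None, None, 3.68),
        ("BSM/chol (2:1)",        1.57, 100, 3.20, None, None, 3.20),
        ("POPC/chol (2:1)",       1.89, 100, 2.79, None, None, 2.79),
        ("DOPC/BSM/chol (1:1:1)", 1.63,  38, 3.09,  62, 2.92, 2.99),
        ("DOPC/PSM/chol (1:1:1)", 1.62, 100, 2.88, None, None, 2.88),
        ("DOPC/chol (2:1)",       1.66, 100, 2.48, None, None, 2.48),
        ("DOPC",                  1.84,  65, 2.81,  35, 0.83, 2.54),
        ("POPC",                  4.04, 100, 2.49, None, None, 2.49),
    ])
    + _rows("M-laurdan", 20.0, [
        ("DPPC",                  1.75,  81, 5.05,  19, 1.05, 4.86),
        ("PSM",                   1.36,  58, 4.69,  42, 2.14, 4.06),
        ("BSM",                   3.11,  28, 5.09,  72, 2.97, 3.81),
        ("DPPC/chol (6:4)",       5.17,  60, 4.80,  40, 0.67, 4.45),
        ("PSM/chol (2:1)",        2.66,  68, 4.55,  32, 0.51, 4.36),
        ("BSM/chol (2:1)",        1.29,  61, 4.83,  39, 2.90, 4.29),
        ("POPC/chol (2:1)",       1.50, 100, 3.98, None, None, 3.98),
        ("DOPC/BSM/chol (1:1:1)", 1.43,  61, 4.19,  39, 3.83, 4.06),
        ("DOPC/PSM/chol (1:1:1)", 2.50,  82, 4.06,  18, 2.12, 3.85),
        ("DOPC/chol (2:1)",       1.49, 100, 3.81, None, None, 3.81),
        ("DOPC",                  1.76,  92, 3.40,   8, 1.89, 3.33),
        ("POPC",                  5.99,  64, 3.42,  36, 0.64, 3.16),
    ])
    + _rows("M-laurdan", 50.0, [
        ("DPPC",                  1.31, 100, 3.28, None, None, 3.28),
        ("PSM",                   1.64,  82, 3.23,  18, 1.67, 3.07),
        ("BSM",                   3.07,  83, 2.82,  17, 1.86, 2.70),
        ("DPPC/chol (6:4)",       1.42, 100, 3.83, None, None, 3.83),
        ("PSM/chol (2:1)",        1.67, 100, 3.67, None, None, 3.67),
        ("BSM/chol (2:1)",        1.43, 100, 3.31, None, None, 3.31),
        ("POPC/chol (2:1)",       2.12, 100, 3.06, None, None, 3.06),
        ("DOPC/BSM/chol (1:1:1)", 1.65, 100, 3.29, None, None, 3.29),
        ("DOPC/PSM/chol (1:1:1)", 1.63, 100, 3.15, None, None, 3.15),
        ("DOPC/chol (2:1)",       1.41,  59, 3.33,  41, 2.78, 3.12),
        ("DOPC",                  1.41,  65, 3.37,  35, 2.01, 3.04),
        ("POPC",                  1.64,  75, 3.11,  25, 1.14, 2.90),
    ])
    + _rows("MoC-laurdan", 20.0, [
        ("DPPC",                  1.49,  85, 5.46,  15, 2.29, 5.24),
        ("PSM",                   1.50,  42, 3.46,  58, 1.82, 2.77),
        ("BSM",                   1.84,  18, 3.29,  82, 1.22, 2.00),
        ("DPPC/chol (6:4)",       1.37,  85, 4.91,  15, 1.62, 4.73),
        ("PSM/chol (2:1)",        2.25,  43, 5.09,  57, 1.90, 4.03),
        ("BSM/chol (2:1)",        1.33,  41, 4.12,  59, 2.04, 3.26),
        ("POPC/chol (2:1)",       1.59,  80, 3.39,  20, 1.22, 3.21),
        ("DOPC/BSM/chol (1:1:1)", 1.37,  54, 3.74,  46, 1.78, 3.17),
        ("DOPC/PSM/chol (1:1:1)", 2.12,  62, 3.59,  38, 1.50, 3.16),
        ("DOPC/chol (2:1)",       1.55,  73, 3.41,  27, 1.89, 3.15),
        ("DOPC",                  1.53,  71, 3.47,  29, 1.44, 3.17),
        ("POPC",                  1.88,  82, 3.19,  18, 1.56, 3.03),
    ])
    + _rows("MoC-laurdan", 50.0, [
        ("DPPC",                  1.38,  18, 4.89,  82, 2.61, 3.28),
        ("PSM",                   1.72,  68, 3.00,  32, 1.06, 2.73),
        ("BSM",                   2.54,  34, 2.44,  66, 0.87, 1.80),
        ("DPPC/chol (6:4)",       1.38,  29, 4.29,  71, 2.79, 3.38),
        ("PSM/chol (2:1)",        1.56,  38, 4.10,  62, 1.81, 3.14),
        ("BSM/chol (2:1)",        1.54,  47, 3.36,  53, 1.43, 2.73),
        ("POPC/chol (2:1)",       2.01,  60, 2.96,  40, 1.54, 2.60),
        ("DOPC/BSM/chol (1:1:1)", 1.75,  51, 3.18,  49, 1.19, 2.66),
        ("DOPC/PSM/chol (1:1:1)", 1.77,  53, 3.26,  47, 1.93, 2.81),
        ("DOPC/chol (2:1)",       1.95,  72, 3.04,  28, 1.69, 2.80),
        ("DOPC",                  1.70,  79, 3.25,  21, 1.50, 3.06),
        ("POPC",                  2.04,  70, 3.02,  30, 1.32, 2.76),
    ])
    + _rows("C-laurdan", 20.0, [
        ("DPPC",                  1.34,  94, 5.08,   6, 1.35, 5.02),
        ("PSM",                   1.48,  42, 3.64,  58, 1.59, 2.87),
        ("BSM",                   1.62,  42, 3.77,  58, 1.61, 2.96),
        ("DPPC/chol (6:4)",       1.66,  85, 4.83,  15, 1.12, 4.69),
        ("PSM/chol (2:1)",        4.04,  59, 5.39,  41, 0.61, 5.05),
        ("BSM/chol (2:1)",        1.34,  83, 4.65,  17, 2.49, 4.44),
        ("POPC/chol (2:1)",       1.63,  90, 3.62,  10, 1.66, 3.53),
        ("DOPC/BSM/chol (1:1:1)", 1.65,  62, 3.81,  38, 1.90, 3.36),
        ("DOPC/PSM/chol (1:1:1)", 2.51,  58, 4.30,  42, 2.01, 3.72),
        ("DOPC/chol (2:1)",       1.50,  60, 3.00,  40, 1.27, 2.62),
        ("DOPC",                  2.30,  47, 2.60,  53, 1.34, 2.13),
        ("POPC",                  2.17,  63, 2.54,  37, 1.48, 2.26),
    ])
    + _rows("C-laurdan", 50.0, [
        ("DPPC",                  2.39,  26, 2.90,  74, 1.34, 2.01),
        ("PSM",                   1.83,  24, 2.80,  76, 1.20, 1.87),
        ("BSM",                   2.35,  35, 2.46,  65, 0.93, 1.83),
        ("DPPC/chol (6:4)",       1.67,  73, 3.07,  27, 2.33, 2.91),
        ("PSM/chol (2:1)",        1.67, 100, 3.22, None, None, 3.22),
        ("BSM/chol (2:1)",        1.47,  75, 2.77,  25, 1.39, 2.57),
        ("POPC/chol (2:1)",       1.75,  35, 2.62,  65, 1.44, 2.02),
        ("DOPC/BSM/chol (1:1:1)", 1.50,  17, 3.34,  83, 1.59, 2.12),
        ("DOPC/PSM/chol (1:1:1)", 2.15,  46, 2.65,  54, 1.27, 2.16),
        ("DOPC/chol (2:1)",       1.99,  22, 2.53,  78, 1.16, 1.69),
        ("DOPC",                  2.35,  16, 2.95,  84, 1.01, 1.70),
        ("POPC",                  2.70,  16, 2.65,  84, 1.04, 1.56),
    ])
)
# fmt: on
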