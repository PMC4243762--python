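"""File formats and the end-to-end pipeline runner.

Interchange conventions (fixed, no unit auto-detection):

* tabular data is CSV; comment lines start with ``#`` and carry provenance
  (seed, thresholds) as ``# key: value`` pairs;
* spectra: columns ``wavelength_nm, intensity``;
* decays: columns ``time_ns, counts`` (optional ``irf_counts``);
* polarized intensities: columns ``ivv, ivh, ihv, ihh``;
* thermal scans / kinetic traces: two columns (temperature_c or time_min,
  value);
* image stacks: multi-page TIFF, one page per ascending channel center;
* fit reports: JSON.

Temperatures are degC, decay times ns, kinetic times minutes, wavelengths
nm, wavenumbers cm^-1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .imaging import GPMap, SpectralStack
from .photophysics import EmissionSpectrum
from .scans import KineticTrace, ThermalScan

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_decay_csv",
    "write_decay_csv",
    "read_polarized_csv",
    "read_scan_csv",
    "read_trace_csv",
    "read_stack_tiff",
    "write_stack_tiff",
    "write_gp_map",
    "write_json_report",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("probekit")


def _read_csv(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """CSV with '# key: value' comment header."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return df, meta


def _write_csv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# probekit: {__version__}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_spectrum_csv(path) -> EmissionSpectrum:
    """Read a wavelength/intensity spectrum.

    Descending wavelength order is tolerated (sorted, with a warning);
    duplicate wavelengths or negative intensities are parse errors naming
    the offending row.
    """
    df, meta = _read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, intensity)")
    lam = df.iloc[:, 0].to_numpy(dtype=float)
    inten = df.iloc[:, 1].to_numpy(dtype=float)
    neg = np.nonzero(inten < 0)[0]
    if neg.size:
        raise ValueError(f"{path}: negative intensity at data row {neg[0]}")
    if np.any(np.diff(lam) < 0):
        logger.warning("%s: wavelengths not ascending; sorting", path)
        order = np.argsort(lam)
        lam, inten = lam[order], inten[order]
    dup = np.nonzero(np.diff(lam) == 0)[0]
    if dup.size:
        raise ValueError(f"{path}: duplicate wavelength at data row {dup[0] + 1}")
    return EmissionSpectrum(
        wavelengths=lam,
        intensities=inten,
        excitation=float(meta.get("excitation_nm", 360.0)),
        sample_meta=meta.get("sample", ""),
    )


def write_spectrum_csv(path, spec: EmissionSpectrum, meta: dict | None = None) -> None:
    header = {"excitation_nm": spec.excitation, "sample": spec.sample_meta}
    header.update(meta or {})
    _write_csv(
        path,
        pd.DataFrame({"wavelength_nm": spec.wavelengths, "intensity": spec.intensities}),
        header,
    )


def read_decay_csv(path):
    """Read a TCSPC histogram (time_ns, counts[, irf_counts])."""
    from .decay import DecayHistogram

    df, _ = _read_csv(path)
    irf = df["irf_counts"].to_numpy(dtype=float) if "irf_counts" in df.columns else None
    return DecayHistogram(
        bin_centers=df.iloc[:, 0].to_numpy(dtype=float),
        counts=df.iloc[:, 1].to_numpy(dtype=float),
        irf=irf,
    )


def write_decay_csv(path, hist, meta: dict | None = None) -> None:
    data = {"time_ns": hist.bin_centers, "counts": hist.counts}
    if hist.irf is not None:
        data["irf_counts"] = hist.irf
    _write_csv(path, pd.DataFrame(data), meta)


def read_polarized_csv(path):
    """Read polarized intensities, one (ivv, ivh, ihv, ihh) row per sample."""
    from .anisotropy import PolarizedIntensities

    df, _ = _read_csv(path)
    return [
        PolarizedIntensities(row.ivv, row.ivh, row.ihv, row.ihh)
        for row in df.itertuples()
    ]


def read_scan_csv(path, quantity: str = "GP") -> ThermalScan:
    df, meta = _read_csv(path)
    return ThermalScan(
        temperatures=df.iloc[:, 0].to_numpy(dtype=float),
        values=df.iloc[:, 1].to_numpy(dtype=float),
        quantity=meta.get("quantity", quantity),
    )


def read_trace_csv(path) -> KineticTrace:
    df, _ = _read_csv(path)
    return KineticTrace(
        times=df.iloc[:, 0].to_numpy(dtype=float),
        intensities=df.iloc[:, 1].to_numpy(dtype=float),
    )


def read_stack_tiff(path, channel_centers) -> SpectralStack:
    """Read a multi-page TIFF as a spectral stack (one page per channel)."""
    pages = tifffile.imread(path)
    pages = np.atleast_3d(pages)
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page 2-D TIFF")
    centers = np.asarray(channel_centers, dtype=float)
    if pages.shape[0] != centers.size:
        raise ValueError(
            f"{path}: {pages.shape[0]} pages but {centers.size} channel centers"
        )
    return SpectralStack(channel_centers=centers, pixels=pages.astype(float))


def write_stack_tiff(path, stack: SpectralStack) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.pixels.astype(np.float32))


def write_gp_map(path, gpmap: GPMap) -> None:
    """GP map as 32-bit float TIFF; masked pixels are NaN."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, gpmap.gp.astype(np.float32))


def write_json_report(path, payload: dict, seed: int | None = None) -> None:
    out = {"probekit_version": __version__, "seed": seed}
    out.update(payload)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    raise TypeError(f"not JSON serializable: {type(obj)}")


ALL_STAGES = ("solvents", "decay", "anisotropy", "scans", "imaging")


@dataclass
class RunConfig:
    """Configuration for the synthetic end-to-end study.

    With no input paths, every stage runs on synthetic data generated from
    `seed`; identical config + seed gives byte-identical outputs.
    """

    out_dir: str = "probekit_run"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    gp_channels: tuple[float, float] = (440.0, 490.0)
    mask_min_intensity: float = 100.0
    chi2_improvement: float = 0.10
    r0: float = 0.4
    verbosity: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages of the synthetic characterization study.

    Produces per-stage JSON reports, a combined probe/solvent summary table
    (phi, tau components, <tau>, kr, knr, GP, r, theta) and a run log.
    Returns the summary payload.
    """
    from . import anisotropy as aniso
    from . import datasets, decay, imaging, photophysics, scans, solvents, synthetic

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {}

    if "solvents" in config.stages:
        rows = []
        for row in datasets.SOLVENT_PHOTOPHYSICS:
            kr, knr = photophysics.rate_constants(row.phi, row.tau)
            solvent = solvents.SOLVENTS[row.solvent]
            spec = synthetic.gen_spectrum(solvent, seed=int(rng.integers(2**31)))
            rows.append(
                {
                    "probe": row.probe,
                    "solvent": row.solvent,
                    "epsilon": row.epsilon,
                    "phi": row.phi,
                    "tau_ns": row.tau,
                    "kr_ns-1": kr,
                    "knr_ns-1": knr,
                    "gp_printed": row.gp,
                    "gp_synthetic": photophysics.gp_from_spectrum(spec),
                    "delta_f": solvents.orientational_polarizability(
                        solvent.epsilon, solvent.n
                    ),
                }
            )
        df = pd.DataFrame(rows)
        _write_csv(out / "solvent_summary.csv", df, {"seed": config.seed})
        report["solvents"] = {"n_rows": len(df)}

    if "decay" in config.stages:
        rows = []
        for table_row in datasets.LIPID_LIFETIMES:
            comps = table_row.components()
            rows.append(
                {
                    "probe": table_row.probe,
                    "sample": table_row.sample,
                    "temperature_c": table_row.temperature_c,
                    "alpha1": comps[0].alpha,
                    "tau1_ns": comps[0].tau,
                    "alpha2": comps[1].alpha if len(comps) > 1 else np.nan,
                    "tau2_ns": comps[1].tau if len(comps) > 1 else np.nan,
                    "mean_tau_ns": decay.mean_lifetime(comps),
                    "mean_tau_printed": table_row.mean_tau,
                }
            )
        df = pd.DataFrame(rows)
        _write_csv(out / "lifetime_summary.csv", df, {"seed": config.seed})
        # one simulate-and-fit round trip as a pipeline smoke check
        comps = [decay.DecayComponent(0.56, 6.18), decay.DecayComponent(0.44, 0.53)]
        hist = decay.simulate_decay(
            comps, total_counts=1_000_000, seed=int(rng.integers(2**31))
        )
        fit = decay.fit_decay(hist, 2)
        write_json_report(
            out / "decay_fit.json",
            {
                "components": [
                    {"alpha": c.alpha, "tau_ns": c.tau} for c in fit.components
                ],
                "chi2": fit.chi2,
                "mean_tau_ns": fit.mean_tau,
            },
            seed=config.seed,
        )
        report["decay"] = {"n_rows": len(df), "fit_chi2": fit.chi2}

    if "anisotropy" in config.stages:
        rows = []
        for r_true in (0.05, 0.15, 0.25, 0.35):
            p = synthetic.gen_polarized(r_true, 1e6, g_true=0.9)
            res = aniso.anisotropy_result(p)
            theta = aniso.rotational_relaxation_time(res.r, 3.0, config.r0)
            rows.append(
                {"r_true": r_true, "g": res.g, "r": res.r, "theta_ns": theta}
            )
        df = pd.DataFrame(rows)
        _write_csv(out / "anisotropy_summary.csv", df, {"seed": config.seed, "r0": config.r0})
        report["anisotropy"] = {"n_rows": len(df)}

    if "scans" in config.stages:
        scan = synthetic.gen_thermal_scan(seed=int(rng.integers(2**31)))
        tfit = scans.fit_transition(scan)
        trace = synthetic.gen_insertion_trace(
            noise_frac=0.05, seed=int(rng.integers(2**31))
        )
        ifit = scans.fit_insertion(trace)
        write_json_report(
            out / "scan_fits.json",
            {
                "transition": {
                    "tm_c": tfit.tm,
                    "width_c": tfit.width,
                    "detected": tfit.detected,
                },
                "insertion": {"imax": ifit.imax, "t_half_min": ifit.t_half},
            },
            seed=config.seed,
        )
        report["scans"] = {"tm_c": tfit.tm, "t_half_min": ifit.t_half}

    if "imaging" in config.stages:
        _, stack = synthetic.two_region_scene(seed=int(rng.integers(2**31)))
        gpm = imaging.gp_map(
            stack, *config.gp_channels, min_total_intensity=config.mask_min_intensity
        )
        hist = imaging.gp_histogram(gpm)
        write_stack_tiff(out / "scene_stack.tiff", stack)
        write_gp_map(out / "gp_map.tiff", gpm)
        _write_csv(
            out / "gp_histogram.csv",
            pd.DataFrame(
                {
                    "bin_center": 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:]),
                    "count": hist.counts,
                }
            ),
            {"seed": config.seed, "threshold": config.mask_min_intensity},
        )
        report["imaging"] = {
            "gp_mean": hist.mean,
            "gp_median": hist.median,
            "n_pixels": hist.n_pixels,
        }

    write_json_report(out / "run_report.json", report, seed=config.seed)
    if config.verbosity:
        logger.info("pipeline finished: stages=%s out=%s", config.stages, out)
    return report
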