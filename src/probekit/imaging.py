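"""Ratiometric GP imaging from multi-channel spectral stacks.

A two-photon spectral acquisition yields one image per 10-nm emission
channel (420-600 nm).  The per-pixel generalized polarization map is

    GP = (I440 - I490) / (I440 + I490)

computed on the two channels nearest 440 and 490 nm, with dim pixels
(total below an intensity threshold) masked out.  Image convention:
row-major, origin at the top-left, 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectralStack",
    "GPMap",
    "GPHistogram",
    "gp_map",
    "total_fluorescence",
    "gp_histogram",
]


class ChannelError(KeyError):
    """Requested emission channel is not present in the stack."""


@dataclass
class SpectralStack:
    """Per-channel pixel grids sharing one shape; centers in nm, ascending."""

    channel_centers: np.ndarray
    pixels: np.ndarray  # (n_channels, height, width)

    def __post_init__(self) -> None:
        self.channel_centers = np.asarray(self.channel_centers, dtype=float)
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.channel_centers.ndim != 1:
            raise ValueError("channel_centers must be 1-D")
        if np.unique(self.channel_centers).size != self.channel_centers.size:
            raise ValueError("channel centers must be unique")
        if not np.all(np.diff(self.channel_centers) > 0):
            raise ValueError("channel centers must be ascending")
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (n_channels, height, width)")
        if self.pixels.shape[0] != self.channel_centers.size:
            raise ValueError("one pixel grid per channel is required")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")

    def channel(self, center: float, tol: float = 1.0) -> np.ndarray:
        """The pixel grid for the channel nearest `center`, within tol nm."""
        idx = int(np.argmin(np.abs(self.channel_centers - center)))
        if abs(self.channel_centers[idx] - center) > tol:
            raise ChannelError(
                f"no channel within {tol} nm of {center} nm "
                f"(available: {self.channel_centers.tolist()})"
            )
        return self.pixels[idx]


@dataclass
class GPMap:
    """Per-pixel GP with a validity mask; masked-out pixels hold NaN."""

    gp: np.ndarray
    mask: np.ndarray  # True where the pixel is valid
    threshold: float

    def __post_init__(self) -> None:
        self.gp = np.asarray(self.gp, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.gp.shape != self.mask.shape:
            raise ValueError("gp and mask shapes must match")
        valid = self.gp[self.mask]
        if valid.size and (np.any(valid < -1) or np.any(valid > 1)):
            raise ValueError("unmasked GP values must lie in [-1, 1]")
        if np.any(np.isfinite(self.gp[~self.mask])):
            raise ValueError("masked-out pixels must carry no GP value")

    @property
    def values(self) -> np.ndarray:
        """Flat array of valid GP values."""
        return self.gp[self.mask]


def gp_map(
    stack: SpectralStack,
    ch_a: float = 440.0,
    ch_b: float = 490.0,
    min_total_intensity: float = 0.0,
) -> GPMap:
    """Per-pixel GP map from two emission channels.

    Pixels whose summed channel intensity falls below min_total_intensity
    (or is zero) are masked.  Pixelwise identical to the scalar GP formula.
    """
    i_a = stack.channel(ch_a)
    i_b = stack.channel(ch_b)
    total = i_a + i_b
    mask = total >= max(min_total_intensity, 0.0)
    mask &= total > 0  # GP undefined on fully dark pixels
    gp = np.full(total.shape, np.nan)
    np.divide(i_a - i_b, total, out=gp, where=mask)
    return GPMap(gp=gp, mask=mask, threshold=min_total_intensity)


def total_fluorescence(
    stack: SpectralStack, band: tuple[float, float] | None = None
) -> np.ndarray:
    """Per-pixel intensity summed over channels within `band` (inclusive, nm)."""
    if band is None:
        sel = np.ones_like(stack.channel_centers, dtype=bool)
    else:
        lo, hi = band
        sel = (stack.channel_centers >= lo) & (stack.channel_centers <= hi)
    if not np.any(sel):
        raise ValueError("band selects no channels")
    return stack.pixels[sel].sum(axis=0)


@dataclass
class GPHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    median: float
    mode: float  # center of the most occupied bin
    n_pixels: int


def gp_histogram(gpmap: GPMap, bins: int = 50) -> GPHistogram:
    """Distribution of valid GP pixels over [-1, 1] with summary statistics."""
    vals = gpmap.values
    if vals.size == 0:
        raise ValueError("fully masked map: no GP distribution to summarize")
    counts, edges = np.histogram(vals, bins=bins, range=(-1.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return GPHistogram(
        bin_edges=edges,
        counts=counts,
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        mode=float(centers[np.argmax(counts)]),
        n_pixels=int(vals.size),
    )
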