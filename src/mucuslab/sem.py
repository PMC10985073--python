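"""Cryo-SEM micrograph quantification of the mucus pore network.

Pores image dark against the brighter mucin walls. The pipeline crops the
instrument footer, smooths with a Gaussian filter (size 10 px), splits
pore/wall phases with a global Otsu threshold, converts 8-connected pore
components to µm² areas, and measures the wall density as the summed image
gradient magnitude normalized per µm² of image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import filters, measure

__all__ = [
    "Micrograph",
    "PoreStats",
    "load_micrograph",
    "preprocess",
    "segment_pores",
    "wall_density",
    "analyze_micrograph",
    "percent_change",
]

#: "Filter size of 10" realized as sigma = size/4 px with a radius-5 kernel.
GAUSS_KERNEL_SIZE = 10


@dataclass
class Micrograph:
    """Grayscale micrograph with physical scale.

    ``footer_rows`` bottom rows (instrument banner) are discarded by
    :func:`preprocess`.
    """

    pixels: np.ndarray
    um_per_px: float
    footer_rows: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D grayscale array")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if not 0 <= self.footer_rows < self.pixels.shape[0]:
            raise ValueError("footer_rows must be smaller than the image height")

    @property
    def area_um2(self) -> float:
        return float(self.pixels.size) * self.um_per_px**2


@dataclass
class PoreStats:
    """Per-image pore areas and wall density."""

    pore_areas: np.ndarray  # µm², one entry per pore
    wall_density: float | None = None  # gradient magnitude per µm²
    wall_gradient_sum: float | None = None  # unnormalized sum

    def __post_init__(self) -> None:
        self.pore_areas = np.asarray(self.pore_areas, dtype=float)
        if np.any(self.pore_areas <= 0):
            raise ValueError("pore areas must be positive")

    @property
    def n_pores(self) -> int:
        return len(self.pore_areas)

    @property
    def total_pore_area(self) -> float:
        return float(self.pore_areas.sum())

    @property
    def mean_pore_area(self) -> float:
        return float(self.pore_areas.mean()) if self.n_pores else float("nan")

    @property
    def median_pore_area(self) -> float:
        return float(np.median(self.pore_areas)) if self.n_pores else float("nan")


def load_micrograph(
    path: str | Path, um_per_px: float | None = None, footer_rows: int | None = None
) -> Micrograph:
    """Read a TIFF/PNG micrograph, merging an optional JSON sidecar.

    The sidecar ``<image>.json`` may hold ``um_per_px`` and ``footer_rows``;
    explicit arguments take precedence.
    """
    import imageio.v3 as iio

    path = Path(path)
    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:  # collapse RGB(A) to luminance
        img = img[..., :3].mean(axis=-1)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    scale = um_per_px if um_per_px is not None else meta.get("um_per_px")
    if scale is None:
        raise ValueError(f"no um_per_px given for {path} (argument or JSON sidecar)")
    footer = footer_rows if footer_rows is not None else int(meta.get("footer_rows", 0))
    return Micrograph(img, float(scale), footer)


def preprocess(img: Micrograph, kernel_size: int = GAUSS_KERNEL_SIZE) -> Micrograph:
    """Crop the footer and Gaussian-smooth.

    The Gaussian uses sigma = kernel_size/4 px and radius kernel_size//2
    (normalized kernel, so a constant image is unchanged and total intensity
    of an interior impulse is preserved).
    """
    if img.footer_rows >= img.pixels.shape[0]:
        raise ValueError("footer exceeds image height")
    body = img.pixels[: img.pixels.shape[0] - img.footer_rows, :]
    smooth = ndimage.gaussian_filter(
        body, sigma=kernel_size / 4.0, radius=kernel_size // 2, mode="reflect"
    )
    return Micrograph(smooth, img.um_per_px, 0)


def segment_pores(img: Micrograph, min_pore_px: int = 5) -> PoreStats:
    """Segment pores (dark phase) and convert them to µm² areas.

    Global Otsu threshold; pore pixels are those below it; 8-connected
    components smaller than ``min_pore_px`` pixels are discarded; components
    touching the image border are retained (excluding them would bias against
    large pores on high-magnification crops).
    """
    px = img.pixels
    if np.ptp(px) == 0:
        warnings.warn("uniform image: no threshold exists, reporting 0 pores")
        return PoreStats(np.empty(0))
    thr = filters.threshold_otsu(px)
    labels = measure.label(px < thr, connectivity=2)
    counts = np.bincount(labels.ravel())[1:]  # skip background label 0
    counts = counts[counts >= min_pore_px]
    return PoreStats(counts.astype(float) * img.um_per_px**2)


def wall_density(img: Micrograph) -> tuple[float, float]:
    """Summed Sobel gradient magnitude, per µm² and raw.

    Returns ``(density, raw_sum)`` where density = raw_sum / image area in
    µm². Invariant to constant intensity offsets; zero for a constant image.
    """
    gx = ndimage.sobel(img.pixels, axis=1, mode="reflect")
    gy = ndimage.sobel(img.pixels, axis=0, mode="reflect")
    raw = float(np.hypot(gx, gy).sum())
    return raw / img.area_um2, raw


def analyze_micrograph(
    img: Micrograph, min_pore_px: int = 5, kernel_size: int = GAUSS_KERNEL_SIZE
) -> PoreStats:
    """Full per-image pipeline: preprocess, segment pores, wall density."""
    pre = preprocess(img, kernel_size)
    stats = segment_pores(pre, min_pore_px)
    dens, raw = wall_density(pre)
    stats.wall_density = dens
    stats.wall_gradient_sum = raw
    return stats


def percent_change(treated: PoreStats, control: PoreStats) -> dict[str, float]:
    """Treated-over-control percentages (control = 100%).

    Reports mean pore area and wall density as 100·treated/control. A zero
    (or undefined) control maps to NaN (ND).
    """
    out: dict[str, float] = {}
    c_area = control.mean_pore_area
    t_area = treated.mean_pore_area
    out["pore_area_pct"] = (
        100.0 * t_area / c_area if c_area and np.isfinite(c_area) and c_area > 0 else float("nan")
    )
    if control.wall_density and control.wall_density > 0 and treated.wall_density is not None:
        out["wall_density_pct"] = 100.0 * treated.wall_density / control.wall_density
    else:
        out["wall_density_pct"] = float("nan")
    return out
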