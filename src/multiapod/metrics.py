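"""Image-quality metrics: lateral beam projections, main-lobe widths,
side-lobe ROI levels and contrast-to-noise ratio (CNR).

The lateral projection of a point target is the axial maximum of the
envelope over a window around the target depth, peak-normalized in dB —
the proxy for the two-way lateral beam pattern.  Widths are the linearly
interpolated full widths at a level below the peak, reported in micrometers.
Side-lobe levels are read in two lateral ROI strips 0.3–0.4 mm either side
of the target.  CNR compares log-compressed ("brightness") statistics inside
an anechoic cyst against a same-depth background:

    CNR = |mean(outside) - mean(inside)| / sqrt(var(inside) + var(outside))
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .beamformer import BModeImage
from .exceptions import NoCrossingError, RoiError, StageOrderError

__all__ = [
    "LateralProjection",
    "RoiSpec",
    "lateral_projection",
    "width_at_level",
    "sidelobe_level",
    "cnr",
    "make_cyst_roi",
    "speckle_snr",
]

#: Half-extent (m) of the axial projection window around a target depth:
#: spans the 2-cycle pulse length (~75 um round trip) plus margin so the
#: target's side lobes are included.
PROJECTION_HALF_WINDOW = 0.15e-3

#: Lateral side-lobe ROI offsets (m) from the target: 0.3–0.4 mm, applied
#: symmetrically on both sides of the peak.
SIDELOBE_ROI = (0.3e-3, 0.4e-3)


@dataclass(frozen=True)
class LateralProjection:
    """Peak-normalized lateral beam profile (dB) of one target."""

    lateral_axis: np.ndarray
    level_db: np.ndarray
    target_label: str = ""
    axial_window: tuple[float, float] | None = None


@dataclass(frozen=True)
class RoiSpec:
    """CNR regions: a disc inside the cyst and background rectangles outside.

    ``inside_center`` is (axial, lateral) in m; ``outside_rects`` are
    (z_min, z_max, x_min, x_max) tuples at the same depth, flanking the cyst.
    """

    inside_center: tuple[float, float]
    inside_radius: float
    outside_rects: tuple[tuple[float, float, float, float], ...]


def make_cyst_roi(
    depth_m: float = 3.5e-3,
    cyst_radius_m: float = 0.5e-3,
    lateral_m: float = 0.0,
) -> RoiSpec:
    """Default CNR geometry for a cyst.

    Inside: concentric disc at 70% of the cyst radius (avoids boundary
    blur).  Outside: two 0.7 x 0.7 mm background squares at the cyst depth,
    laterally offset +/-1.2 mm.
    """
    half = 0.35e-3
    return RoiSpec(
        inside_center=(depth_m, lateral_m),
        inside_radius=0.7 * cyst_radius_m,
        outside_rects=(
            (depth_m - half, depth_m + half, lateral_m - 1.2e-3 - half, lateral_m - 1.2e-3 + half),
            (depth_m - half, depth_m + half, lateral_m + 1.2e-3 - half, lateral_m + 1.2e-3 + half),
        ),
    )


def lateral_projection(
    img: BModeImage,
    axial_window: tuple[float, float],
    target_label: str = "",
) -> LateralProjection:
    """Axial-max lateral beam profile over ``axial_window``, in dB (peak 0).

    Operates on linear-scale (envelope or normalized) pixels.
    """
    if img.stage not in ("envelope", "normalized"):
        raise StageOrderError(
            f"lateral_projection expects a linear-scale image, got {img.stage!r}"
        )
    z0, z1 = axial_window
    rows = (img.axial_axis >= z0) & (img.axial_axis <= z1)
    if not rows.any():
        raise RoiError("axial window contains no image rows")
    prof = img.pixels[rows].max(axis=0)
    peak = prof.max()
    if peak <= 0:
        raise RoiError("projection is identically zero")
    with np.errstate(divide="ignore"):
        level = 20.0 * np.log10(prof / peak)
    return LateralProjection(
        lateral_axis=img.lateral_axis.copy(),
        level_db=level,
        target_label=target_label,
        axial_window=(z0, z1),
    )


def width_at_level(proj: LateralProjection, level_db: float) -> float:
    """Linear-interpolated full width (um) at ``level_db`` below the peak."""
    if level_db >= 0:
        raise NoCrossingError("level_db must be negative")
    y = proj.level_db
    x = proj.lateral_axis
    i0 = int(np.argmax(y))

    def crossing(step: int) -> float:
        i = i0
        while y[i] > level_db:
            i += step
            if i < 0 or i >= y.size:
                raise NoCrossingError(
                    f"projection never crosses {level_db} dB on one side of the peak"
                )
        x1, x2 = x[i - step], x[i]
        y1, y2 = y[i - step], y[i]
        return x1 + (level_db - y1) * (x2 - x1) / (y2 - y1)

    return (crossing(+1) - crossing(-1)) * 1e6


def sidelobe_level(
    proj: LateralProjection,
    roi_lateral: tuple[float, float] = SIDELOBE_ROI,
) -> tuple[float, float]:
    """(min, max) projection level (dB) in the side-lobe ROI strips.

    The ROI covers lateral offsets ``roi_lateral`` from the peak, on both
    sides of it.
    """
    lo, hi = roi_lateral
    if not (0 < lo < hi):
        raise RoiError("roi_lateral must satisfy 0 < lo < hi")
    x0 = proj.lateral_axis[int(np.argmax(proj.level_db))]
    offset = np.abs(proj.lateral_axis - x0)
    mask = (offset >= lo) & (offset <= hi)
    if not mask.any():
        raise RoiError("side-lobe ROI falls outside the lateral axis")
    vals = proj.level_db[mask]
    return float(vals.min()), float(vals.max())


def _roi_masks(img: BModeImage, roi: RoiSpec) -> tuple[np.ndarray, np.ndarray]:
    z = img.axial_axis[:, None]
    x = img.lateral_axis[None, :]
    zc, xc = roi.inside_center
    inside = (z - zc) ** 2 + (x - xc) ** 2 <= roi.inside_radius**2
    outside = np.zeros_like(inside)
    for z0, z1, x0, x1 in roi.outside_rects:
        outside |= (z >= z0) & (z <= z1) & (x >= x0) & (x <= x1)
    return inside, outside


def cnr(img: BModeImage, roi: RoiSpec) -> float:
    """Contrast-to-noise ratio on log-compressed pixel values.

    ``|S_o - S_i| / sqrt(var_i + var_o)``; a zero denominator (constant
    ROIs) returns +inf.
    """
    if img.stage != "log_compressed":
        raise StageOrderError(f"cnr expects a log-compressed image, got {img.stage!r}")
    inside, outside = _roi_masks(img, roi)
    if not inside.any() or not outside.any():
        raise RoiError("CNR ROI is empty")
    if (inside & outside).any():
        raise RoiError("CNR ROIs overlap")
    vi = img.pixels[inside]
    vo = img.pixels[outside]
    denom = math.sqrt(vi.var() + vo.var())
    diff = abs(vo.mean() - vi.mean())
    if denom == 0.0:
        return math.inf
    return diff / denom


def speckle_snr(
    img: BModeImage,
    region: tuple[float, float, float, float],
) -> float:
    """Envelope SNR (mean/std) over a rectangular region (z0, z1, x0, x1).

    Fully developed (Rayleigh) speckle gives sqrt(pi/(4-pi)) ~ 1.91.
    Operates on linear-scale pixels.
    """
    if img.stage not in ("envelope", "normalized"):
        raise StageOrderError("speckle_snr expects a linear-scale image")
    z0, z1, x0, x1 = region
    rows = (img.axial_axis >= z0) & (img.axial_axis <= z1)
    cols = (img.lateral_axis >= x0) & (img.lateral_axis <= x1)
    if not rows.any() or not cols.any():
        raise RoiError("speckle region is empty")
    vals = img.pixels[np.ix_(rows, cols)]
    return float(vals.mean() / vals.std())
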