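"""Delay-and-sum receive beamforming and the B-mode pipeline stages.

Stages run left to right: ``das_beamform`` (dynamic receive focusing with a
pluggable receive apodization) → ``envelope_detect`` (analytic-signal
magnitude along depth) → ``normalize_self`` (divide by the image's own peak)
→ ``log_compress`` (20 log10, clipped to the display dynamic range).
The minimum-selection combiner operates between normalization and log
compression (see :mod:`multiapod.combiner`).

Coordinates: axial depth from the array face, lateral from the array
center, meters.  The axial image grid is the RF sample grid converted by
z = c*t/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .exceptions import (
    ApodizationMappingError,
    NormalizationError,
    StageOrderError,
)
from .simulator import ArrayConfig, RFChannelData
from .windows import ApodizationProfile

__all__ = ["BModeImage", "das_beamform", "envelope_detect", "normalize_self", "log_compress"]

#: Default imaged depth span (m): covers the 2.5–4.5 mm targets and the
#: speckle field around the 3.5 mm cyst.
DEFAULT_Z_SPAN = (2.0e-3, 5.0e-3)


@dataclass(frozen=True)
class BModeImage:
    """An image at one pipeline stage.

    ``pixels`` is [axial x lateral].  ``stage`` is one of ``rf_line``,
    ``envelope``, ``normalized``, ``log_compressed``; log-compressed pixels
    lie in [-dynamic_range_db, 0].
    """

    pixels: np.ndarray
    axial_axis: np.ndarray
    lateral_axis: np.ndarray
    stage: str
    dynamic_range_db: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))
        object.__setattr__(self, "axial_axis", np.asarray(self.axial_axis, dtype=float))
        object.__setattr__(
            self, "lateral_axis", np.asarray(self.lateral_axis, dtype=float)
        )
        if self.pixels.shape != (self.axial_axis.size, self.lateral_axis.size):
            raise StageOrderError("pixel array does not match its coordinate axes")


def das_beamform(
    rf: RFChannelData,
    config: ArrayConfig,
    profile: ApodizationProfile,
    z_span: tuple[float, float] = DEFAULT_Z_SPAN,
) -> BModeImage:
    """Dynamic-focus delay-and-sum with the given receive apodization.

    For each scanline and axial sample z, receive delays follow the
    element-to-(z, scanline) geometry (transmit time ≈ z/c, exact at the
    transmit focus); channel samples are fetched with linear interpolation,
    weighted by the apodization profile and summed.  The profile must have
    the full subaperture length; truncated edge subapertures re-generate the
    same window family at the reduced element count.
    """
    if profile.N != config.n_sub:
        raise ApodizationMappingError(
            f"profile length {profile.N} != subaperture size {config.n_sub}"
        )
    k0 = int(np.ceil(z_span[0] * 2 / config.c * rf.fs))
    k1 = int(np.floor(z_span[1] * 2 / config.c * rf.fs))
    z = np.arange(k0, k1 + 1) / rf.fs * config.c / 2
    elem_x = config.element_x
    scan_x = config.scanline_x
    n_t = rf.samples.shape[2]
    pixels = np.zeros((z.size, config.n_scanlines))
    weight_cache: dict[int, np.ndarray] = {}

    for i in range(config.n_scanlines):
        el = rf.active_elements[i]
        n_a = el.size
        if n_a not in weight_cache:
            if n_a == profile.N:
                w = profile.weights
            else:
                # shrunk edge subaperture: same family at the reduced count,
                # scaled to the supplied profile's peak gain
                w = profile.regenerate(n_a).weights * profile.weights.max()
            weight_cache[n_a] = w
        w = weight_cache[n_a]
        d_rx = np.hypot(elem_x[el][:, None] - scan_x[i], z[None, :])
        tau = (z[None, :] + d_rx) / config.c
        x = (tau - rf.t0) * rf.fs
        i0 = np.floor(x).astype(np.int64)
        frac = x - i0
        valid = (i0 >= 0) & (i0 < n_t - 1)
        i0c = np.clip(i0, 0, n_t - 2)
        chan = rf.samples[i, :n_a]
        rows = np.arange(n_a)[:, None]
        vals = chan[rows, i0c] * (1 - frac) + chan[rows, i0c + 1] * frac
        vals[~valid] = 0.0
        pixels[:, i] = w @ vals

    return BModeImage(
        pixels=pixels,
        axial_axis=z,
        lateral_axis=scan_x.copy(),
        stage="rf_line",
    )


def envelope_detect(img: BModeImage) -> BModeImage:
    """Magnitude of the analytic signal along the axial dimension."""
    if img.stage != "rf_line":
        raise StageOrderError(f"envelope_detect expects rf_line, got {img.stage!r}")
    env = np.abs(hilbert(img.pixels, axis=0))
    return BModeImage(env, img.axial_axis.copy(), img.lateral_axis.copy(), "envelope")


def normalize_self(img: BModeImage) -> BModeImage:
    """Divide the envelope image by its own global maximum."""
    if img.stage not in ("envelope", "normalized"):
        raise StageOrderError(f"normalize_self expects an envelope, got {img.stage!r}")
    peak = img.pixels.max()
    if peak <= 0:
        raise NormalizationError("cannot normalize an all-zero image")
    return BModeImage(
        img.pixels / peak, img.axial_axis.copy(), img.lateral_axis.copy(), "normalized"
    )


def log_compress(img: BModeImage, dynamic_range_db: float = 60.0) -> BModeImage:
    """20*log10 of the normalized envelope, clipped to [-dynamic_range_db, 0]."""
    if img.stage != "normalized":
        raise StageOrderError(f"log_compress expects normalized, got {img.stage!r}")
    if dynamic_range_db <= 0:
        raise NormalizationError("dynamic range must be positive")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(img.pixels)
    db = np.clip(db, -dynamic_range_db, 0.0)
    return BModeImage(
        db,
        img.axial_axis.copy(),
        img.lateral_axis.copy(),
        "log_compressed",
        dynamic_range_db=dynamic_range_db,
    )
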