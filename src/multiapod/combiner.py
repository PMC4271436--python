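"""Minimum-selection (non-linear apodization) combiner.

The core of the dual-/tri-apodization method: each candidate response or
image is normalized by its own peak, and the combined output is the
pointwise minimum across candidates.  The main lobe of the combination
inherits the narrowest member main lobe (the rectangular window's), while
each side lobe is suppressed to the lowest member level at that location.

Dual apodization combines the rectangular and Dolph-Chebyshev windows;
tri apodization adds the Kaiser window to pull down the first side lobe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .beamformer import BModeImage
from .exceptions import (
    AxisMismatchError,
    GridMismatchError,
    InvalidWindowError,
    NormalizationError,
)
from .windows import ApodizationProfile, SpectralResponse, make_profile

__all__ = [
    "CombinationSpec",
    "DUAL",
    "TRI",
    "combine_spectra_min",
    "combine_images_min",
]


@dataclass(frozen=True)
class CombinationSpec:
    """An ordered set of 2 (dual) or 3 (tri) member window specifications.

    Members are ``(family, param)`` pairs; they must be distinct.
    """

    members: tuple[tuple[str, float | None], ...]
    name: str

    def __post_init__(self) -> None:
        if len(self.members) not in (2, 3):
            raise InvalidWindowError(
                f"a combination needs 2 or 3 members, got {len(self.members)}"
            )
        if len(set(self.members)) != len(self.members):
            raise InvalidWindowError("combination members must be distinct")

    def profiles(self, N: int) -> list[ApodizationProfile]:
        return [make_profile(family, N, param) for family, param in self.members]


#: The control parameters used throughout: alpha = 2.5 for Dolph-Chebyshev
#: (−50 dB equiripple) and alpha_k = 2.5/pi for Kaiser (−21 dB first side lobe).
DUAL = CombinationSpec(
    members=(("rectangular", None), ("dolph_chebyshev", 2.5)), name="dual"
)
TRI = CombinationSpec(
    members=(
        ("rectangular", None),
        ("dolph_chebyshev", 2.5),
        ("kaiser", 2.5 / math.pi),
    ),
    name="tri",
)


def combine_spectra_min(responses: list[SpectralResponse]) -> SpectralResponse:
    """Pointwise minimum of peak-normalized spectra, re-normalized to 0 dB.

    All responses must share the same bin axis and already be peak-normalized
    (max 0 dB).  Minimum in dB equals minimum on the linear magnitude scale
    for positive data.
    """
    if len(responses) < 2:
        raise AxisMismatchError("need at least two responses to combine")
    ref = responses[0]
    for r in responses[1:]:
        if r.bins.shape != ref.bins.shape or not np.allclose(r.bins, ref.bins):
            raise AxisMismatchError("responses are not on a common bin axis")
    combined = np.minimum.reduce([r.magnitude_db for r in responses])
    combined = combined - combined.max()
    return SpectralResponse(
        bins=ref.bins.copy(),
        magnitude_db=combined,
        N=ref.N,
        pad_factor=ref.pad_factor,
    )


def combine_images_min(images: list[BModeImage]) -> BModeImage:
    """Pixelwise minimum of self-normalized envelope images (linear scale).

    Follows the block order of the method: envelope detection → per-image
    self-normalization → minimum-selection comparator → (later) log
    compression.  Inputs must share a pixel grid and each must have max 1
    (within 1e-9).  The output maximum is ≤ 1 (equal to 1 wherever the
    member peaks coincide, e.g. a common point-target peak).
    """
    if len(images) < 2:
        raise GridMismatchError("need at least two images to combine")
    ref = images[0]
    for img in images:
        if img.pixels.shape != ref.pixels.shape or not (
            np.allclose(img.axial_axis, ref.axial_axis)
            and np.allclose(img.lateral_axis, ref.lateral_axis)
        ):
            raise GridMismatchError("images are not on a common pixel grid")
        if img.stage != "normalized":
            raise NormalizationError(
                f"images must be self-normalized envelopes, got stage {img.stage!r}"
            )
        if abs(img.pixels.max() - 1.0) > 1e-9:
            raise NormalizationError("image is not normalized to peak 1")
    combined = np.minimum.reduce([img.pixels for img in images])
    return BModeImage(
        pixels=combined,
        axial_axis=ref.axial_axis.copy(),
        lateral_axis=ref.lateral_axis.copy(),
        stage="normalized",
    )
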