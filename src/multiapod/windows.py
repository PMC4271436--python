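"""Apodization window synthesis and spectral (impulse-response) measurement.

The three window families used by the minimum-selection apodization method:

* rectangular (uniform) — narrowest main lobe, highest side lobes (−13 dB);
* Dolph-Chebyshev — equiripple side lobes at a level set by the control
  parameter ``alpha`` (side lobes at −20·alpha dB), synthesized by inverse
  DFT of its Chebyshev-polynomial spectrum;
* Kaiser — a tunable trade-off window built from the zero-order modified
  Bessel function, controlled by ``alpha_k`` (spectral shape parameter
  beta = pi * alpha_k).

A window's "impulse response" here is the magnitude of its zero-padded DFT,
peak-normalized to 0 dB, on a *bin* axis where one bin equals one sample
spacing of the unpadded length-N DFT.  Main-lobe widths and side-lobe levels
are measured on that response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidWindowError, NoCrossingError, ResolutionError

__all__ = [
    "ApodizationProfile",
    "SpectralResponse",
    "NO_SIDELOBE",
    "bessel_i0",
    "make_rectangular",
    "make_dolph_chebyshev",
    "make_kaiser",
    "make_profile",
    "impulse_response",
    "mainlobe_width",
    "highest_sidelobe",
    "sidelobe_floor",
]

#: Sentinel returned by :func:`highest_sidelobe` / :func:`sidelobe_floor`
#: when the response is monotone (no side lobe exists).
NO_SIDELOBE = -math.inf

#: Default zero-padding factor: bin resolution 1/64 ≈ 0.016 bins, fine
#: enough to quote widths to two decimals.
DEFAULT_PAD_FACTOR = 64


@dataclass(frozen=True)
class ApodizationProfile:
    """A length-N apodization weight vector, peak-normalized to 1.

    Attributes
    ----------
    weights : ndarray
        Real weights in [0, 1] with ``max(weights) == 1``, symmetric
        (``w[n] == w[N-1-n]``).
    family : str
        One of ``"rectangular"``, ``"dolph_chebyshev"``, ``"kaiser"``.
    param : float or None
        Control parameter — ``alpha`` for Dolph-Chebyshev, ``alpha_k`` for
        Kaiser, ``None`` for rectangular.
    """

    weights: np.ndarray
    family: str
    param: float | None = None

    @property
    def N(self) -> int:
        return self.weights.size

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if not np.all(np.isfinite(w)):
            raise InvalidWindowError("window weights must be finite")

    def regenerate(self, N: int) -> "ApodizationProfile":
        """Same family and control parameter at a different length.

        Used when a truncated edge subaperture needs a shorter window of the
        same spectral character.
        """
        return make_profile(self.family, N, self.param)


@dataclass(frozen=True)
class SpectralResponse:
    """Peak-normalized padded-DFT magnitude of a window, in dB.

    ``bins`` is in units of the *unpadded* N-point DFT sample spacing;
    fractional values arise from zero-padding (spacing ``1/pad_factor``).
    The main lobe is centered at bin 0 and ``max(magnitude_db) == 0``.
    """

    bins: np.ndarray
    magnitude_db: np.ndarray
    N: int
    pad_factor: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", np.asarray(self.bins, dtype=float))
        object.__setattr__(
            self, "magnitude_db", np.asarray(self.magnitude_db, dtype=float)
        )


def bessel_i0(x: float) -> float:
    """Zero-order modified Bessel function I0 by its power series.

    ``I0(x) = sum_m ((x/2)^(2m) / (m!)^2)``; terms are accumulated until a
    term falls below 1e-12 of the running sum.  The series converges for all
    finite ``x`` and is even in ``x``.
    """
    x = float(x)
    if not math.isfinite(x):
        raise InvalidWindowError("bessel_i0 requires finite x")
    half_sq = (x / 2.0) ** 2
    term = 1.0
    total = 1.0
    m = 0
    while term > 1e-12 * total:
        m += 1
        term *= half_sq / (m * m)
        total += term
    return total


def make_rectangular(N: int) -> ApodizationProfile:
    """Uniform (rectangular) window: all weights 1."""
    _check_length(N)
    return ApodizationProfile(np.ones(N), "rectangular", None)


def _cheb_poly(m: int, x: np.ndarray) -> np.ndarray:
    """Chebyshev polynomial T_m evaluated piecewise.

    cos/acos inside [-1, 1] and cosh/acosh outside, avoiding complex
    intermediates; the sign of x < -1 carries (-1)^m.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    inner = np.abs(x) <= 1.0
    out[inner] = np.cos(m * np.arccos(x[inner]))
    ax = np.abs(x[~inner])
    out[~inner] = np.cosh(m * np.arccosh(ax)) * np.where(
        x[~inner] < 0, (-1.0) ** m, 1.0
    )
    return out


def make_dolph_chebyshev(N: int, alpha: float) -> ApodizationProfile:
    """Equiripple (Dolph-Chebyshev) window with side lobes at −20·alpha dB.

    ``alpha`` is the common logarithm of the main-lobe-to-side-lobe amplitude
    ratio R = 10^alpha.  The weights are the inverse DFT of the Chebyshev
    spectrum ``W(k) = T_{N-1}(beta * cos(pi*k/N)) / R`` with
    ``beta = cosh(acosh(R) / (N-1))``, carrying the linear-phase origin shift
    that centers the window (for even N this is the (−1)^k half-period shift
    combined with the extra half-sample term that keeps the length-N weight
    vector elementwise symmetric).  The numerically-zero imaginary residue of
    the inverse DFT is discarded.
    """
    _check_length(N)
    if not (alpha > 0):
        raise InvalidWindowError(f"alpha must be positive, got {alpha}")
    R = 10.0 ** alpha
    order = N - 1
    beta = math.cosh(math.acosh(R) / order)
    # Signed DFT frequency indices: the origin shift to sample (N-1)/2 is a
    # half-sample phase for even N and is only single-valued on the signed axis.
    k = np.arange(N)
    kk = np.where(k <= N // 2, k, k - N)
    W = _cheb_poly(order, beta * np.cos(np.pi * kk / N)) / R
    shift = np.exp(-1j * np.pi * kk * (N - 1) / N)
    w = np.fft.ifft(W * shift)
    if np.abs(w.imag).max() > 1e-8:
        raise InvalidWindowError("Chebyshev synthesis produced a non-real window")
    w = w.real
    w = w / w.max()
    return ApodizationProfile(w, "dolph_chebyshev", float(alpha))


def make_kaiser(N: int, alpha_k: float) -> ApodizationProfile:
    """Kaiser window with control parameter ``alpha_k`` (beta = pi*alpha_k).

    ``w[n] = I0(pi*alpha_k * sqrt(1 - (2n/(N-1) - 1)^2)) / I0(pi*alpha_k)``.
    ``alpha_k = 0`` degenerates to the rectangular window.
    """
    _check_length(N)
    if alpha_k < 0:
        raise InvalidWindowError(f"alpha_k must be nonnegative, got {alpha_k}")
    beta = math.pi * alpha_k
    n = np.arange(N)
    arg = beta * np.sqrt(np.maximum(0.0, 1.0 - (2.0 * n / (N - 1) - 1.0) ** 2))
    denom = bessel_i0(beta)
    w = np.array([bessel_i0(a) for a in arg]) / denom
    w = w / w.max()
    return ApodizationProfile(w, "kaiser", float(alpha_k))


_FACTORIES = {
    "rectangular": lambda N, p: make_rectangular(N),
    "dolph_chebyshev": lambda N, p: make_dolph_chebyshev(N, p),
    "kaiser": lambda N, p: make_kaiser(N, p),
}


def make_profile(family: str, N: int, param: float | None = None) -> ApodizationProfile:
    """Dispatch on window family name."""
    try:
        factory = _FACTORIES[family]
    except KeyError:
        raise InvalidWindowError(f"unknown window family {family!r}") from None
    return factory(N, param)


def impulse_response(
    profile: ApodizationProfile, pad_factor: int = DEFAULT_PAD_FACTOR
) -> SpectralResponse:
    """Peak-normalized padded-DFT magnitude of a window, in dB.

    The window is zero-padded to ``N * pad_factor`` samples; the magnitude
    spectrum is fftshifted so the main lobe sits at bin 0, converted to dB
    and normalized so its maximum is exactly 0 dB.
    """
    if pad_factor < 16:
        raise ResolutionError(
            f"pad_factor must be >= 16 for sub-1/16-bin resolution, got {pad_factor}"
        )
    N = profile.N
    M = N * pad_factor
    mag = np.abs(np.fft.fft(profile.weights, M))
    mag = np.fft.fftshift(mag)
    bins = (np.arange(M) - M // 2) / pad_factor
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mag / mag.max())
    db[~np.isfinite(db)] = -400.0  # exact nulls; far below any display range
    db -= db.max()  # force the peak to exactly 0 dB
    return SpectralResponse(bins=bins, magnitude_db=db, N=N, pad_factor=pad_factor)


def _peak_index(resp: SpectralResponse) -> int:
    return int(np.argmax(resp.magnitude_db))


def _mainlobe_edges(resp: SpectralResponse) -> tuple[int, int]:
    """Indices of the first local minima flanking the peak (main-lobe ends)."""
    db = resp.magnitude_db
    i0 = _peak_index(resp)
    r = i0
    while r + 1 < db.size and db[r + 1] < db[r]:
        r += 1
    l = i0
    while l - 1 >= 0 and db[l - 1] < db[l]:
        l -= 1
    return l, r


def mainlobe_width(resp: SpectralResponse, level_db: float = -6.0) -> float:
    """Full main-lobe width (bins) at ``level_db`` below the peak.

    The width spans the first crossings of ``level_db`` on either side of the
    peak, linearly interpolated between adjacent spectrum samples.
    """
    if level_db >= 0:
        raise NoCrossingError("level_db must be negative (below the 0 dB peak)")
    db = resp.magnitude_db
    bins = resp.bins
    i0 = _peak_index(resp)

    def crossing(step: int) -> float:
        i = i0
        while db[i] > level_db:
            i += step
            if i < 0 or i >= db.size:
                raise NoCrossingError(
                    f"response never falls below {level_db} dB on one side of the peak"
                )
        x1, x2 = bins[i - step], bins[i]
        y1, y2 = db[i - step], db[i]
        return x1 + (level_db - y1) * (x2 - x1) / (y2 - y1)

    return crossing(+1) - crossing(-1)


def highest_sidelobe(resp: SpectralResponse) -> float:
    """Maximum level (dB) outside the main lobe.

    The main lobe extends from the peak to the first local minimum on each
    side.  A monotone response (no side lobe) returns the ``NO_SIDELOBE``
    sentinel (−inf).
    """
    l, r = _mainlobe_edges(resp)
    db = resp.magnitude_db
    outside = np.concatenate([db[:l], db[r + 1 :]])
    if outside.size == 0:
        return NO_SIDELOBE
    return float(outside.max())


def _sidelobe_peak_levels(resp: SpectralResponse) -> tuple[np.ndarray, np.ndarray]:
    """Levels of side-lobe local maxima left and right of the main lobe,
    ordered by distance from the peak."""
    db = resp.magnitude_db
    l, r = _mainlobe_edges(resp)
    interior = (db[1:-1] > db[:-2]) & (db[1:-1] >= db[2:])
    peaks = np.flatnonzero(interior) + 1
    left = peaks[peaks < l][::-1]  # nearest-first
    right = peaks[peaks > r]
    return db[left], db[right]


def sidelobe_floor(resp: SpectralResponse, skip: int = 1) -> float:
    """Plateau level (dB) of the harmonic side lobes.

    Robust estimate of the common level of the side-lobe peaks beyond the
    ``skip`` side lobes nearest the main lobe on each side: the median of the
    remaining side-lobe local-maximum levels.  Combined (minimum-selected)
    responses keep a few transition lobes near the main lobe; the median
    ignores them and reports the equiripple floor.  Returns ``NO_SIDELOBE``
    if no side lobes remain.
    """
    left, right = _sidelobe_peak_levels(resp)
    rest = np.concatenate([left[skip:], right[skip:]])
    if rest.size == 0:
        return NO_SIDELOBE
    return float(np.median(rest))


def _check_length(N: int) -> None:
    if not isinstance(N, (int, np.integer)) or N < 2:
        raise InvalidWindowError(f"window length must be an integer >= 2, got {N!r}")
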