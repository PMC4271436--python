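"""Point-scatterer RF simulator for a focused high-frequency linear array.

Generates per-channel receive RF data for a 128-element, 40 MHz linear array
sweeping a walking 32-element subaperture across 128 scanlines.  Each
scatterer contributes, for every transmit/receive element pair of the active
subaperture, the band-limited round-trip wavelet delayed by the two-way
propagation time and scaled by spherical spreading (1/(d_tx * d_rx)) and the
far-field directivity of each element (width = pitch) on both legs.
Transmit is focused at a fixed depth with per-element delays referenced to
the scanline's own element (which fires at t = 0, so the on-axis focal round
trip is exactly 2 * focus / c); receive focusing is left to the beamformer.

The model is two-dimensional (no elevation), with no attenuation and no
multiple scattering.  Transmit apodization is always uniform; the
apodization under test is applied on receive only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import GeometryError, PhantomError

__all__ = [
    "ArrayConfig",
    "Phantom",
    "RFChannelData",
    "DEFAULT_POINT_DEPTHS",
    "DEFAULT_CYST_DENSITY",
    "make_point_phantom",
    "make_cyst_phantom",
    "simulate_rf",
]

#: The five point-target depths (m) of the resolution experiment.
DEFAULT_POINT_DEPTHS = (2.5e-3, 3.0e-3, 3.5e-3, 4.0e-3, 4.5e-3)

#: Background scatterer density (per mm^2) giving fully developed speckle.
#: With standard-normal amplitudes the effective scatterer count per
#: resolution cell is about a third of the nominal one, so ~30 per focal
#: cell are needed before the background envelope SNR sits at the Rayleigh
#: limit ~1.91.
DEFAULT_CYST_DENSITY = 6000.0

#: Axial extent (m) of the speckle field surrounding the cyst.
CYST_AXIAL_SPAN = (2.0e-3, 5.0e-3)


@dataclass(frozen=True)
class ArrayConfig:
    """Geometry and excitation of the simulated linear array.

    Defaults reproduce the study setup: 128 elements at 40 um pitch,
    40 MHz center frequency, 32-element subaperture, 128 scanlines,
    transmit focus 3.5 mm, speed of sound 1500 m/s, and a band-limited
    2-cycle (envelope FWHM) excitation burst.  ``fs`` is a simulator choice
    (10x the center frequency; fractional delays are linearly interpolated
    downstream).
    """

    n_elements: int = 128
    n_sub: int = 32
    n_scanlines: int = 128
    f0: float = 40e6
    pitch: float = 40e-6
    c: float = 1500.0
    tx_focus: float = 3.5e-3
    fs: float = 400e6
    n_cycles: int = 2
    dynamic_range_db: float = 60.0

    def __post_init__(self) -> None:
        if self.n_sub > self.n_elements:
            raise GeometryError("subaperture cannot exceed the full aperture")
        if self.fs < 8 * self.f0:
            raise GeometryError("fs must be at least 8x the center frequency")
        for name in ("pitch", "c", "tx_focus", "f0", "fs"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")

    @property
    def element_x(self) -> np.ndarray:
        """Element centers (m), symmetric about the array center."""
        return (np.arange(self.n_elements) - (self.n_elements - 1) / 2) * self.pitch

    @property
    def scanline_x(self) -> np.ndarray:
        """One scanline per element x-position."""
        return (np.arange(self.n_scanlines) - (self.n_scanlines - 1) / 2) * self.pitch

    @property
    def wavelength(self) -> float:
        return self.c / self.f0

    def subaperture(self, scanline: int) -> np.ndarray:
        """Active element indices for a scanline.

        Up to ``n_sub`` contiguous elements around the scanline position,
        truncated (shrinking) at the array ends.
        """
        lo = scanline - (self.n_sub - 1) // 2
        hi = scanline + self.n_sub // 2
        return np.arange(max(lo, 0), min(hi, self.n_elements - 1) + 1)

    def excitation(self) -> np.ndarray:
        """The transmit pulse: a Hann-tapered sinusoid at ``f0``.

        ``n_cycles`` counts carrier cycles at the envelope's half maximum
        (the usual way a band-limited imaging pulse is specified); the total
        tapered duration is twice that.  The smooth envelope matters: a
        hard-edged burst radiates edge transients that dominate the off-axis
        field and mask the apodization-controlled side-lobe structure.
        """
        n = int(round(2 * self.n_cycles / self.f0 * self.fs))
        t = np.arange(n) / self.fs
        return np.sin(2 * np.pi * self.f0 * t) * np.hanning(n)

    def round_trip_wavelet(self) -> np.ndarray:
        """Pulse-echo waveform: the excitation convolved with itself.

        The excitation is band-limited identically on the way out and on the
        way back, so the wavelet a scatterer returns is the excitation's
        self-convolution (peak-normalized).  Its length — about 8 carrier
        cycles end to end, ~3 at half maximum — sets the axial resolution
        and, importantly, must span the subaperture's off-axis delay spread
        for apodization to control the side-lobe region coherently.
        """
        p = self.excitation()
        q = np.convolve(p, p)
        return q / np.abs(q).max()


@dataclass(frozen=True)
class Phantom:
    """A set of point scatterers: axial/lateral position (m) and amplitude."""

    axial_m: np.ndarray
    lateral_m: np.ndarray
    amplitude: np.ndarray
    seed: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        ax = np.atleast_1d(np.asarray(self.axial_m, dtype=float))
        lat = np.atleast_1d(np.asarray(self.lateral_m, dtype=float))
        amp = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        if not (ax.shape == lat.shape == amp.shape):
            raise PhantomError("axial, lateral and amplitude must have equal length")
        if ax.size and np.any(ax <= 0):
            raise GeometryError("scatterers must lie in front of the array (axial > 0)")
        if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(amp))):
            raise PhantomError("scatterer positions and amplitudes must be finite")
        object.__setattr__(self, "axial_m", ax)
        object.__setattr__(self, "lateral_m", lat)
        object.__setattr__(self, "amplitude", amp)

    @property
    def n_scatterers(self) -> int:
        return self.axial_m.size


@dataclass(frozen=True)
class RFChannelData:
    """Per-channel receive data: [scanline, subaperture element, time sample].

    Truncated edge scanlines use only the first ``len(active_elements[i])``
    element rows; the rest stay zero.
    """

    samples: np.ndarray
    t0: float
    fs: float
    active_elements: tuple[np.ndarray, ...]

    @property
    def n_scanlines(self) -> int:
        return self.samples.shape[0]


def make_point_phantom(depths_m=DEFAULT_POINT_DEPTHS) -> Phantom:
    """Unit-amplitude point targets at the image lateral center."""
    depths = np.atleast_1d(np.asarray(depths_m, dtype=float))
    if depths.size == 0:
        raise PhantomError("point phantom needs at least one depth")
    return Phantom(
        axial_m=depths,
        lateral_m=np.zeros_like(depths),
        amplitude=np.ones_like(depths),
        label="points",
    )


def make_cyst_phantom(
    diameter_m: float = 1.0e-3,
    depth_m: float = 3.5e-3,
    density_per_mm2: float = DEFAULT_CYST_DENSITY,
    seed: int = 0,
    config: ArrayConfig | None = None,
    axial_span: tuple[float, float] = CYST_AXIAL_SPAN,
) -> Phantom:
    """Anechoic cyst in a uniform random speckle background.

    Scatterers are drawn uniformly over the imaged region (lateral span =
    n_scanlines * pitch, axial ``axial_span``) with standard-normal
    amplitudes; those inside the cyst disc are removed.  Reproducible under
    a fixed seed.
    """
    config = config or ArrayConfig()
    z0, z1 = axial_span
    if not (z0 < depth_m < z1) or diameter_m >= (z1 - z0):
        raise GeometryError("cyst must fit inside the imaged axial span")
    if density_per_mm2 <= 0:
        raise PhantomError("scatterer density must be positive")
    half_lat = config.n_scanlines * config.pitch / 2
    area_mm2 = (2 * half_lat * 1e3) * ((z1 - z0) * 1e3)
    n = int(round(density_per_mm2 * area_mm2))
    rng = np.random.default_rng(seed)
    z = rng.uniform(z0, z1, n)
    x = rng.uniform(-half_lat, half_lat, n)
    amp = rng.standard_normal(n)
    keep = (z - depth_m) ** 2 + x**2 > (diameter_m / 2) ** 2
    _warn_if_sparse(density_per_mm2, config)
    return Phantom(
        axial_m=z[keep],
        lateral_m=x[keep],
        amplitude=amp[keep],
        seed=seed,
        label="cyst",
    )


def _warn_if_sparse(density_per_mm2: float, config: ArrayConfig) -> None:
    """Warn when the density gives < 1 scatterer per resolution cell."""
    aperture = config.n_sub * config.pitch
    lat_res = 0.886 * config.wavelength * config.tx_focus / aperture
    ax_res = config.c * config.n_cycles / (2 * config.f0)
    cell_mm2 = (lat_res * 1e3) * (ax_res * 1e3)
    if density_per_mm2 * cell_mm2 < 1.0:
        warnings.warn(
            "scatterer density below one per resolution cell; "
            "speckle will not be fully developed",
            stacklevel=3,
        )


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=False, fastmath=True)
    def _accumulate_kernel(tx_delay, dist, gain, amps, inv_c, fs, n_t):
        n_a, n_s = dist.shape
        out = np.zeros((n_a, n_t))
        for s in range(n_s):
            for it in range(n_a):
                tau_tx = tx_delay[it] + dist[it, s] * inv_c
                a_tx = amps[s] * gain[it, s]
                for ir in range(n_a):
                    x = (tau_tx + dist[ir, s] * inv_c) * fs
                    i0 = int(x)
                    if 0 <= i0 < n_t - 1:
                        a = a_tx * gain[ir, s]
                        f = x - i0
                        out[ir, i0] += a * (1.0 - f)
                        out[ir, i0 + 1] += a * f
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _accumulate_numpy(tx_delay, dist, gain, amps, inv_c, fs, n_t):
    """Vectorized fallback: same spike-train accumulation via bincount."""
    n_a = dist.shape[0]
    # tau[it, ir, s]; amplitude a[it, ir, s]
    tau_tx = tx_delay[:, None] + dist * inv_c  # (n_a_tx, n_s)
    a_tx = amps[None, :] * gain  # (n_a_tx, n_s)
    out = np.zeros((n_a, n_t))
    for ir in range(n_a):
        x = (tau_tx + dist[ir] * inv_c).ravel() * fs
        a = (a_tx * gain[ir]).ravel()
        i0 = np.floor(x).astype(np.int64)
        f = x - i0
        ok = (i0 >= 0) & (i0 < n_t - 1)
        i0, f, a = i0[ok], f[ok], a[ok]
        out[ir] += np.bincount(i0, weights=a * (1 - f), minlength=n_t)[:n_t]
        out[ir] += np.bincount(i0 + 1, weights=a * f, minlength=n_t)[:n_t]
    return out


def simulate_rf(
    config: ArrayConfig,
    phantom: Phantom,
    max_depth: float | None = None,
) -> RFChannelData:
    """Simulate per-channel receive RF for every scanline.

    ``max_depth`` sets the recorded time span (default: deepest scatterer,
    or 5 mm if deeper, plus a margin).  An empty phantom yields all-zero RF.
    """
    deepest = phantom.axial_m.max() if phantom.n_scatterers else 5.0e-3
    z_cov = max_depth if max_depth is not None else max(deepest, 5.0e-3)
    pulse = config.round_trip_wavelet()
    t_max = 2 * (z_cov + 0.5e-3) / config.c + pulse.size / config.fs
    n_t = int(math.ceil(t_max * config.fs)) + 2

    elem_x = config.element_x
    scan_x = config.scanline_x
    active = tuple(config.subaperture(i) for i in range(config.n_scanlines))
    samples = np.zeros((config.n_scanlines, config.n_sub, n_t))
    inv_c = 1.0 / config.c

    if phantom.n_scatterers:
        zs = phantom.axial_m
        xs = phantom.lateral_m
        amps = phantom.amplitude
        accumulate = _accumulate_kernel if _HAVE_NUMBA else _accumulate_numpy
        for i in range(config.n_scanlines):
            el = active[i]
            xe = elem_x[el]
            # transmit focal delays, center element of the subaperture fires at 0
            d_focus = np.hypot(xe - scan_x[i], config.tx_focus)
            tx_delay = (config.tx_focus - d_focus) / config.c
            dist = np.hypot(xe[:, None] - xs[None, :], zs[None, :])
            # One-way element gain: spherical spreading times the far-field
            # directivity of an element of width = pitch (kerf neglected);
            # without it the periodic aperture's grating response (pitch >
            # wavelength here) floods wide angles identically for every
            # receive window.
            sin_theta = (xs[None, :] - xe[:, None]) / dist
            gain = np.sinc(config.pitch * sin_theta / config.wavelength) / dist
            spikes = accumulate(tx_delay, dist, gain, amps, inv_c, config.fs, n_t)
            samples[i, : el.size] = fftconvolve(spikes, pulse[None, :], axes=-1)[
                :, :n_t
            ]

    return RFChannelData(samples=samples, t0=0.0, fs=config.fs, active_elements=active)
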