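"""Window synthesis and spectral measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special
from scipy.signal import windows as sp_windows

from multiapod.exceptions import (
    InvalidWindowError,
    NoCrossingError,
    ResolutionError,
)
from multiapod.windows import (
    NO_SIDELOBE,
    ApodizationProfile,
    bessel_i0,
    highest_sidelobe,
    impulse_response,
    mainlobe_width,
    make_dolph_chebyshev,
    make_kaiser,
    make_profile,
    make_rectangular,
    sidelobe_floor,
)

ALPHA = 2.5
ALPHA_K = 2.5 / math.pi


def brute_force_chebyshev(N: int, alpha: float) -> np.ndarray:
    """Independent oracle: the inverse-DFT sum written as explicit loops.

    w(n) = (1/N) sum_k W(k) exp(-j*pi*k*(N-1)/N) exp(2j*pi*k*n/N) on signed
    frequency indices, evaluating the Chebyshev polynomial from its
    trigonometric definition term by term.
    """
    R = 10.0 ** alpha
    order = N - 1
    beta = math.cosh(math.acosh(R) / order)
    w = np.zeros(N, dtype=complex)
    for n in range(N):
        acc = 0.0 + 0.0j
        for k in range(N):
            kk = k if k <= N // 2 else k - N
            x = beta * math.cos(math.pi * kk / N)
            if abs(x) <= 1:
                Wk = math.cos(order * math.acos(x))
            else:
                Wk = math.copysign(1.0, x) ** order * math.cosh(
                    order * math.acosh(abs(x))
                )
            Wk /= R
            phase = cmath_exp(-math.pi * kk * (N - 1) / N + 2 * math.pi * kk * n / N)
            acc += Wk * phase
        w[n] = acc / N
    w = w.real
    return w / w.max()


def cmath_exp(angle: float) -> complex:
    return complex(math.cos(angle), math.sin(angle))


class TestConstruction:
    def test_rectangular_is_all_ones(self):
        for N in (2, 32):
            prof = make_rectangular(N)
            np.testing.assert_array_equal(prof.weights, np.ones(N))

    @pytest.mark.parametrize("N", [2, 1, 0, -3])
    def test_short_windows_rejected(self, N):
        if N >= 2:
            make_rectangular(N)
        else:
            with pytest.raises(InvalidWindowError):
                make_rectangular(N)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_chebyshev_rejects_nonpositive_alpha(self, bad):
        with pytest.raises(InvalidWindowError):
            make_dolph_chebyshev(32, bad)

    def test_kaiser_rejects_negative_alpha_k(self):
        with pytest.raises(InvalidWindowError):
            make_kaiser(32, -0.1)

    @pytest.mark.parametrize("N", [8, 16, 32])
    def test_chebyshev_matches_brute_force_inverse_dft(self, N):
        """Vectorized synthesis equals the explicit inverse-DFT sum oracle."""
        fast = make_dolph_chebyshev(N, ALPHA).weights
        slow = brute_force_chebyshev(N, ALPHA)
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    @pytest.mark.parametrize("N", [8, 15, 32, 33])
    def test_chebyshev_matches_scipy(self, N):
        """Cross-check against scipy's independent equiripple implementation
        (attenuation in dB = 20 * alpha)."""
        ref = sp_windows.chebwin(N, 20 * ALPHA)
        ref = ref / ref.max()
        np.testing.assert_allclose(
            make_dolph_chebyshev(N, ALPHA).weights, ref, atol=1e-12
        )

    def test_kaiser_matches_scipy(self):
        ref = sp_windows.kaiser(32, math.pi * ALPHA_K)
        np.testing.assert_allclose(
            make_kaiser(32, ALPHA_K).weights, ref / ref.max(), atol=1e-12
        )

    def test_kaiser_zero_parameter_degenerates_to_rectangular(self):
        np.testing.assert_allclose(
            make_kaiser(32, 0.0).weights, make_rectangular(32).weights, atol=1e-12
        )

    @given(
        st.integers(min_value=4, max_value=48),
        st.sampled_from(["rectangular", "dolph_chebyshev", "kaiser"]),
        st.floats(min_value=0.5, max_value=4.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_profile_invariants(self, N, family, param):
        """Weights are finite, within [0, 1], peak-normalized and symmetric."""
        if family == "kaiser":
            param = param / math.pi
        prof = make_profile(family, N, None if family == "rectangular" else param)
        w = prof.weights
        assert np.all(np.isfinite(w))
        assert w.max() == pytest.approx(1.0, abs=0)
        assert np.all(w >= -1e-12) and np.all(w <= 1 + 1e-12)
        np.testing.assert_allclose(w, w[::-1], atol=1e-9)


class TestBessel:
    def test_at_zero(self):
        assert bessel_i0(0.0) == 1.0

    @pytest.mark.parametrize("x", [0.5, 1.0, 2.5, 10.0])
    def test_matches_scipy_special(self, x):
        assert bessel_i0(x) == pytest.approx(special.i0(x), rel=1e-10)

    @given(st.floats(min_value=-20, max_value=20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_even_symmetry(self, x):
        assert bessel_i0(-x) == bessel_i0(x)


class TestSpectralMeasurement:
    def test_rectangular_reference_values(self):
        """N=32 uniform window: 1.21-bin -6 dB width, -13 dB side lobe."""
        resp = impulse_response(make_rectangular(32))
        assert mainlobe_width(resp, -6.0) == pytest.approx(1.21, abs=0.02)
        assert highest_sidelobe(resp) == pytest.approx(-13.0, abs=0.3)

    def test_rectangular_nulls_at_integer_bins(self):
        """Dirichlet-kernel zeros at nonzero integer bins."""
        resp = impulse_response(make_rectangular(32))
        for k in (1, 2, 5, -3):
            idx = np.argmin(np.abs(resp.bins - k))
            assert resp.magnitude_db[idx] < -100

    def test_chebyshev_equiripple(self):
        """Every side-lobe local maximum sits within 0.5 dB of -20*alpha."""
        resp = impulse_response(make_dolph_chebyshev(32, ALPHA))
        db = resp.magnitude_db
        interior = (db[1:-1] > db[:-2]) & (db[1:-1] >= db[2:])
        peaks = np.flatnonzero(interior) + 1
        peaks = peaks[np.abs(resp.bins[peaks]) > 2.0]  # outside the main lobe
        assert peaks.size > 10
        assert np.all(np.abs(db[peaks] - (-20 * ALPHA)) < 0.5)
        assert highest_sidelobe(resp) == pytest.approx(-50.0, abs=0.5)

    def test_kaiser_reference_values(self):
        resp = impulse_response(make_kaiser(32, ALPHA_K))
        assert highest_sidelobe(resp) == pytest.approx(-21.0, abs=1.0)
        assert mainlobe_width(resp, -6.0) == pytest.approx(1.43, abs=0.03)

    def test_peak_is_exactly_zero_db(self):
        for fam, p in [("rectangular", None), ("dolph_chebyshev", 2.0), ("kaiser", 0.7)]:
            resp = impulse_response(make_profile(fam, 24, p))
            assert resp.magnitude_db.max() == 0.0

    def test_bin_axis_spacing(self):
        resp = impulse_response(make_rectangular(16), pad_factor=32)
        d = np.diff(resp.bins)
        np.testing.assert_allclose(d, 1 / 32)

    def test_coarse_padding_rejected(self):
        with pytest.raises(ResolutionError):
            impulse_response(make_rectangular(32), pad_factor=8)

    def test_width_level_sets_nest(self):
        resp = impulse_response(make_dolph_chebyshev(32, ALPHA))
        assert mainlobe_width(resp, -35.0) >= mainlobe_width(resp, -6.0)

    def test_width_matches_dense_scan_oracle(self):
        """Interpolated width agrees with a brute-force threshold scan to
        one spectrum-sample spacing."""
        for fam, p in [("rectangular", None), ("kaiser", ALPHA_K)]:
            resp = impulse_response(make_profile(fam, 32, p))
            level = -6.0
            above = resp.magnitude_db >= level
            i0 = np.argmax(resp.magnitude_db)
            left = i0
            while above[left - 1]:
                left -= 1
            right = i0
            while above[right + 1]:
                right += 1
            oracle = resp.bins[right] - resp.bins[left]
            assert mainlobe_width(resp, level) == pytest.approx(
                oracle, abs=2 / resp.pad_factor
            )

    def test_no_crossing_error(self):
        resp = impulse_response(make_rectangular(32))
        with pytest.raises(NoCrossingError):
            mainlobe_width(resp, -500.0)

    def test_monotone_response_has_no_sidelobe(self):
        """A pure Gaussian-like monotone spectrum returns the sentinel."""
        bins = np.linspace(-8, 8, 1025)
        db = -3.0 * bins**2
        from multiapod.windows import SpectralResponse

        resp = SpectralResponse(bins=bins, magnitude_db=db, N=16, pad_factor=64)
        assert highest_sidelobe(resp) == NO_SIDELOBE
        assert sidelobe_floor(resp) == NO_SIDELOBE

    def test_kaiser_monotone_tradeoff(self):
        """Width grows and side lobe falls as alpha_k increases."""
        widths, slls = [], []
        for ak in (0.0, 0.25, 0.5, 0.8, 1.2):
            resp = impulse_response(make_kaiser(32, ak))
            widths.append(mainlobe_width(resp, -6.0))
            slls.append(highest_sidelobe(resp))
        assert all(b >= a - 1e-9 for a, b in zip(widths, widths[1:]))
        assert all(b <= a + 1e-9 for a, b in zip(slls, slls[1:]))
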