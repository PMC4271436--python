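# Methods

## Window synthesis

Three receive-apodization families, all length N = 32 (the subaperture
size), peak-normalized to 1:

* **Rectangular** — all ones; −6 dB spectral main-lobe width 1.21 bins,
  highest side lobe −13 dB.  One *bin* is one sample spacing of the
  unpadded N-point DFT.
* **Dolph-Chebyshev** — the equiripple window whose spectrum is the
  degree-(N−1) Chebyshev polynomial `T_{N-1}(β cos(πk/N)) / R` with
  `R = 10^α` and `β = cosh(acosh(R)/(N−1))`; side lobes all at −20·α dB.
  The weights are its inverse DFT carried to the window's linear-phase
  center; for even N the required origin shift is a half-sample phase, and
  the numerically-zero imaginary residue is discarded.  The construction is
  cross-checked in the tests against an explicit inverse-DFT sum and
  against `scipy.signal.windows.chebwin`.
* **Kaiser** — `w[n] = I0(πα_K √(1−(2n/(N−1)−1)²)) / I0(πα_K)`, with the
  zero-order modified Bessel function evaluated by its power series
  (terms accumulated until below 1e−12 of the running sum).  α_K = 0
  degenerates to the rectangular window.

Control parameters are fixed at α = 2.5 (−50 dB equiripple) and
α_K = 2.5/π (−21 dB first side lobe, 1.43-bin main lobe) throughout.

**A deliberate choice:** the exact −50 dB equiripple window measures
1.895 bins at −6 dB, not the oft-quoted 1.85.  The (1.85, −50 dB) pair
describes the *ideal continuous* degree-N Chebyshev curve; no realizable
length-32 weight vector attains both (sampling that curve at 32 points
degrades the realized ripple to −43 dB).  Since the entire method rests on
the −50 dB floor being real — the combined images inherit it — this
package keeps the exact equiripple construction and accepts the 0.04-bin
wider main lobe.

## Spectral measurement

A window's impulse response is the magnitude of its zero-padded DFT
(pad factor 64 by default, i.e. 1/64-bin resolution; measurements need at
least 1/16), peak-normalized to 0 dB, main lobe centered at bin 0.  Widths
are full widths between the first level crossings on either side of the
peak, linearly interpolated between samples.  The main lobe is bounded by
the first local minimum on each side; the *highest side lobe* is the
maximum outside it.  The *harmonic side-lobe floor* is the median level of
side-lobe local maxima beyond the first side lobe on each side — a robust
plateau estimate that ignores the few transition lobes a minimum-selected
spectrum keeps near its main lobe.

## Minimum-selection combiner

Spectra are combined as the pointwise minimum of dB magnitudes (equivalent
to the linear-scale minimum for positive data), re-normalized to a 0 dB
peak.  Images are combined on the linear envelope scale *after* each has
been normalized by its own global maximum and *before* log compression —
the block order matters and is fixed; per-scanline normalization was
considered and rejected in favor of whole-image normalization.  The
combiner requires identical grids and unit peaks and guarantees
`out ≤ every input` pointwise; ties need no breaking.

## RF simulator

A deliberately small stand-in for a full ultrasound field simulator,
retaining exactly the physics the method depends on:

* **Geometry** — 128 point-sampled elements at 40 μm pitch, 128 scanlines
  at the element x-positions, walking 32-element subaperture (shrinking at
  the array ends), speed of sound 1500 m/s, transmit focus 3.5 mm.
* **Excitation** — a Hann-tapered 40 MHz burst whose envelope half-maximum
  spans `n_cycles = 2` carrier cycles (the usual convention for quoting a
  band-limited pulse length; total tapered duration 4 cycles).  A
  hard-edged burst is *not* usable here: its onset/offset transients
  dominate the off-axis field, are apodization-independent, and bury the
  side-lobe structure the method manipulates.
* **Round-trip wavelet** — the excitation convolved with itself: the pulse
  is band-limited identically on transmission and reception.  Its ~200 ns
  span covers the subaperture's off-axis delay spread, which is what makes
  the side-lobe region coherent and therefore window-controlled.
* **Element directivity** — each element radiates/receives with the
  far-field factor `sinc(w sinθ / λ)`, width w = pitch (kerf neglected).
  This is essential at 40 μm pitch > λ = 37.5 μm: without it the periodic
  aperture's grating response floods wide angles with window-independent
  energy and the cyst interior fills identically for every method.
* **Propagation** — every (tx element, rx element, scatterer) triple
  contributes the wavelet delayed by the exact two-way time and scaled by
  `1/(d_tx·d_rx)` spreading and both directivities.  Contributions are
  accumulated as a fractional-delay spike train at fs = 400 MHz (10× f0,
  linear interpolation; verified insensitive up to 1.2 GHz) and convolved
  once per channel with the wavelet.  Transmit delays are referenced so
  the scanline's own element fires at t = 0 (on-axis focal round trip is
  exactly 2·z_f/c).  Transmit apodization is always uniform; the window
  under test applies on receive only.
* Not modeled: elevation geometry (the simulator is 2-D), attenuation,
  multiple scattering, transducer electromechanical response.

## Beamformer and image pipeline

Delay-and-sum with dynamic receive focusing at every axial sample:
τ(z, e) = (z + d_e(z))/c, channel samples fetched by linear interpolation,
weighted and summed.  Truncated edge subapertures re-generate the same
window family at the reduced element count rather than cropping, preserving
the family's spectral character (scaled by the supplied profile's peak, so
degenerate profiles propagate faithfully).  The axial image grid is the RF
sample grid via z = c·t/2; depth is measured from the array face, lateral
from the array center, meters everywhere.  Envelope = magnitude of the
analytic signal along depth per scanline; log compression clips
20·log10(normalized envelope) to [−60, 0] dB for display parity.

## Phantoms

* **Points** — unit scatterers at 2.5/3.0/3.5/4.0/4.5 mm on the lateral
  center line; the third sits at the transmit focus.
* **Cyst** — a 1 mm anechoic disc at 3.5 mm inside a uniform random
  scatterer field (lateral span = aperture span, axial 2–5 mm),
  standard-normal amplitudes, reproducible per seed.  Density default
  6000/mm²: with Gaussian amplitudes the effective per-cell scatterer count
  is ≈ N/3, and ~30 effective per focal resolution cell is where the
  background envelope SNR reaches the Rayleigh limit √(π/(4−π)) ≈ 1.91.
  The SNR diagnostic is evaluated in two strips flanking the cyst
  (z 2.6–3.2 mm, |x| 0.9–1.8 mm) where the diffraction gain is depth-flat;
  a density warning fires below one scatterer per cell.

## Metrics

* **Lateral projection** — axial maximum of the envelope over
  target depth ± 0.15 mm (covering the wavelet plus margin), peak-
  normalized in dB.  The maximum (rather than the mean) preserves
  side-lobe peaks.
* **Widths** — interpolated full widths at −6 and −35 dB, in μm.
* **Side-lobe ROI** — min/max of the projection over lateral offsets
  0.3–0.4 mm on *both* sides of the peak.
* **CNR** — computed on log-compressed ("brightness") pixels:
  inside = concentric disc at 70% of the cyst radius (0.35 mm, keeping
  clear of boundary blur); outside = two 0.7 × 0.7 mm squares at the cyst
  depth, laterally offset ±1.2 mm.  Denominator √(σ²_i + σ²_o); constant
  ROIs give +∞ by convention.

## Experiment scale and runtimes

Defaults run the full 128-scanline array.  The point experiment simulates
once (5 scatterers) and beamforms three windows: a few seconds.  The cyst
experiment uses a 10-seed ensemble at 6000/mm² (~90k scatterers each),
about 45 s per seed on one CPU; per-seed CNR is reported alongside the
ensemble mean, and the percent improvement uses ensemble-mean CNRs.
Orchestration tests use a 48-element reduced array.

## What the synthetic experiments do and do not show

The generator reproduces the *mechanism*: coherent, window-controlled
side-lobe structure around point targets, fully developed speckle, and an
anechoic target whose fill is dominated by lateral side-lobe leakage.  On
those terms the method behaves as published — dual/tri keep the
rectangular main-lobe width to ~1%, suppress the focal side-lobe ROI by
well over 6 dB, and the ensemble CNR orders rect < dual ≤ tri with the
Dolph-Chebyshev window above the rectangular one.

Absolute contrast numbers transfer less directly.  This simulator's
point-spread function is clean: its integrated side-lobe energy beyond the
cyst radius is −44 dB (rectangular) and −53 dB (Chebyshev), so the cyst
interior sits near the display floor and the measurable CNR gain of
dual/tri lands near +15…+18% rather than the +41/+51% reported for a full
transducer simulation, whose unmodeled clutter sources (elevation plane,
transducer ringing) fill the cyst further and leave more headroom for
suppression.  The ordering, not the magnitude, is the robust conclusion.
Real-probe effects — frequency-dependent attenuation, element cross-talk,
phase aberration — are likewise outside the model.
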