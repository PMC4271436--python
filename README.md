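# multiapod

Minimum-selection non-linear apodization (dual-/tri-apodization) for
high-frequency ultrasound B-mode imaging, with everything needed to evaluate
it end to end: window synthesis, a point-scatterer RF simulator for a 40 MHz
linear array, delay-and-sum receive beamforming, and image-quality metrics.

## The problem and the method

Receive apodization trades side-lobe level against lateral resolution: the
uniform (rectangular) window has the narrowest main lobe but −13 dB side
lobes that fill anechoic structures and depress contrast; tapered windows
(Dolph-Chebyshev, Kaiser) suppress side lobes at the cost of a wider main
lobe.  Dual-/tri-apodization escapes the trade-off non-linearly: beamform
the *same* receive data with two (or three) windows, envelope-detect,
normalize each image by its own peak, and keep the **pointwise minimum**
across images:

```
y(r) = min_k  |E_k(r)| / max_r |E_k(r)| ,   k ∈ {rect, Dolph-Chebyshev[, Kaiser]}
```

Near the beam axis the rectangular image is smallest (narrowest main lobe),
so the combination inherits its resolution; in the side-lobe region the
equiripple Dolph-Chebyshev image is smallest (−20·α dB floor, α = 2.5 →
−50 dB), so the combination inherits its contrast.  The Kaiser member
(α_K = 2.5/π, first side lobe −21 dB at 1.43 bins) pulls down the first
side lobe that neither of the other two controls.

The package implements the three window families from their closed forms
(`multiapod.windows`), the minimum combiner for spectra and images
(`multiapod.combiner`), a Field-II-style point-scatterer simulator for the
128-element, 40 μm pitch, 3.5 mm transmit-focus array (`multiapod.simulator`),
dynamic-focus delay-and-sum with pluggable receive apodization
(`multiapod.beamformer`), and the evaluation metrics — lateral beam
projections, −6/−35 dB main-lobe widths, side-lobe ROI levels and the
cyst contrast-to-noise ratio CNR = |S̄_o − S̄_i| / √(σ²_i + σ²_o)
(`multiapod.metrics`).  `multiapod.experiments` orchestrates the three
standard experiments across the five methods.

## Worked example

```python
from multiapod import run_ipr_report
print(run_ipr_report().round(2))
```

```
                 width_6db_bins  highest_sidelobe_db  sidelobe_floor_db
rectangular                1.21               -13.23             -27.85
dolph_chebyshev            1.89               -50.00             -50.00
kaiser                     1.45               -21.59             -36.28
dual                       1.21               -13.46             -50.00
tri                        1.21               -19.29             -50.00
```

Reading the table: dual/tri keep the rectangular 1.21-bin main lobe while
their harmonic side-lobe floor drops to the Chebyshev −50 dB level; tri also
pulls the highest (first) side lobe from −13.5 down to −19.3 dB.

The imaging experiments run the full simulate → beamform → combine →
measure pipeline:

```python
from multiapod import ExperimentConfig, run_point_experiment
res = run_point_experiment(ExperimentConfig())
print(res.width_6db_um.round(1).loc[["target_3"]])       # focal target
```

```
          rectangular  dolph_chebyshev  kaiser  dual   tri
target_3         91.9            112.7   101.4  92.8  92.8
```

The focal-target −6 dB lateral width of dual/tri (92.8 μm) stays within 1%
of the rectangular window's 91.9 μm, while their side-lobe ROI level
(0.3–0.4 mm off the target) drops from −44…−49 dB to −54…−70 dB.

The same pipeline is available from a shell:

```bash
multiapod ipr   --out out/            # window table + spectrum text files
multiapod point --out out/            # B-mode PNGs + width/side-lobe CSVs
multiapod cyst  --out out/ --seed 0 --n-seeds 10   # per-seed and mean CNR
```

Each subcommand accepts `--config cfg.yaml` overriding any parameter, e.g.

```yaml
array:
  n_cycles: 2
  tx_focus: 0.0035
cyst_density: 6000
methods: [rectangular, dual, tri]
```

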