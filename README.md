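# relaxmap

Noise-gated pixel-wise T1/T2 MRI relaxometry.

## The problem

Quantitative relaxometry estimates the longitudinal (T1) and transverse
(T2) relaxation times of every pixel in a magnetic-resonance image by
acquiring the same slice many times — varying the repetition time TR at
fixed echo time TE for T1 mapping, or varying TE at fixed TR for T2
mapping — and fitting an exponential model to each pixel's
intensity-vs-time curve:

    SI(TR) = A · (1 − e^(−TR/T1))      (saturation recovery)
    SI(TE) = A · e^(−TE/T2)            (monoexponential decay)

with `A` absorbing proton density and the fixed-time factor of the
spin-echo signal `SI ≈ PD · (1 − e^(−TR/T1)) · e^(−TE/T2)`. At TR = T1
the recovery reaches 63.2% of its plateau; at TE = T2 the decay falls to
36.8% of its start.

Most of a typical field of view is aerated space containing nothing but
magnitude-image noise. Fitting those pixels wastes the bulk of the
computation and fills the relaxation-time histograms with garbage
entries. relaxmap gates the fit with a small feed-forward network — K
inputs (one per acquisition), 10 hidden tanh units, one sigmoid output —
trained **per scan** on two user-chosen 10×10 square regions of the very
image being analysed: one on a sample (label 1), one on aerated
background (label 0). Training on the scan itself bakes the session's
actual noise character into the classifier. Only retained pixels are
fitted; the products are co-registered T-maps, amplitude maps, R² maps
(R² = 1 − SSE/SST per pixel), the binary network-response mask, and
relaxation-time histograms before/after gating.

Intended users: anyone doing bench or preclinical relaxometry from
single-slice DICOM series (phantoms, cell cultures) who wants clean
quantitative maps and histograms without hand-drawn masks.

## Worked example

`examples/04_noise_gated_t1_map.py` simulates a three-tube phantom
(64×64, Rician noise σ=20) through the 23-point TR protocol
(40 … 15 000 ms at TE = 20 ms), trains the classifier on its own ROIs,
and fits T1 both ungated and gated:

```
fits performed: 4096 ungated -> 591 gated (14.4% of the work)
  tube 1: true T1    300 ms, fitted median   299.3 ms, median R^2 0.9964
  tube 2: true T1    900 ms, fitted median   897.5 ms, median R^2 0.9965
  tube 3: true T1   2200 ms, fitted median  2171.8 ms, median R^2 0.9945
aerated pixels retained by the gate: 0 (ungated fitting wasted 3505 fits on air)
```

The gate cut the pixel fits to 14.4% of the image — the
hardware-independent measure of the speed-up, set entirely by the ratio
of object to air pixels — while the fitted medians track the true values
to well under 1–2% and no air pixel survives into the maps or
histograms. The other examples cover the signal physics
(`01_signal_models.py`, which prints the proton Larmor frequencies
63.86621838 MHz at 1.5 T and 127.73243676 MHz at 3 T), phantom
simulation to DICOM (`02`), and classifier training (`03`).

## Command line

```bash
relaxmap simulate --mode t1 --seed 1 --out phantom_dicom/
relaxmap fit --input phantom_dicom/ --mode t1 \
    --object-roi 91,91,10 --air-roi 2,54,10 --seed 1 --out run1/
relaxmap panels --run run1/
```

`fit` writes the maps and histograms as CSV, the trained classifier as
JSON, before/after comparison panels as PNG, and a `report.json` with
the pixel accounting. A YAML config (`--config`) can replace the flags.
Choose the object ROI on the weakest-signal sample present (slowest
recovery for T1, shortest T2 for T2): the classifier then interpolates
between its two training classes for every other sample instead of
extrapolating.

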