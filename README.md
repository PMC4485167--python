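# barcodeassay

Readout toolkit for **barcode-formatted immunoassays**: point-of-care
test strips whose binding lines are laid out as a genuine Code 39
barcode, so that a stock barcode-scanner app gives the qualitative call
and grayscale densitometry of the same image gives the quantitative
one.

## The idea

Code 39 encodes every character as 9 elements — 5 bars interleaved with
4 spaces, exactly 3 of them wide.  The characters `-` and `+` share
their first 5 elements and differ only in the last 4: `-` ends in two
wide bars with narrow spaces, `+` in two narrow bars with wide spaces.
An assay plate realizes those two wide bars as four binding strips —
each wide bar divided into a 3 mm **test line**, a ~0.5 mm white
barrier, and a 2 mm **control line** — with the rest of the barcode
printed in black:

* analyte present → all four strips darken → the divided bars read as
  wide → the scanner reports **`-`** (positive);
* valid negative → only the control lines darken → narrow bars flanked
  by widened spaces → the scanner reports **`+`**;
* a missing control line leaves no valid character → no read → the
  test is void.

Strip darkness is quantified by the **optical density ratio**

```
ODR = (I_b − I_s) / I_b
```

with `I_b` the background luminosity and `I_s` the strip luminosity
(`I = 0.299 R + 0.587 G + 0.114 B` for RGB pixels); ODR is 0 for a
blank strip, 1 for black on white, and invariant to uniform exposure
changes.  Each region is sampled as 3 disjoint groups of 4715 pixels.
Dose–response is modeled with the four-parameter logistic
`ODR(c) = lower + (upper − lower) / (1 + (midpoint/c)^slope)`, whose
closed-form inverse turns a measured ODR into a concentration with an
interval.

The package provides the whole loop in silico: a Code 39 encoder and
pattern algebra, a synthetic renderer with physical geometry and
optical degradation (blur, lighting gradient, seeded noise), a
scanline decoder, densitometry, calibration fitting/inversion, and
multiplexing schemes (`-/+` and `F/$` pairs, or `A+B-`-style
designator pairs).  It is aimed at assay designers who want to probe
the readability envelope of such layouts before any wet chemistry.

## Worked example

`python examples/03_readability_sweep.py`:

```
minimum readable ODR for '+': 0.24
minimum readable ODR for '-': 0.44

'+'  ODR 0.08 ..########## 0.96   (#=scans, .=fails)
'-'  ODR 0.08 .....####### 0.96   (#=scans, .=fails)
```

The scanner reads `+` once its control bars reach ODR 0.24, but `-`
needs ODR 0.44: the white barrier inside each divided wide bar only
blurs shut when the strips are dark enough, so faint positives are the
hard case — the false-negative risk zone of the design.

`python examples/04_quantify_and_calibrate.py` closes the loop
quantitatively:

```
fitted 4PL: lower=0.045 upper=0.560 midpoint=5.73 slope=1.95
quantifiable range: 0.08 - 21.6 mIU/mL

qualitative call: positive
test-line ODR: measured 0.213 (target 0.216)
estimated concentration: 3.96 mIU/mL (interval 3.57-4.36; true 4.00)
```

A specimen rendered at 4.0 mIU/mL is called positive, its test-line
ODR is measured to within 0.003 of the rendered target, and inverting
the fitted curve recovers the concentration within 1%.

There is also a thin CLI (`barcodeassay encode|render|decode|quantify|
calibrate|simulate|report`, YAML-configurable, `dump-config` shows all
defaults); the examples directory is the guided tour.

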