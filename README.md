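# t1norm

Quantitative T1 mapping of the pediatric brain with single-shot
inversion-recovery Look-Locker FLASH, plus the statistics needed to turn
regional T1 values into age-normative reference curves.

## The problem

The longitudinal relaxation time T1 is a tissue property: it tracks water
content, myelination and iron deposition, and in the developing brain it
falls steeply over the first years of life before flattening toward
adulthood. A clinically useful normative reference therefore needs (i) a
fast, accurate T1 mapping sequence, (ii) regional statistics over a
pediatric cohort spanning infancy to adolescence, and (iii) an age model
with percentile bands against which an individual patient can be compared.

`t1norm` implements that chain as a desk-scale, fully synthetic pipeline.
Because no raw patient data are available, the package ships a
**synthetic cohort generator** — a schematic digital head phantom whose
nine regions (caudate nucleus, putamen, globus pallidus, thalamus, dentate
nucleus, frontal and occipital white matter, brainstem, bulbus oculi)
carry age-dependent ground-truth T1 — and runs the *real* analysis on it:
per-pixel curve fitting of simulated 67-frame image series, ROI
statistics with two simulated observers, regression-family comparison,
and reliability statistics. Every downstream number can be checked
against the generator's ground truth.

## The model

A slice-selective inversion pulse is followed by a continuous 4-s FLASH
readout (TR/TE 4.0/2.2 ms, flip angle 6°, 15 radial spokes per frame →
60-ms temporal footprint, 67 frames, 220×220 matrix at 1×1 mm). The
continuous readout shortens the apparent recovery (Look-Locker effect), so
each pixel's intensity follows

    S(t) = A − B·exp(−t/T1*),        1/T1* = 1/T1 − ln(cos α)/TR,

and the true T1 is recovered by the correction **T1 = T1\*·(B/A − 1)**.
Pixelwise nonlinear least squares of (A, B, T1*) over the frame series
yields the T1 map (a vectorized Levenberg–Marquardt solves all ~23 000
foreground pixels of a slice at once; magnitude images get polarity
restoration first).

Regional T1 versus age x is modeled by the power law

    T1(x) = a·x^r + b,   r = −n/10  (integer n),

selected against linear, logarithmic, square-root and exponential
alternatives by adjusted R². Normative bands are the 2.5th/97.5th
percentiles, prediction ± 1.959964·SD of the residuals. Reliability uses
Bland–Altman limits of agreement, ICC(2,1) and Wilcoxon rank-sum
contrasts between structures.

## Worked example

Fit a single noisy pixel series (`python examples/fit_single_series.py`):

```
frames: 67, footprint 60 ms
true T1        :   1101.0 ms
apparent T1*   :    438.3 ms
fitted T1*     :    445.1 ms
corrected T1   :   1101.8 ms (+0.08%)
converged: True, residual sum of squares 5246
```

The apparent T1* (438 ms) is far below the true T1 (1101 ms) — that is the
Look-Locker effect — and the correction recovers the truth to 0.1% at 1%
image noise.

Fit normative curves on the default cohort
(`python examples/normative_curves.py`):

```
region                   family       n  adjR2    T1(1y)   T1(10y)         band@10y
caudate_nucleus          power_n10    4  0.917    1512.3    1277.0 [ 1219.0, 1334.9]
putamen                  power_n10    4  0.897    1381.0    1163.6 [ 1103.4, 1223.8]
frontal_white_matter     power_n10    8  0.905     982.0     756.3 [  680.0,  832.6]
...
bulbus_oculi             exponential   -  0.002    3992.1    3992.2 (age-independent)
```

Every age-dependent region selects the power family and recovers its
generating exponent; the vitreous body is correctly flagged as
age-independent (no family reaches adjusted R² of 0.2). The third example,
`examples/reliability_small_cohort.py`, runs the full imaging chain on
eight subjects and prints pooled means, inter-rater ICC(2,1) (≈0.997 for
brain structures, markedly lower for the eye) and left–right biases.

A disk-based three-stage CLI mirrors the library:

```sh
t1norm simulate --config cfg.yaml --out DIR   # NIfTI series + labels + truth
t1norm fit      --in DIR                      # T1 maps + masks + sidecars
t1norm analyze  --in DIR                      # CSV tables + summary.json
```

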