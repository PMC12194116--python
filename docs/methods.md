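# Methods

## Dose schedule

The experimental protocol applies galvanic current for one second at each of
29 intensities: 0.00 to 1.00 mA in 0.10 mA steps, then 1.50 to 10.00 mA in
0.50 mA steps. `make_dose_schedule` reproduces exactly this list; dose is
indexed by intensity because the application time is fixed.

## Synthetic B-mode generator

Real frames from this protocol are not publicly available, so the image
stage is exercised on a parametric emulation of their salient structure.

**Speckle.** Fully developed speckle is modeled by a Rayleigh envelope: each
pixel is `m·(1 + s·(R − 1))` with `R` Rayleigh-distributed with unit mean,
`m` the background gray level (default 60) and `s ∈ [0, 1]` the speckle
blend (default 0.5), rounded and clipped to 8 bits. `s = 0` gives a flat
field, which the degenerate-input tests rely on. RF-level physics (point
spread, depth-dependent attenuation, log compression) is deliberately out of
scope: the purpose is to exercise the texture operators, not to calibrate
them against a scanner.

**Lesions.** The focus count at dose `d` is Poisson with mean
`r(d) = 8·d²/(d² + 3²)`: negligible below 1 mA, rising over 1–4 mA, and
plateauing near 8 foci — the qualitative dose-response shape reported for
this protocol. Mean focus radius is `0.03 + 0.025·d/(d+3)` cm. Each focus is
a disc brightened by 90 gray levels whose boundary is modulated by random
2nd–4th angular harmonics with relative amplitude `0.45·d/(d+3)`, so lesions
are near-circular at low dose and lobulated at high dose; this is what makes
the measured convexity fall with dose, mirroring the progressive loss of
geometric regularity the protocol describes. Above 4 mA every focus casts a
posterior shadow: all pixels below it within its horizontal extent are
multiplied by 0.6, the simplest model of gas-induced acoustic shadowing. The
generator returns exact ground truth (centers, radii, union mask), and an
optional minimum center separation supports segmentation-correctness tests
with guaranteed non-merging foci.

**What passing image tests do and do not show.** The generator reproduces
the monotone-then-plateau count/area trends, the convexity and homogeneity
declines, and shadowing — the features the pipeline must detect. It does not
reproduce anisotropic speckle correlation, operator-dependent gain, real
lesion morphology, or depth-dependent artifacts, so green tests demonstrate
correctness of the measurement and statistics code, not clinical validity on
scanner data.

**Tabular generator.** For statistical parameter recovery the three
geometric features are linear in three shared standard-normal factors:
`Number = 2.0 + 0.8·z₁`, `Area = 0.030 + 0.006·z₁ + 0.008·z₂`,
`Perimeter = 0.80 + 0.125·z₁ + 0.075·z₂ + 0.20·z₃` (cm units), giving a
closed-form covariance used directly in tests. Dose is the composite linear
model applied to the features plus `N(0, σ²)` noise. Features are left
unclipped: negative draws are rare (<0.2%) at these means and truncation
would bias coefficient recovery. With the reference coefficient vector the
explained dose variance is `βᵀΣβ ≈ 19.76 mA²`, so residual σ = 3.14 mA
calibrates the population R² to ≈ 0.667; σ = 0.3 mA is the low-noise setting
for coefficient recovery. Per-frame and per-replicate seeds are derived as
`master + index` for reproducibility with independent streams.

## Affected-area segmentation and geometry

The detection rule is deliberately transparent: a pixel is "affected" when
it exceeds `median + k·(1.4826·MAD)` of the ROI (default `k = 3`), computed
robustly so the bright foci themselves do not inflate the threshold; the
rule is therefore equivariant to constant gray-level shifts.
Components (8-connected by default) smaller than 20 px are discarded.

Region boundary length is the 0.5-level marching-squares contour simplified
with a 1-pixel Douglas–Peucker tolerance; the simplification removes the
single-pixel staircase that otherwise inflates the boundary of smooth shapes
by up to ~27% (a digital disc's crack boundary vs its circumference), and
the resulting estimator is accurate to a few percent on discs and squares.
Convexity is the summed convex-hull perimeter over the summed region
perimeter, capped at 1: it is 1 for convex shapes up to discretization and
decreases with boundary irregularity. (The opposite ratio, region/hull,
would grow with irregularity; the orientation used here is the one for which
the low-dose value is 1 and the dose trend is a decline.) Area is the pixel
count times the squared pixel spacing (default 0.01 cm/px, which puts areas
and perimeters on the cm scale the composite-model coefficients expect).

The region-level texture triple (homogeneity, contrast, ASM) is computed on
the union bounding box of the detected regions, so it contrasts altered
tissue against its immediate surroundings. With no regions the vector takes
the degenerate values (1, 0, 1) — an unperturbed image — matching the
near-1.00 low-dose behavior of ratio-like descriptors. Whether the original
measurement software used the region mask, its bounding box, or the whole
frame is unknown; the bounding window is the choice here.

## Texture descriptors

Gray levels are uniformly quantized to L = 32 bins (configurable), a
standard compromise for 8-bit ultrasound texture. The GLCM pools the four
unit-distance directions (0°, 45°, 90°, 135°) into one symmetrized,
normalized matrix to reduce directional bias. Features use the Haralick
forms: contrast `Σ(i−j)²p`, sum average `Σk·p_{x+y}(k)`, sum-of-squares
variance `Σ(i−μ)²p(i,j)` with μ the marginal mean, difference variance
computed as the variance of the signed-difference marginal `p_{x−y}`,
correlation `(Σij·p − μxμy)/(σxσy)` defined as 0 when a marginal is
degenerate (so flat windows stay finite), and inverse difference moment
`Σp/(1+(i−j)²)`. GLDS uses displacement (0, 1): the normalized histogram of
absolute level differences, summarized by mean, contrast (second moment),
ASM, entropy (natural log, `0·ln 0 := 0`) and homogeneity `Σg(k)/(1+k)`.
Haar statistics are the mean and variance of the absolute pooled detail
coefficients (LH, HL, HH) of a one-level 2-D Haar transform on the
even-cropped frame; the sign of a detail coefficient carries no echotexture
meaning, hence the absolute value. Every descriptor is checked against a
literal-formula brute-force oracle in the tests.

## Statistical stage

* **Spearman screen** — tie-corrected rank correlation, p from the
  t-approximation with n−2 df; constant inputs are rejected rather than
  silently returning NaN.
* **Simple regressions** — OLS per feature with R, R², SE of the estimate
  `√(RSS/(n−2))`, ANOVA F, standardized beta and the 95% CI of the slope.
* **Backward elimination** — starting from the full model, the predictor
  with the largest partial-F p ≥ 0.10 is removed and the model refit until
  all survive; for single-predictor removal the partial-F test equals the
  coefficient t-test, and the 0.10 default matches the removal rule of
  mainstream statistical software. Rank-deficient designs are rejected with
  a diagnostic. Under the null a noise predictor is removed with probability
  exactly 0.90, which is what the tests assert.
* **Composite index** — `UZ_eDosis` is evaluated with the fixed reference
  coefficients (0.542, −316.88, −2.678, 20.284) rather than refit
  coefficients, so the index is a stable instrument rather than a
  dataset-dependent quantity.
* **Dose groups** — low [0, 1], medium (1, 4], high (4, ∞) mA, closed on
  the left boundary so that "greater than 4" is strict. (An alternative
  1/6 mA split exists in part of the source material; the boundaries are a
  parameter.)
* **Group tests** — Kruskal–Wallis with tie correction (H defined as 0 when
  all observations are identical), chi-square asymptotic p; pairwise
  Mann–Whitney U with the tie-corrected normal approximation, no continuity
  correction (matching "asymptotic two-tailed significance" reporting), each
  p multiplied by 3 and capped at 1.

## Problem sizes and tolerances

Coefficient recovery uses n = 2000 with σ = 0.3 mA and a 3-standard-error
band; the R² calibration averages 200 replicates of n = 2000 at σ = 3.14 mA
and allows ±2 percentage points around 66.7%; the image trend check uses the
full 29-dose schedule at 256×256 px. Oracle-equivalence tests use 1e-9
tolerances (1e-12 where the computation is exact); the permutation check of
the Kruskal–Wallis p uses 1e5 draws at n = 12 with a tolerance combining
Monte-Carlo error and the known small-sample slack of the chi-square
asymptotics.

## Known limitations

The speckle model is white (no lateral/axial correlation length), lesion
appearance is stylized, and segmentation assumes bright-on-dark lesions with
a stationary background; none of the defaults have been calibrated against
clinical scanners. The composite index inherits the linearity and
feature-choice assumptions of the reference model and should be re-estimated
for other transducers, depths, or tissues.
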