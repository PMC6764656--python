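# Methods

This note records the models `uraman` implements, the assumptions behind
them, the parameter choices that matter, and what the synthetic-data
tests do and do not demonstrate about real instrument data.

## Data model

A raw dataset is a collection of replicate Raman scans (intensity vs
Raman shift, cm⁻¹) per urine specimen, plus a metadata table (donor,
sex, birth year, collection date, menstruation flag, control flag).
Scans are resampled by linear interpolation onto a common working grid,
250–1950 cm⁻¹ at 2 cm⁻¹ spacing (851 channels). The acquisition range
covers the biological fingerprint region; instruments of this class
have ~8 cm⁻¹ spectral resolution, so a 2 cm⁻¹ digitization step
oversamples safely and loses nothing. Interpolation never extrapolates:
a grid extending past the recorded range is an error, not a guess.
Downstream operations address rows by specimen id, never by position,
so row order is immaterial except where explicitly tested.

## Preprocessing

The chain is: baseline-correct each scan, average a specimen's
replicate scans channel-wise, vector-normalize the averaged spectrum,
and (at analysis time) truncate to the 400–1800 cm⁻¹ analysis window
(701 channels). Two windows coexist deliberately — the full acquisition
range is kept through preprocessing, and the narrower window is a
configuration knob applied as the last step before chemometrics, so
either choice can be reproduced.

**Baseline model.** Urine spectra ride on a broad fluorescence
background. The default corrector fits a polynomial of degree
`poly_order` (default 7) by iteratively reweighted least squares with
an asymmetric, clipped quadratic cost: residuals below the fit and
small positive residuals are penalized quadratically; the penalty of
residuals above a scale threshold *s* is clipped (weight zero), so
peaks cannot drag the fit upward. Each iteration re-tunes *s* as a
residual quantile targeting twice the configured `peak_fraction`
(capped at 60% of channels) — the doubling is a tail allowance, since
Lorentzian bands extend well past their nominal FWHM footprint and
would otherwise bias the fit upward. The basis is Legendre on the
rescaled axis for conditioning; convergence is declared when the
coefficient change falls below `tol` (default 1e-6), within `max_iter`
(default 100) iterations. On 50 seeded synthetic spectra (random
quadratic baselines plus 3–8 Lorentzian peaks covering ≤ 20% of
channels) the median recovered-baseline RMSE is ≈ 1.4% of the tallest
peak amplitude, within the 2% contract the test suite enforces. An
ordinary asymmetric least-squares polynomial fit (`method="als"`,
constant small weight on positive residuals) is available for
comparison.

Negative intensities after subtraction are retained, not clipped:
clipping would bias the subsequent normalization.

**Normalization** is the Euclidean (L2) norm — the standard meaning of
"vector normalized" in vibrational spectroscopy; L1/area normalization
is available behind a config switch. Normalization removes overall
intensity differences but *couples channels*: a change in one band's
concentration redistributes apparent variation onto all other bands.
The attribution tests account for this explicitly.

## Chemometrics

**PCA** is the plain mean-centered singular value decomposition; no
per-channel standardization (spectra are already unit-norm;
standardizing would inflate noise-only channels). Component sign is
fixed so each loading's largest-magnitude channel is positive, making
stored models bit-reproducible across runs. Variance fractions are
singular values squared over their total; the number of components
retained for classification is the smallest count reaching a cumulative
variance tier (90/95/99/99.9% are conventional choices).

**DAPC** fits a Gaussian linear discriminant — per-class means and one
pooled within-class covariance (unbiased n−k denominator) — on the
leading PC scores. Priors default to empirical class frequencies
(uniform available). The pooled covariance is regularized only by
adding 1e-8 × trace/dim to the diagonal: deliberately minimal, so the
overfitting behaviour of very high variance tiers (e.g. 35 PCs from a
couple hundred specimens) remains observable rather than being tuned
away. Ties at equal posterior go to the first class in lexicographic
order (tested).

**Blind leave-one-out validation** refits *both* the PCA and the
discriminant on every fold of n−1 specimens; the held-out spectrum
never influences centering, loadings or discriminant parameters. This
is the strict no-leakage reading of a "build/test" routine; a
fixed-PCA mode (`refit_pca=False`) exists for comparison and is
knowingly leaky. When a variance tier is requested the PC count may
differ between folds (each fold's variance fractions differ); reports
record the per-fold count and its mode. Multi-class problems are fit as
one multi-class discriminant and summarized one-vs-rest per class.

Leave-one-out on effect-free data is *pessimistic*: the discriminant
fits noise and makes some minority-class predictions, so null accuracy
falls below the majority-class rate rather than at it. The leakage
guard in the test suite therefore brackets null accuracy between two
Monte-Carlo chance strategies — a frequency-random guesser (lower
bound) and an always-majority guesser (upper bound) — rather than
demanding it sit exactly at the majority rate.

## Distance statistics

Each specimen is reduced to distances from the synthetic-urine negative
control: **TPD**, the Euclidean distance between the specimen's first
four PC scores and the control's mean score vector, and **TSD**, the
same distance over all channels of the analysis window. Four components
is the convention (and the default) because that tier captures ≥ 95% of
variance in datasets of this kind; the count is a parameter for
sensitivity analysis. Control scans are preprocessed identically and
included in the PCA fit, so specimen and control live in one coordinate
system; their mean score vector is the control point. Orthogonal
projection is a contraction, so TSD ≥ TPD whenever the PCA is fit on
the same windowed data (tested numerically).

**ANOVA.** TPD is analyzed by 2-way ANOVA with both factors categorical
(birth year enters as a factor, not a covariate). The two-step protocol
fits the interaction first and refits without it when non-significant.
Sum-of-squares types I/II/III are all available; the default is II for
no-interaction fits and III with an interaction (unbalanced designs).
p-values below 1e-12 are rendered as "<1e-12", never 0. Constant
responses yield zero sums of squares with F and p reported as NaN.
**Tukey HSD** pairwise comparisons use the studentized range with the
Tukey–Kramer rule for unbalanced groups (via statsmodels).

A caution the test suite encodes: when donors contribute several
specimens, TPD values are clustered within donor and a plain 2-way
ANOVA on specimen-level rows is anticonservative for donor-level
factors such as sex. The type-I calibration study therefore uses one
specimen per donor (200 independent specimens); mixed-effects modeling
of clustered designs is out of scope.

## Synthetic cohorts

The generator emulates the structure the analysis assumes. Each donor
draws a birth year (87.5% in 1995–1998, mirroring a young study
population, the rest uniform over 1947–2000) and per-peak amplitudes:

    amp = base × sex_multiplier^(is male) × (1 + age_slope·(year − 1996))
              × LogNormal(cv = donor_cv)

Each specimen applies a day-level LogNormal(cv = day_cv) factor, drawn
**per peak**: a single scalar day factor common to all peaks would be
removed exactly by vector normalization, leaving no day-to-day
variation downstream, so per-peak draws are the faithful choice for a
generator meant to exercise the longitudinal analyses. Peaks are
Lorentzians (default FWHM 10 cm⁻¹, slightly broader than the nominal
8 cm⁻¹ instrument resolution; Gaussian selectable) at the named urine
bands — urea 1002 (dominant), creatinine 680, collagen 870, uric acid
981, glucose 1071 and 1117 cm⁻¹ — with relative amplitudes
(1.0/0.45/0.20/0.30/0.18/0.15) that are order-of-magnitude choices;
true relative band intensities of normal urine are only qualitatively
known. Every spectrum adds a quadratic baseline plus an exponentially
decaying fluorescence background, and every replicate scan adds
independent Gaussian noise (default sd 0.01, 1% of the urea apex).

The control standard has a fixed profile (base amplitudes ×
`control_scale`, default 0.5 — a negative-control standard is more
dilute than urine) with no donor/day variation. The menstruation knob
adds a blood-marker band at 1545 cm⁻¹ with amplitude
`menstruation_effect`, default 0 so that default syntheses carry the
flag with no spectral consequence (matching the null finding such
studies report); the knob exists for power studies. Random streams are
split by (donor, specimen, scan) with `numpy.random.SeedSequence`, so
generating a subset never shifts the remainder's draws, and a fixed
seed is bit-reproducible.

Defaults mirror the cross-sectional study shape (39 female / 9 male
donors); donor_cv = 0.15 and day_cv = 0.08 place within-donor variation
below between-donor variation, as repeated-collection studies observe.

**What the generator does not model:** real urine matrix chemistry and
covarying metabolite panels, physically calibrated Raman cross
sections, wavenumber miscalibration, cosmic-ray spikes, detector
nonlinearity, or heteroscedastic noise. Passing tests demonstrate the
*pipeline's* correctness and calibration under the stated statistical
structure — not that any particular classification accuracy will be
attained on instrument data.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` scale the study down to
desk-scale sizes, stated here as the package's own choices: the
acceptance script's cross-sectional cohort uses 39 + 9 donors × 2
specimens × 5 scans (96 specimens) with a 1.2× male urea multiplier —
chosen so the synthetic study reproduces the qualitative shape of a
marginal sex effect (classification modestly above chance with
female-heavy sensitivity/specificity asymmetry, sex ANOVA p near 0.05);
the power/calibration checks use 200 donors × 1 specimen × 2 scans with
a 1.25× effect (power arm) or none (null arm); the 30-day mode uses 4
donors × 30 days with donor_cv = 0.3 ≫ day_cv = 0.05. The separable
limit uses a 2× urea multiplier against cvs of 0.02/0.01, i.e. a ≥ 5σ
class separation.

## Running on instrument data

The pipeline applies unchanged to real scan matrices in the wide or
long CSV dialect plus a metadata table (`uraman preprocess` → `pca` →
`loo`/`tpd`/`anova`). On a published normal-urine specimen bank of
~235 specimens, sex-classification LOO accuracy in the low-70s to
mid-80s percent across the 90–99.9% variance tiers is the plausible
range; this is documented as a non-desk check and not asserted by any
test, since it requires downloading the external dataset.

## Known limitations

- The baseline corrector assumes the background is polynomial-smooth;
  sharp fluorescence edges or fringes would leak into corrected spectra.
- DAPC is linear with a shared covariance; strongly nonlinear class
  structure is out of scope, as are kernel/regularized discriminant
  variants beyond the minimal ridge.
- ANOVA treats specimens as independent; repeated-measures and
  mixed-effects designs are not modeled.
- The leave-one-out routine refits one PCA per fold, which is O(n)
  SVDs; for thousands of specimens a fixed-PCA approximation or
  incremental update would be needed.
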