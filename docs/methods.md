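# Methods

## Scope

`tricscreen` analyzes temperature-related intensity change (TRIC)
displacement experiments: an unlabeled peptide competes a high-affinity
fluorescent tracer peptide off a receptor in 384-well plates, and the
change in the tracer's heating response reports the competitor's
affinity.  The package covers the whole chain — equilibrium models, raw
trace processing, per-well quality control, single-dose hit calling,
dose-response K_i fitting, positional-scan profiling and microarray
comparison — plus a synthetic data generator that stands in for the
instrument so every stage can be verified against known ground truth.

## Competitive equilibrium model

One receptor site binds either the tracer T (dissociation constant K_D)
or the unlabeled competitor C (inhibition constant K_i).  Given total
concentrations, the free-receptor concentration R solves the mass
balance

    R (1 + T_tot/(K_D + R) + C_tot/(K_i + R)) = R_tot,

equivalent to a cubic in R with exactly one root giving all free
concentrations in [0, total].  Two independent routes are implemented:

* **Closed form** — the trigonometric solution of the cubic, refined by
  a bracket-safeguarded Newton iteration on the mass balance.  The raw
  trigonometric root suffers catastrophic cancellation when totals and
  constants span many orders of magnitude (relative errors can exceed
  100% on the bound-tracer concentration); the polish restores machine
  accuracy (worst observed deviation from a reference bracketed root
  search: 4e-15 over 5,000 random systems spanning 1 pM – 1 mM).
* **Fixed point** — damped iteration on the free concentrations
  (damping 0.5, relative tolerance 1e-12, at most 10,000 iterations;
  worst case observed ~2,700 iterations).  Serves as the independent
  oracle; the two routes agree to better than 1e-8 relative.

All concentrations are molar internally.  Files and configs carry unit
tags because displacement assays routinely mix nanomolar (tracer) and
hundreds-of-micromolar (competitor) quantities.

### EC50 / K_i conversion

`ec50_to_ki` offers two modes.  `cheng_prusoff` applies
K_i = EC50 / (1 + [T]_free/K_D) with the free tracer evaluated at
half-displacement; it assumes negligible tracer depletion.  `exact`
inverts the competitive equilibrium numerically: it finds the K_i whose
predicted half-displacement concentration equals the EC50.  At the
benchmark working point (receptor 5 nM, tracer 2 nM, K_D 1.54 nM) the
receptor strongly depletes the tracer and Cheng–Prusoff overestimates
K_i by more than two-fold (noiseless check: exact-mode conversion bias
0.24%, Cheng–Prusoff 127%), so `exact` is the default everywhere a K_i
is attached to a fitted EC50.  If even an infinitely strong competitor
at the requested EC50 could not displace half the complex, the EC50 is
below the tracer's resolvable range and a range error is raised — the
tight-binding regime in which the tracer itself must be exchanged for a
weaker one.

## Synthetic trace model

A well's trace is a two-state mixture.  Each state (tracer bound /
free) has a cold-state fluorescence and, after IR-laser onset at t = 0,
relaxes mono-exponentially:

    s_x(t) = f_init_x · (1 + amp_x · (1 − exp(−t/tau_x))),  t ≥ 0.

A well at bound fraction fb emits fb·s_bound + (1−fb)·s_free with
multiplicative i.i.d. Gaussian noise per sample.  This is the simplest
model reproducing the phenomenology (fast post-onset intensity change
reaching a quasi-plateau whose amplitude depends on binding state); no
deeper photophysics is claimed.

Defaults: schedule −1 s to +1.5 s at 100 Hz; tau_bound 0.15 s, tau_free
0.12 s; amp_bound −0.12, amp_free −0.06; equal cold-state fluorescence
(1.0 a.u.); noise CV 0.5%.  The schedule places the hot window on the
quasi-plateau, and the amplitude gap makes a fully displacing
competitor score area ≈ 2 after calibration — comfortably separable at
the 0.5 binder threshold.  Real instruments add features the generator
deliberately omits: well-to-well brightness variation, temperature
drift, photobleaching, correlated noise, and capillary/meniscus optics.
Passing tests therefore demonstrate correctness of the analysis logic
under the stated noise model, not robustness to every instrument
artifact.

Artifact wells: autofluorescence and quenching scale the whole trace by
(1 ± magnitude) (steady-state brightness changes); aggregation adds 1–3
smooth Gaussian bumps (width 0.05–0.3 s) in the heating window, modeled
as positive excursions because aggregate particles transiting the
detection volume transiently brighten the signal; bubbles apply a step
discontinuity at a random time.

## Trace analysis

**F_norm** is the per-mille ratio of hot-window to cold-window mean
fluorescence (defaults: F_0 over [−0.8, 0] s, F_1 over [1.0, 1.4] s —
placement is an instrument convention; the windows sit on stable
baseline and quasi-plateau).  F_norm is invariant under trace scaling.

**QC** flags per well, always reported with their underlying metrics:

* *autofluorescent / quenched*: cold baseline above/below the plate
  median baseline by more than 25% / 20%.
* *aggregated*: two complementary residuals on the baseline-normalized
  heating curve, either of which fires the flag.  (1) deviation of the
  moving-median-smoothed curve from its best isotonic (monotone) fit —
  the direction is chosen by fit quality, keeping verdicts
  deterministic; (2) residual after affine regression onto the
  plate-median heating curve, which also catches bumps that happen to
  reshape the decay monotonically and are invisible to any monotone
  reference.  Thresholds are the larger of an absolute floor (0.015 /
  0.03 normalized units) and a multiple (3 / 6) of the per-trace robust
  noise scale (1.4826 × MAD of first-difference baseline residuals,
  outlier-resistant by construction).  Calibrated on clean vs injected
  plates at default noise: 100% detection at bump magnitude 0.1 with
  <1% false flags, including on strongly displaced (binder) wells.
* *bubble_or_precipitate*: a single-sample step in the high-passed
  first differences exceeding max(0.03, 10 × noise scale × √2).
  Hardware axial-scan verdicts, when exported by an instrument, are
  accepted as external flags and merged.

Absolute floors exist because the score numerators contain smooth
model-mismatch terms of a few 1e-3 that would otherwise be divided by a
vanishing noise estimate on noiseless data.

**Area statistic.**  Each trace is normalized to its own cold-window
mean; the absolute difference between the mean test and mean control
curves is integrated (trapezoid) over the heating window and divided by
a calibration scale.  The scale is chosen per assay configuration so
that a fully displacing competitor scores exactly 2 under the default
photophysics, which keeps the fixed 0.5 hit threshold meaningful if the
photophysics or assay concentrations change.  The absolute (unsigned)
difference is used because the hit call is one-sided on a magnitude
while the sign of the TRIC response depends on the dye.  QC-flagged
wells are excluded before the statistic; a peptide whose test wells all
fail QC is reported unevaluable, never silently zero.  Binders are
`area > 0.5` (strict) among evaluable peptides.

## Dose-response fitting

Series are 12-point, two-fold dilutions by default.  Two models:

* `competitive_exact` (default): least squares over (baseline,
  amplitude, log10 K_i) with the exact displacement equilibrium as the
  forward model.  Initialization profiles log K_i over a grid (the
  model is linear in baseline and amplitude at fixed K_i), then a
  Levenberg–Marquardt polish.  This removes the low-depletion
  assumption that fails near the tracer's K_D.
* `logistic4`: four-parameter logistic on log10 concentration
  (initialized from extreme-concentration means, mid-response EC50,
  slope 1), with K_i attached through the exact EC50 inversion.  Kept
  as a model-agnostic diagnostic; its free slope makes its K_i tail
  noticeably wider than the exact model's at the benchmark conditions.

Fits report both EC50 and K_i with the conversion system echoed.
Pre-conditions: at least 8 QC-passing points spanning ≥ 2 decades,
otherwise the series is *unfittable* (with reason).  If the predicted
response span over the titrated range falls below
max(5 × residual SD, 2 per-mille), the verdict is *no displacement* and
the K_i is censored one-sided as `ki > top concentration` — the span is
judged in-range rather than on extrapolated asymptotes because a
noise-chasing fit can report a huge asymptotic amplitude on a flat
series.  S/N is the fitted response span divided by the residual SD
(the S/N definition is a package convention; several are in use).

**Outlier exclusion** follows an iterative externally studentized
residual rule: after a provisional fit, the single worst point with
|t| > 3.0 (leverage-corrected, linearized Jacobian) is excluded and the
curve refit, at most twice.  A point must additionally have a raw
residual above 0.05 per-mille — studentization is scale-free, and
without the floor, optimizer-tolerance noise on an essentially perfect
(noiseless) fit would be studentized into spurious outliers.  On
noiseless series the rule excludes nothing, exactly; on noisy series
the 3.0 threshold has the usual t-tail, so a clean noisy series
occasionally loses a point (~5–10% of series) — the price of the fixed
threshold, accepted as the method's convention.

**Replicates** are summarized on the linear scale (mean, SD, median,
25–75% quantiles by linear interpolation, whiskers within 1.5 × IQR,
outliers beyond) with a geometric-mean companion, since affinities tend
to be log-normal.

## Libraries, arrays, and the scan comparison

Residue coordinates are 1-based inclusive throughout, anchored by a
configurable parent start so windows carry protein numbering (e.g. the
benchmark 15-mer at positions 414–428).  Overlapping libraries tile a
parent with fixed-length windows (default 15-mers, offset 1);
positional scans substitute each selected position with all 20 amino
acids, WT-identical entries marked.

The synthetic array generator models spot intensity as Langmuir
occupancy of the immobilized variant by the probe protein (default
50 nM) times a capture capacity, with 5% multiplicative spot noise over
3 replicate arrays — typical replicate variability for printed peptide
arrays.  Normalization divides each array by its mean WT-spot intensity
after optional negative-control background subtraction (floored at
zero), then averages across arrays; the matrix is scale-invariant per
array by construction.

The array/TRIC comparison is a Spearman rank correlation between
WT-normalized intensity and −log10 K_i.  Censored (non-displacing)
peptides are ranked jointly below every finite affinity (average ranks)
by default — preserving order information without inventing affinities —
or can be excluded.  In the end-to-end synthetic scan, mutant
affinities span 1.5 decades around the benchmark K_i and each variant's
dilution series starts at 32 × its true K_i, mirroring the experimental
practice of choosing per-peptide starting concentrations; a common
fixed top concentration would place weak variants outside the tracer's
resolvable range and degrade the correlation for reasons unrelated to
the analysis.

## Problem sizes

The test and acceptance workloads use the study's own scales: 1,000
random systems for the solver cross-check, 100 replicate titrations for
recovery statistics, a 220-peptide duplicate screen over 50 noise
seeds, 100 QC plates, and a 100-variant positional scan — sizes chosen
to make the measured rates stable at the stated tolerances.

## Known limitations

* Kinetics (on/off rates), ternary-complex (non-displacing) binding and
  multivalent avidity are out of scope; the dimeric tracer is modeled
  as one species with one effective K_D.
* The trace model is phenomenological; thermophoretic depletion and
  temperature-field spatial structure of full MST are not simulated.
* QC heuristics are software proxies for instrument-internal
  classifiers (axial scans, vendor aggregation models); their
  thresholds were calibrated on the synthetic noise model.
* Working receptor/tracer concentrations for a screen are config, not
  constants — they are assay-specific and must be supplied per
  experiment.
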