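# Methods

`shetca` implements a computational surrogate for bioautography: given an
ordered series of chromatographic fractions of a complex mixture, it asks
which compounds are responsible for a pooled bioactivity readout (e.g. %
DPPH radical scavenging per fraction), using only HPTLC plate photographs
and the fractions' assay values.

## Densitometry model

A plate photograph is a height x width x 3 RGB array. One colour channel
is selected per (illumination, phase) combination: green for normal-phase
plates at 254 nm (the plate fluoresces green and the green channel tracks
absorbing spots best), blue for reversed-phase plates at 254 nm and for
366 nm in either phase (most spots emit blue), and grayscale (mean of R,
G, B) for white-light images before and after derivatization, where spot
colours vary. The profile of a track is the channel mean across the
track's width, trimmed by 1 mm per edge (default band width 7 mm),
sampled at 1000 vertical positions.

Polarity: under 254 nm and white light the background is bright and spots
absorb, so peaks point down; the profile is flipped as `background -
profile`. At 366 nm the background is dark and spots emit; `profile -
background` is used. The background estimate is the per-track median,
which is robust to a handful of bands. A spot the same colour as the
background produces a *negative* peak after orientation; baseline
correction followed by rectification (multiplying negative values by -1)
turns it into a genuine band rather than a baseline distortion.

Pixel/mm conventions are fixed and documented in
`shetca.densitometry`: image row 0 is the plate top, Rf increases upward,
profile point *i* sits at plate-height bin centre (i + 0.5)/n. The
shipped default geometry (application line 8 mm, solvent front 75 mm,
imaged height 97.52 mm) makes the 1000-point profile retain exactly 687
Rf points after cropping to [application, front]; the retained count is
always *computed* from geometry, never hard-coded.

## Baseline correction

Baselines are cubic splines (natural end conditions) through
automatically chosen anchors — a deterministic surrogate for interactive
spline anchoring. The profile is split into windows of 5 % of the Rf
range. A robust line through the window medians (refitted on the closer
half) absorbs slow drift; the noise scale is 1.4826 x the median absolute
deviation of the detrended profile. Each window contributes one anchor
at its "quiet" points (within 3 noise scales of the line); windows
dominated by a peak contribute none, so the spline interpolates across
bands. The rule is deliberately two-sided: a one-sided "lowest
intensities" rule would anchor inside negative-going bands and flatten
exactly the peaks rectification is meant to rescue. Outside the anchor
range the baseline continues linearly with the end slope (clamping to the
end anchor value would ignore drift at the profile ends; the natural
spline's own end cubic can diverge). Fewer than four surviving anchors
triggers a linear fallback, flagged on the result.

## Peak model and detection

Bands are area-parameterised Gaussians

    f(rf) = area / (hwhm * sqrt(pi / ln 2)) * exp(-ln 2 ((rf - c)/hwhm)^2),

whose integral is exactly `area` (hwhm = half-width at half-maximum).
Overlapping bands are deconvolved by bounded least squares on a sum of k
components inside an Rf window (areas >= 0, centres inside the window,
relative cost tolerance 1e-8). Initialisation uses local maxima (or the
assigned band positions in the pipeline), trapezoidal slice areas and
hwhm = window/(4k).

The per-cell detection decision — is compound c present in fraction f? —
is a deterministic surrogate for visual inspection with three parts: the
fitted component must sit at the compound's assigned Rf (within 2 hwhm),
have a plausible width (at most 2.5 x the assigned hwhm), and its area
must exceed 3 x the noise-equivalent area (residual RMSE x hwhm x
sqrt(pi/ln 2), i.e. fitted height above 3 x residual noise). The Rf/width
identification step matters: without it, rectified noise and baseline
ripple are happily fitted as broad pseudo-bands and nearly every cell
"detects". Undetected cells are stored as MISSING (empty CSV cell, NaN
in memory), never as 0 — the distinction carries the sparse-vs-imputed
contrast that motivates the package.

## Association engines

For compound profile x and activity y, both over fractions,

    cov(x, y) = sum (x_i - mean x)(y_i - mean y) / (N - 1)
    rho(x, y) = cov(x, y) / (s_x s_y)           (sample sds, N - 1).

* **HetCA (full)** computes rho over *all* fractions of the zero-imputed
  matrix and calls a compound ACTIVE iff rho > 0 (strict).
* **sHetCA (sparse)** first drops fractions whose activity is below 5 %
  (they contribute nothing but noise and can promote spurious local
  correlations), then uses only the fractions where the compound is
  detected; ACTIVE iff rho > 0 AND cov > 0, both strict. Compounds with
  fewer than 3 usable fractions are EXCLUDED (a correlation over 2 points
  is always +/-1); zero-variance vectors are EXCLUDED as well.

The zero-imputation artefact is mechanical: a compound confined to a few
fractions acquires a long run of imputed zeros wherever *other* compounds
drive the activity, dragging its full-matrix mean and correlation down —
abundance can track activity perfectly inside the detection window yet
yield rho < 0 overall. The sparse statistics are immune by construction.
Ties at exactly zero correlation or covariance are INACTIVE (strict
positivity); the activity filter is applied before per-compound presence
masking.

## Latent-variable models

PLS1 is fitted by NIPALS with sequential deflation on the centred, scaled
matrix (UV: divide by column sd; Pareto: by sqrt(sd); constant columns
dropped). OPLS removes y-orthogonal structured variation first
(orthogonal-signal correction) and fits one predictive component on the
filtered matrix; with zero orthogonal components it reproduces
1-component PLS exactly. Coefficients ("CoeffMLR") are reported in
scaled space; p(corr) is the correlation between the predictive score and
each scaled column; VIP uses the per-component explained-y sums of
squares (predictive component only for OPLS) and satisfies mean VIP² = 1.

Decision rules: coefficient rule — ACTIVE iff CoeffMLR > 0 and p(corr) >
0; VIP rule — ACTIVE iff VIP > 0.6 and p(corr) > 0 (strict thresholds).

Cross-validation is 7-fold with round-robin assignment (observation i in
fold i mod 7), refitting within each training fold (recentred, global
scale weights). Round-robin rather than consecutive blocks is essential
for ordered elution data: holding out a consecutive block removes a
compound's entire elution window, its training column becomes identically
zero, and Q² collapses for structural rather than statistical reasons.
Component counts are grown while Q² improves by more than 0.01 (cap 10).

Validation: 200 response permutations (the model is credible when the
original Q² exceeds every permuted Q²); RMSEE = sqrt(SS_res/(N - 1 - A));
Hotelling T² over all score columns with the F-based 95 % limit; DModX as
the per-observation normalised residual sd with an F-based limit (the
commercial normalisation is proprietary; ours is the standard
approximation); CV-scores from the fold models, sign-aligned to the full
model; CV-ANOVA as an F test of (SS_tot - PRESS)/A against
PRESS/(N - A - 1) — a documented approximation to the published
formulation.

## Synthetic fractionation studies

The generator emulates a centrifugal-partition-chromatography run of an
artificial mixture followed by a pooled radical-scavenging assay:

* **Elution**: each compound's amount is spread over the 69 ordered
  fractions (ids Fr02–Fr70) as a normalised Gaussian on the fraction
  index, with 5 % multiplicative log-normal noise (exact mass
  conservation at zero noise).
* **Activity**: activity_f = 100 (1 - exp(-s · dose_f)) with dose_f =
  sum potency_c conc[f, c] — a saturating cumulative model chosen because
  pooled assays show exactly the masking behaviour it produces (a
  dominant active flattens co-eluting minor actives). The scale s is
  calibrated deterministically so the median dosed fraction sits at 75 %
  activity.
* **Measurement**: densitograms (687 points) are rendered from the same
  Gaussian band model the analysis fits, plus a slow sinusoidal baseline
  drift (amplitude 5) and additive noise (sd 0.3); plate photographs add
  per-pixel sensor noise (sd 0.5 grey levels) which both emulates camera
  shot noise and dithers the 8-bit quantisation so that averaging across
  a track's width recovers sub-grey-level intensity differences.
* **Detection limit**: 1 % of the study's largest concentration; the
  ground-truth masked matrix is MISSING exactly below it.

The default study has 43 compounds (14 active) laid out so that each
active dominates its own detection window (centres every 4 fractions,
sigma 0.8) and inactives sit in the activity valleys between actives.
Planted failure modes: an inactive "shadow" co-eluting with an active
(concentration correlation >= 0.95 — the false-positive mechanism), a
low-abundance active eluting in the dip between two dominant actives
(false negative by overshadowing), an inactive spread thinly across many
fractions, a low-activity leading region (Fr02–Fr19) holding only
inactives, one deliberately overlapping band pair (deconvolution path)
and one band coloured like the plate background (negative-peak path).

What passing tests do *not* show about real data: real plates have
uneven illumination, spot tailing, Rf drift between plates and
compound-specific response nonlinearity, none of which the generator
models; the synthetic study demonstrates that the *mechanisms* (sign
flip under zero imputation, overshadowing, shadow false positives) are
handled, not that real success rates will match.

## Problem sizes

The default study (69 fractions x 43 compounds x 4 illumination modes,
687 Rf points) was chosen to mirror a realistic single-campaign
fractionation; the full rendered pipeline (about 3,000 bounded peak fits)
runs in well under a minute, and permutation validation (200 refits with
7-fold CV) in a few seconds.

## Known limitations

* Compound-to-window assignments are inputs (from the simulator or the
  user); the package does not identify compounds.
* One measurement mode per compound; cross-mode signal fusion is out of
  scope.
* The automatic anchor, detection and component-selection rules are
  deterministic surrogates for interactive choices; their parameters are
  configurable but their defaults were fixed from the module oracles, not
  tuned per dataset.
* DModX and CV-ANOVA follow documented approximations of proprietary
  definitions.
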