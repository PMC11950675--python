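# Methods

`macpolar` turns event-level flow cytometry, antibody-array densitometry,
viability assays and immune-deconvolution outputs into a small set of
robust, comparable summaries. This note documents the models and
conventions behind each stage, the defaults and why they were chosen, and
what the synthetic-data suites do and do not demonstrate.

## Event-level statistics (gating)

Events are filtered with a rectangular live-cell gate: closed intervals on
the scatter channels (FSC for size, SSC for granularity), excluding debris
and doublets the way a manual polygon gate would, but in a form that is
reproducible and testable. No density-based doublet discrimination or
spillover compensation is attempted; channel values are treated as linear
arbitrary units.

Positivity thresholds come from fluorescence-minus-one (FMO) controls: the
threshold for a channel is an empirical percentile (default 99) of the FMO
control's values in that channel, using linear interpolation between order
statistics so thresholds are bit-stable. An event is *positive* when its
value is strictly greater than the threshold — an event exactly at an
FMO-derived cutoff behaves like the control and counts negative. This
convention is fixed and applied consistently in percent-positive,
quadrant-gating and stemness-binning code paths. Quadrant fractions always
sum to 100 before any display rounding.

The per-sample summary of a marker is the median fluorescence intensity
(MFI) of the gated events; even event counts use the mean of the two
central order statistics. A helper enforces the acquisition convention of
at least 20,000 recorded events per sample.

## Robust normalization

Cross-sample marker contrasts use the modified z-score

    z_n = 0.6745 * (x_n - median(x)) / MAD(x),   MAD = median(|x - median(x)|),

computed per feature across the samples of one study (the axis is explicit
in the API, never inferred). 0.6745 is the MAD of the standard normal, so
the score is numerically comparable to a classical z-score but immune to
single extreme samples. Outputs are truncated to [-3.5, +3.5] by default —
the conventional outlier band for this statistic, here interpreted as a
hard truncation; `clip=False` disables it and both behaviors are tested.
No small-sample consistency correction is applied beyond the fixed
constant.

A feature constant across samples has MAD = 0 and carries no contrast; its
z column is set to all zeros and surfaced as a warning rather than an
error (a hard-error policy is opt-in). Treatment effects within one cell
line use log2(treated MFI / control MFI) against the replicate-matched
control, with per-condition medians as the reported summary; non-positive
MFIs are an error, never silently floored.

## Polarization scoring and classification

The M1 score of a sample is the unweighted mean of the modified z-scores
of its M1 markers (CD86, CD80, MHC II, CD274, CD11c); the M2 score is the
mean over CD163 and CD206. Classification is a total, deterministic
function of the pair, evaluated in a fixed order:

1. M1 if m1 > 0.5 and m2 < 0;
2. M2 if m2 > 0.5 and m1 < 0;
3. Unpolarized if both scores are negative;
4. Mixed otherwise.

The Mixed fallback makes the function total: a rule set with Mixed defined
only as "neither score beyond ±0.5" would leave pairs like (0.6, 0.6)
unclassified. Strength uses the type-congruent score — m1 for an M1 call,
m2 for an M2 call, max(|m1|, |m2|) for Mixed; Unpolarized is always
"none". The score is rounded to one decimal and binned: none below 0.5,
moderate in [0.5, 1] (closed on both ends), strong above 1 (strict). The
rounding step reflects how such score tables are reported at one-decimal
precision (0.47 reads as 0.5, i.e. moderate); it is a flag (default on)
because the unrounded rule is equally defensible, and the test suite pins
down exactly which published rows are sensitive to it. These choices
reproduce all eight published (score pair, type, strength) rows of the
eight-cell-line co-culture study the defaults are modeled on.

Because the z-transform is relative to the sample set, adding or removing
a sample re-normalizes every column and can change classifications; that
is a property of the method, not a defect, and is covered by a test.

Stemness expression (CD44, CD133, ESA percent-positive) is binned low
(< 10%), moderate (10–40%) and high (> 40%).

## Cytokine arrays and association screening

Duplicate membrane spots are aggregated per analyte by their mean
(configurable in principle; mean is the common densitometry-plugin
behavior). Background subtraction of the mean negative-control intensity,
floored at zero, is available but off by default. Cross-sample
normalization reuses the modified z-score; "top expressed" analytes of a
sample are those with z at or above a cutoff (default 1.0 — the real
cutoff behind published per-line analyte lists is not recoverable without
the raw membranes, so the default is a documented choice).

Associations between analyte signal intensity and marker MFI are Pearson
correlations on the raw values (z-scores are a display transform only):
two-sided p from the t statistic with n−2 df, 95% CI via the Fisher
z-transform (degenerating to [r, r] at |r| = 1, flagged), and
Benjamini–Hochberg adjustment at a 10% FDR across all analyte × marker
pairs of one call — one BH family per screen, configurable by splitting
calls. Zero-variance series make a pair "undefined" and exclude it from
the family instead of fabricating r = 0. Both the raw p < 0.05 flag and
the q ≤ 0.10 flag are reported, since screening practice uses both.

## Inference

* **Mann-Whitney U** (two groups): midrank ties; exact p by full
  enumeration of all C(n+m, n) assignments when n + m ≤ 12, two-sided p
  defined as the doubled smaller tail probability capped at 1 (conventions
  differ across software; this one is fixed and tested against brute
  force). Larger samples use the tie-corrected normal approximation, and
  every result records which route produced it. With n = 3 per arm — the
  in vivo design size — the exact two-sided p can never go below 0.1; the
  result's `exact` flag makes this floor visible instead of hiding it
  behind an asymptotic p.
* **One-way ANOVA** with post-hoc pairwise t tests against a named control,
  Holm-adjusted (the typical control-vs-treatment asterisk pattern);
  all-constant input returns p = 1 with a zero-variance flag.
* **Chi-square** test of independence without continuity correction
  (Yates correction is a flag for 2×2 tables).
* **BH-FDR** step-up adjustment, default alpha 0.10.

**IC50** is read off the dose-response curve the way it is read off a
plot: average replicate viabilities (% of untreated control) per dose,
find the first adjacent dose pair whose means bracket 50%, and
interpolate linearly on log10(dose). Curves that never cross 50% are
censored at the dose-range edge ("> max dose" / "< min dose") rather than
extrapolated; extra crossings of a non-monotone curve are flagged. A
constrained four-parameter-logistic fit is provided only as a cross-check
in synthetic-recovery tests, not as the estimator.

## Deconvolution fractions

Expression matrices are filtered by dropping genes with TPM < 1; the
aggregation across samples is "at least one sample ≥ threshold" by
default — the least destructive reading of a per-gene low-expression
filter — with "all" and "mean" rules available. The filter is idempotent.

Per-sample M1/M2 ratio is the quotient of the two infiltration scores; a
zero M2 score yields an undefined-flagged ratio, not infinity. Group
shifts are fold changes of group medians versus the control group (medians
because infiltration scores at n = 3 are summarized as median ± IQR;
mean-based fold change is a flag), paired with the exact Mann-Whitney test
above.

## Synthetic data

Every generator is a pure function of its config (seed included) and
draws from numpy's PCG64 `default_rng`, with independent named streams per
generator so outputs are reproducible byte-for-byte.

* **Flow events** (default 20,000/sample, the acquisition minimum): each
  fluorescence channel is a two-component lognormal mixture (negative
  median 100 a.u., positive 1000 a.u., log-sd 0.35) with a planted
  positive fraction; the planted positivity threshold is the geometric
  midpoint, where component overlap is negligible. Scatter channels place
  a known debris fraction (8%) below a known rectangular gate, so gate
  retention is predictable. Lognormality matches the right-skewed,
  strictly positive character of fluorescence data; spectral spillover and
  autofluorescence are deliberately not modeled.
* **MFI panel study**: eight virtual cell lines × the seven-marker panel.
  Each line has an (M1-marker, M2-marker) effect pair in MAD units —
  two strong inducers (+2 on own markers, −1 on the opposite set), two
  moderate, two near-neutral, one unpolarized, one mixed — mapped onto
  log-MFI with a profile scale of 0.35 log-units per MAD unit around
  plausible per-marker baselines, plus multiplicative lognormal noise
  (CV 15%). Because the eight profiles differ, the cross-line MAD of every
  marker is set by the profile spread, not the noise: with noise off the
  scoring pipeline recovers the planted types exactly, and at CV 15% the
  per-marker z noise (≈0.3 sd) is small against the planted contrasts — a
  design-time power analysis, not a tuned number.
* **Cytokine study**: three linked analytes built on the log scale as
  ρ·z(marker) + √(1−ρ²)·noise against the standardized log-MFI of their
  marker (planted ρ = 0.95) plus six independent distractor analytes — an
  array reduced to desk scale, with the distractor count chosen so the
  maximum null |r| at n = 8 stays below the linked r with high
  probability.
* **Dose-response**: 4PL viability 100/(1 + (dose/IC50)^h) on the decade
  grid 0.01–100 µM, true IC50 3 µM, Hill 1, additive noise sd 2% of
  control, 3 replicates per dose.
* **Fraction study**: six arms (untreated control, four monotherapies, one
  quadruple combination), n = 3 per arm; baselines around total
  macrophages 0.45 with M2 0.30 and M1 0.08; two arms carry a planted
  0.5× shift of M2 (and total) macrophages; lognormal noise CV 10%.

## What the synthetic suites show — and what they do not

Passing recovery tests demonstrate that the pipeline's statistics recover
effects of the designed size under the designed noise; they do not
validate the biology of any real co-culture, membrane or tumor. The
published quantities that would require the study's own raw data — the
raw MFI values behind the published polarization-score table, the
cytokine-array intensities behind the published correlation panels, the
measured IC50s, the treatment heatmaps and the in vivo fraction values —
are not reproducible from code alone: they live in the deposited raw
dataset (ArrayExpress accession E-MTAB-14915) and external cohorts, and
are replaced here by property-based and planted-parameter recovery
suites. The published classification *rules*, by contrast, are fully
checkable and are reproduced exactly on the printed score pairs.

## Numerical conventions

Empirical percentiles: linear interpolation. Positivity: strict
inequality. Strength bins: closed [0.5, 1], strict above 1. Exact
Mann-Whitney tail counts use a 1e-9 comparison tolerance on midrank U
values (which are multiples of 0.5). MAD = 0 columns: zeros + warning.
Fisher CI at |r| = 1: [r, r]. Censored IC50s carry the bounding dose in
the result, never a numeric stand-in. Problem sizes in the recovery
suites (100–500 seeds, 10^6 draws for the normal-MAD estimate) were
chosen so each Monte-Carlo band is decisive at desk scale.
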