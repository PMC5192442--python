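# Methods

## Bin grids and the spectrum format

A binned spectrum is a vector of non-negative intensities on a fixed,
solvent-specific chemical-shift grid: 716 bins spanning 0.5–9.0 ppm for D₂O
extracts, 547 bins spanning 0.5–7.0 ppm for CDCl₃. The grid is *defined* by
(n_bins, shift_min, shift_max); the bin width follows as
(shift_max − shift_min)/n_bins (≈ 0.011872 ppm and 0.011883 ppm
respectively), bins are half-open intervals labeled by their centers, and a
file row is matched to the bin whose center lies within half a bin width of
the row's chemical shift. Rows may therefore appear in ascending or
descending ppm order (instrument exports differ). The reader enforces the
exact row count, rejects shifts that match no bin, clamps negative
intensities to zero with a logged warning (bench-top phasing artifacts), and
skips `#` comments and blank lines. The writer emits shifts at 10
significant digits and intensities at 17 (full float64 round-trip).

## Preprocessing pipeline

Order: **mask → noise filter → normalize**, applied identically to the query
and to every database spectrum it is compared with, using the query's mask.

1. *Region mask.* Up to three [low, high] ppm intervals are zeroed; any bin
   whose center falls inside an interval is set to exactly 0. The primary
   use is residual solvent peaks (e.g. HDO near 4.8 ppm).
2. *Noise filter.* Bins below max(intensity)/75 are zeroed. Idempotent and
   scale-equivariant.
3. *Normalization.* qᵢ ← qᵢ / Σⱼ qⱼ². The divisor is stored on the result so
   the raw scale is recoverable. A unit-Euclidean-norm variant is available
   via `method="euclidean"`; all statistics accept the switch, which only
   rescales D and covariance magnitudes.

The mask runs first because a masked region must be ignored by *all* further
computation: were the noise filter applied first, a large solvent peak would
set the max/75 threshold and erase genuine metabolite bins before the mask
could remove it; were normalization applied first, the solvent peak would
dominate the normalizing sum. The division by Σq² (rather than √Σq²) is the
literal reading of the normalization rule this engine implements; the
normalized vectors are not unit length, so inter-spectrum distances reflect
both pattern and effective line count.

## Database

SQLite (single file or in-memory), six tables: `Spectrum` (name, solvent),
`Tag` / `SpectrumTag` (free classification labels), `Bin` (one row per grid
bin per solvent, materialized once), `BSpectrum` (raw intensities, one row
per bin — spectra round-trip bit-identically), `Feature` (tasting or
hardness records; tastings validated as integers 1–5, hardness as positive
reals; multiple records per spectrum are expected, one per panel
evaluation). Foreign keys cascade, so deleting a spectrum removes its links
and features. Raw intensities are stored; preprocessing happens at query
time with the query's own mask, and preprocessed matrices are cached per
(solvent, mask, normalization method) until the next write.

## Similarity search

D(q, Q) = Σᵢ (qᵢ − Qᵢ)² on preprocessed vectors. Hits are database spectra
with D ≤ threshold (inclusive), sorted ascending, ties broken by spectrum id
for reproducibility. Cross-solvent comparison is an error. The sensitivity
profile queries every database spectrum against the whole partition
(equivalently, the distribution of all pairwise distances) and reports hit
counts at thresholds {0.01, 0.02, 0.05, 0.1, 0.2, 0.3} along with each
spectrum's PC1 score; `recommend_threshold` operationalizes the rule of
thumb that a query hitting more than half its partition needs a lower
threshold, returning the largest grid threshold under that budget.

## Association statistics

The unit of analysis is the *feature record*: a hit spectrum with k
tastings contributes k (q, t) pairs, so P counts records, not spectra.
Per bin i over the P pairs:

- covariance cᵢ = (Σⱼ qᵢⱼtⱼ)/P − q̄ᵢ·t̄ (population convention, divide by P;
  q̄ᵢ is the per-bin mean over the P linked vectors);
- Pearson rᵢ with two-pass centering; bins with zero intensity variance, or
  a zero-variance feature sample, yield NaN — "undefined" is distinct from
  "no association" on this axis;
- estimated score A = Σwⱼtⱼ/Σwⱼ, wⱼ = 1/(Dⱼ + D̄ + 1), with D̄ averaged over
  the P feature-linked similarities (a spectrum's D counted once per
  record). A is a convex combination of the tⱼ, hence always inside
  [min t, max t]; when all Dⱼ are equal it reduces to the arithmetic mean;
  adding a constant to all scores shifts A by that constant. If any Dⱼ = 0
  (complete matches), the plain mean over those P′ records is reported
  separately.

P = 0 yields a "no result" signal (None), not an exception; P = 1 gives an
all-zero covariance and an all-undefined correlation (with a warning).

## PCA summary

Mean-centered, unscaled PCA (full SVD) of the preprocessed, unmasked
partition — the same view of the data the similarity engine sees. Signs are
fixed so each loading's largest-magnitude element is positive. The group
separation test is Welch's two-sample t-test on PC1 scores between
tag-bearing spectra and the rest; it is a descriptive convenience, skipped
with a warning when a group has fewer than two members.

## Synthetic data generator

The generator emulates 60 MHz bench-top spectra of food extracts so that
every statistic can be validated against known ground truth.

*Spectra.* Each group (fish-like, vegetable-like; 24 spectra per group by
default) has a template of Lorentzian multiplets at marker-metabolite
shifts: fish — lactate (1.31 ppm doublet, J ≈ 0.12 ppm), creatine
(3.03, 3.92 ppm), TMAO (3.26 ppm), histidine (7.28, 7.89 ppm); vegetable —
sugar resonances between 3.2 and 5.6 ppm (glucose 3.47 ppm and neighbors).
Half-width at half-maximum is 0.03 ppm (≈ 2.5 bins), the broad-line regime
of low-field instruments. The lactate doublet carries a roofing skew of
0.05 toward its downfield coupling partner — the strong-coupling tilt seen
at 60 MHz — which also makes the doublet's template maximum unambiguous.
Per-spectrum, per-peak amplitudes are jittered lognormally and a half-normal
noise floor (SD 1% of the tallest template line) is added; intensities stay
non-negative, and a fixed seed reproduces the dataset byte for byte.

*Amplitude variability.* Background metabolites vary with CV 0.12; the
score-driving metabolites (lactate for tasting, TMAO for hardness) vary with
CV 0.5, reflecting that freshness- and processing-linked metabolites are the
ones that swing within a food group. The moderate *amplitudes* of the
planted peaks (0.5 and 0.8) are deliberate: under sum-of-squares
normalization a peak holding a large share of the total power has its own
normalized variance self-suppressed (its amplitude enters both numerator and
denominator), which would make the planted bin invisible to covariance
mapping. Keeping the planted peaks' power share small preserves a nearly
linear response at their bins.

*Scores.* Tasting for fish spectra is round(3 + slope·z + ε) clipped into
{1…5}, where z is the standardized preprocessed intensity at the planted
lactate bin, slope 1.2 score-units per SD, and ε ~ N(0, 0.4); vegetable
tastings are noise around 3 with no association. Each spectrum receives 2–6
tasting records (matching the several-evaluations-per-sample density of
real panel data). Hardness is 10·exp(0.25·z_TMAO + N(0, 0.05)) — a positive,
monotone response with multiplicative noise — recorded for 80% of spectra.
The generator returns the planted bin indices (the template-argmax bin of
each planted multiplet) as ground truth.

*What the generator does not emulate:* chemical-shift drift with pH or
temperature, peak overlap between groups, baseline roll, solvent-suppression
artifacts, J-coupling beyond first-order multiplets with a fixed roofing
tilt, and inter-panelist bias. Passing tests therefore demonstrate that the
statistics recover associations planted under ideal alignment — they say
nothing about robustness to misaligned or drifting real spectra, which would
need alignment preprocessing outside this package's scope.

## Numerical choices and degenerate inputs

- Normalizing an all-zero spectrum (possible after aggressive masking) is an
  error for a query; all-zero database spectra are skipped from comparisons
  with a warning.
- Threshold comparison is inclusive (D ≤ t); hit ties are ordered by id.
- Correlation values are clipped to [−1, 1] against float rounding.
- Tasting validation accepts integral floats (3.0) but rejects 3.5.
- PCA requires at least k+1 spectra; the separation test requires two
  non-empty groups, at least two members each.

## Problem sizes

Default simulations use 24 spectra per group (48 total, 716 bins), 2–6
tastings per spectrum, and 100 replicates for the recovery experiments —
sizes at which the complete test suite and the acceptance script each run
in well under a minute on one core while leaving the Monte-Carlo margins
(recovery rate, null z-score) comfortably resolved.

## Known limitations

- No spectral alignment: bins are compared positionally, so shift drift
  directly degrades D and the association spectra.
- The covariance spectrum is descriptive; no significance testing or
  multiple-comparison control across bins is attempted, and metabolite names
  attached to peaks are annotation metadata, not inferences.
- Estimated scores inherit the biases of the hit set: in crowded database
  regions a permissive threshold mixes unlike samples (hence the
  sensitivity profile and threshold guidance).
- Cross-solvent search is intentionally unsupported; the two partitions are
  different measurement spaces.
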