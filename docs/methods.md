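# Methods

This note documents the statistical procedure implemented by `arraymeta`,
the choices made where the design space was genuinely open, and what the
synthetic validation does and does not demonstrate.

## Pipeline model

The package operates on *already normalized* expression matrices; it
performs no background correction, quantile normalization or batch
adjustment.  Each study contributes one probes × samples matrix, a
gene → probe annotation, and a partition of samples into groups with one
designated control group.  The unit of comparison is the
(study, non-control group) pair: every downstream quantity — ratio,
*t*-test, merged column — is that group versus its own study's control.

### Scale resolution

Log2 and linear studies are mixed freely in public repositories.  Two
modes:

* **manual** — a whitespace-delimited `NOLOG` token in the study folder
  name marks the study as linear; everything else is taken as log2.
* **auto** (default) — a study is considered log2 if its largest finite
  intensity is ≤ `auto_log_threshold` (default **50**, configurable).
  Normalized log2 intensities essentially never exceed ~16, while linear
  intensities run into the thousands, so any threshold in roughly
  [20, 1000] separates the regimes; 50 leaves headroom for unusual
  normalizations on both sides.  The decision is logged per study and
  should be spot-checked by the user.

Linear values must be strictly positive; a non-positive value in linear
data is a hard error naming the cell, rather than a silent offset that
would distort every ratio.  The boundary is inclusive (max = threshold ⇒
log2).

### Probe collapsing

Genes measured by several probes are collapsed to one per study:

1. Probes are ranked by an ordered suffix whitelist supplied in the
   annotation (Affymetrix-style specificity endings, best first).  A
   probe's rank is the list position of its **longest** matching ending —
   matching longest-first prevents `_at` from swallowing `_s_at`.  With a
   non-empty list, probes matching no suffix are excluded; with an empty
   list all probes rank equally.
2. Among minimum-rank probes, the one with the highest mean (or median,
   per configuration) control-group intensity wins — the brightest probe
   in the reference condition is the one most likely above background.
3. An exact tie keeps the first probe in annotation order (deterministic
   and logged).  A gene whose probes are all excluded is dropped with a
   warning.

### Ratios

Ratios are log2 fold changes: center(group) − center(control) on the log2
scale, with center either mean or median.  Working on the log2 scale
makes fold changes additive and comparable across studies regardless of
their original scale, and is the scale on which the *t*-test operates.
Missing cells are excluded sample-wise; a group with no non-missing
values for a gene yields a missing ratio.  Samples are grouped by the
declared design, not by column order in the data file.

### Merged table

One spreadsheet: rows = genes (in gene-list order), columns = one per
(study, group) comparison, with study number, group name and both sample
sizes carried in header rows and the column labels repeated in a final
`Labels` footer row.  The footer is what makes hand editing safe: users
can sort rows and delete genes or columns in a spreadsheet tool, and the
loader reconstructs column identity from the surviving labels.  The first
column and the footer must remain intact; violations are explicit
validation errors.

### Filters

Three optional hygiene filters, applied in a fixed order with defaults
N ≥ 5 per group, ≥ 5 studies per gene, ≥ 75 % direction agreement:

1. drop columns whose group N is below threshold;
2. drop genes with non-missing ratios in fewer than the minimum number of
   *distinct studies*;
3. drop genes without a sufficient direction majority.  Direction is
   assessed **per study** (a study with several disease groups casts one
   vote: the majority sign of its cells; an exact within-study tie, or
   all zeros, counts for neither side), and the agreement fraction is
   dominant-direction studies over all studies contributing at least one
   non-missing cell.  The per-study reading was chosen over per-column
   because the criterion is "fraction of *studies* agreeing"; both
   denominators coincide for single-group studies.

The agreement boundary is inclusive (exactly 75 % is retained).  Filters
are monotone in every threshold and idempotent (property-tested).

## Statistics

### Per-study test

A two-sample pooled-variance Student's *t*-test (df = n₁ + n₂ − 2) per
gene and comparison, on log2 intensities; Welch's correction is available
behind a flag.  The reported p is **one-tailed in the observed
direction** (p₁ = p₂/2) with direction = sign of the mean difference;
equal means give p₁ = 0.5 and direction 0.  Fewer than two non-missing
values on either side makes the comparison untestable; untestable results
are excluded from combination and logged.  The direction is data-driven
per comparison, not fixed a priori per gene.

### Stouffer's Z-transform (default)

Zᵢ = Φ⁻¹(1 − p₁,ᵢ)·sᵢ with sᵢ the direction sign, combined as
Z_s = Σ Zᵢ / √N and converted to a two-sided p_s = 2(1 − Φ(|Z_s|)).
Notes:

* Φ⁻¹(1 − p) is evaluated as the normal inverse survival function, so
  small p gives a large positive Z before the sign is applied.
* √N is the canonical denominator, under which Z_s is standard normal
  when the inputs are; a plain-average Σ Zᵢ / N variant is provided as a
  configuration switch for compatibility with tools that print it, and is
  strictly conservative (Var = 1/N).
* Since the per-study p₂ is exactly uniform under the null (Gaussian
  data, exact *t*), Φ⁻¹(1 − p₂/2)·sign(t) is exactly standard normal, so
  the Stouffer null is exactly calibrated — the simulation below measures
  0.049 at nominal 0.05.
* Scores are unweighted by design; weighted Stouffer and random-effects
  models are out of scope.

### Fisher's method

χ² = −2 Σ ln p₁,ᵢ on 2k degrees of freedom, with a consensus sign by
majority vote of directions (an exact vote tie yields sign 0).

**Calibration caveat.**  Fisher's method assumes its inputs are uniform
on (0, 1) under the null.  One-tailed p-values taken in the *observed*
direction live on (0, 0.5], which shifts the null statistic upward by
2k·ln 2 and makes the method anticonservative: at k = 6 the nominal 0.05
level corresponds to an actual rate near 0.38 (measured by
`scripts/acceptance.py` and the test suite).  This is a property of the
procedure as defined — one observed-direction tail fed into a sign-blind
combiner — and is reported rather than silently corrected; for calibrated
inference use the Stouffer method, whose signed construction absorbs the
direction information correctly.

p-values are clamped to [1e−300, 1] before Φ⁻¹/log with a logged warning;
combined p-values are floored at the smallest positive float rather than
reported as 0.

No multiple-testing correction is applied by default (raw combined p per
gene); an optional Benjamini–Hochberg column can be switched on.

## Synthetic data

`arraymeta.synth` emulates a multi-cohort disease-vs-control
meta-analysis at the scale of a typical curated case study: defaults are
12 studies, 2 groups each, 8 samples per group, 288 genes, 1–3 probes per
gene, i.i.d. Gaussian noise with σ = 1 on the log2 scale, baseline
intensities ~ N(8, 1), and an `_at`/`_s_at`/`_x_at` suffix scheme.  Eight
samples per group is representative of public heart-disease cohorts and
sits above the N ≥ 5 filter; σ = 1 is a typical within-group log2 SD for
microarray data.  Injected genes receive a constant log2 effect in every
non-control group; designated "true" probes sit 3 log2 units above their
decoys, so control brightness identifies them deterministically at n = 8.
Studies can be emitted on linear scale (values 2^x, `NOLOG` folder
token).  A single integer seed drives everything; identical configs yield
byte-identical trees.

What this generator does **not** model: batch and platform effects,
probe-specific affinity and cross-hybridization, heavy-tailed or
heteroscedastic noise, correlated genes, missing-not-at-random values,
and annotation drift between platforms.  Passing the validation suite
therefore demonstrates correctness of the pipeline's arithmetic and
logic under its own assumptions (independent Gaussian log2 noise, honest
annotations), not robustness to real-data artifacts.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 2000 null genes × 6
studies (n = 8/group) for null calibration, judged against the binomial
99 % interval; 500 effect genes (|Δ| = 1, alternating sign) plus 200 null
genes across 12 studies for sensitivity (threshold p < 0.001 with correct
sign, expected > 0.9) and for the Stouffer-vs-Fisher median comparison;
a 4-study/40-gene pair of trees for linear-vs-log2 equivalence (agreement
to 1e−9); and 100 genes × 3 studies with 2–3 probes each for
probe-selection accuracy.  Twelve studies for the sensitivity run matches
the generator's default study count; at the same per-study power a
6-study design has true sensitivity ≈ 0.92, close enough to the 0.9
criterion that a 500-gene sample would fail it by noise alone in a
non-trivial fraction of seeds.  Effect recovery is judged on the grand
mean of merged ratios over all injected cells (within 3 SE of the
injected Δ); individual cells have SE = σ√(2/n) = 0.5 and are not each
required to sit within 3 SE, which would be violated by chance ~0.3 % of
the time.

## Known limitations

* Identifier matching is exact and case-sensitive; no symbol aliasing or
  cross-platform ID reconciliation.
* One test per (study, group): a study with several disease groups
  contributes several — correlated — p-values to the combination (they
  share the control sample).  The combination treats them as
  independent, which overstates evidence for multi-group studies; the
  per-study direction vote in the filters partially compensates.
* Fisher's method is anticonservative as described above.
* The auto log2 heuristic can be fooled by unusual normalizations
  (e.g. z-scored data); the per-study log line exists so users can
  verify it.
* No random-effects model: between-study heterogeneity is not estimated,
  matching the fixed-combination design.
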