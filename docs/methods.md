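# Methods

## Data model

A cohort is a complete panel: every subject has exactly one z-score per
scheduled visit, for a single measure (zWFL, zWA or zMUAC). Visits are
aligned by nominal `visit_index`; age in months is metadata used only by
mBIV's time window. Complete-case enforcement is deliberate — the study
designs this toolkit targets exclude children with any missing
measurement, and every detector averages per time-point, which requires a
rectangular grid. Irregular schedules and missing visits are out of scope
(distance measures tolerant of missingness, such as Fréchet distance,
would be the natural extension).

## Detectors

All standard deviations use the population divisor *n*. This is a
convention choice (the alternative, *n − 1*, changes flags only at the
margin) made so that MMOM with a single cluster reduces *exactly* to
SMOM, which the test suite asserts.

* **sBIV** flags z strictly beyond fixed per-measure limits — defaults
  zWFL (−5, 5), zMUAC (−5, 5), zWA (−6, 5), the WHO flag limits. Strict
  inequality means boundary values pass; cut-offs are configuration, not
  code.
* **mBIV** clears an sBIV candidate if any *other* measurement of the
  same child, within ±24 months of age (symmetric window), lies within
  2 z-units of the candidate. The candidate itself is excluded from its
  neighbour set. A child with no in-window neighbours keeps the flag
  (vacuous confirmation).
* **SMOM** flags |x − mean| > 2 SD per visit column. A zero-SD column
  flags nothing.
* **MMOM** first clusters whole trajectories with k-means (Euclidean,
  k-means++ initialization, 10 restarts, fixed seed; default k = 2, the
  group count typically found in infant growth cohorts), then applies the
  SMOM rule within each cluster. k is configurable; the VAT ordering in
  the patterns module supports choosing it by inspection.
* **COT** builds a complete-linkage hierarchy on Euclidean trajectory
  distances, cuts it into `nc = max(2, ⌊n/10⌋)` clusters (floor division;
  the max(2, ·) guard binds below n = 30), and flags all members of
  clusters strictly smaller than the average size n/nc. "Small" is the
  one genuinely open definition here; the threshold is configurable as an
  absolute size.
* **MMOT** computes each member's RSS to its k-means cluster's per-visit
  mean trajectory (plain cluster mean, not leave-one-out) and flags
  RSS > mean + 2 SD of the within-cluster RSS distribution. The rule is
  one-sided by intent: only fitting *badly* is anomalous. Singleton
  clusters are skipped (no RSS spread to threshold against).

Determinism: every stochastic step takes an explicit seed. sBIV, mBIV,
SMOM and COT are exactly equivariant under subject reordering; MMOM and
MMOT are equivariant up to k-means local optima, which fixed seeding and
10 restarts make stable on separated data.

## Synthetic outlier injection

Error magnitudes are deterministic — intensity × the relevant SD (σ = 1
for types a/b, the subject's own trajectory SD for type c) — with only
the sign random for types a and c; type b is always positive and applies
to the absolute value, modelling extreme implausible spikes. Whether
type b should preserve the original sign is ambiguous; `perturb` isolates
the rule so either convention is a one-line change. The per-type count is
round-half-up(rate × n), which reproduces the documented 157/382/361
per-type counts on the three population shapes. Cells are drawn uniformly
without replacement and never double-flagged, so ALL-type injection at 5%
per type contaminates exactly 15% of cells; on the 849 × 9 cohort this
touches ≈ 650 subjects at ≈ 1.76 outliers each. The concentrated mode
(30% of children, 4 outliers each, types cycled a, b, c, …) keeps the
total count while packing errors into fewer children.

## Evaluation

Measurement-level truth is the exact injected cell; trajectory-level
truth is any subject with ≥ 1 injected cell. The universe is all cells
(respectively all subjects), so specificity is computed over genuinely
clean units. Undefined ratios (zero denominator) are NaN, never 0, and
are excluded from repetition averages with the missing count reported —
silently coding them as 0 would bias low-intensity summaries where
detectors often fire nowhere. Kappa uses the standard chance-corrected
form on the 2 × 2 table. The experiment runner redraws cohort noise *and*
injection each repetition by default (a fixed-cohort mode exists for
variance decomposition); per-repetition seeds are spawned deterministically
from the master seed, and the same repetition seeds are shared across grid
cells so intensity comparisons are paired.

## Growth patterns and impact

Pattern detection uses the same complete-linkage hierarchy cut at k = 2.
Membership agreement between two partitions is computed by maximizing the
matched mass over one-to-one label matchings (Hungarian assignment on the
contingency table) and dividing by n. This definition matters: greedy or
majority matching can differ by several points, so it is stated here
prominently. Externally produced partitions (e.g. from latent class mixed
models, which this package does not fit) can be read from CSV and scored
with the same function. Group curves are per-visit cluster means passed
through LOESS (span 0.75); on linear data the smoother is exact.

## Synthetic cohorts

The generator emulates the published shapes of the target populations:
z_ij = intercept_g + slope_g·t + curvature_g·t² + u_i + ε_ij with
multinomial group assignment. Preset intercepts/slopes encode the verbal
cluster descriptions ("severe wasting, increase within abnormal levels"
≈ −3.5 rising to ≈ −2.7; "wasting, increase to normal" ≈ −3.0 rising to
≈ 0; and analogous zWFL/zMUAC pairs), with group weights proportional to
the reported cluster sizes (199:194, 490:359, 634:168). Within-cohort
variance components are unpublished; the defaults subject_sd = 0.8 and
noise_sd = 0.3 z-units are documented placeholders chosen to give
realistic overlap between groups, and are configurable. Per-subject
random sub-streams mean enlarging a cohort never reshuffles existing
subjects. The generator does not model edema, measurement rounding,
digit preference, visit-date jitter or correlated device error — so
passing tests demonstrate behaviour under idealized Gaussian noise, not
robustness to every real-world artifact.

## Problem sizes and known limitations

Trend tests average 20 repetitions on the 393 × 8 preset; the stochastic
injection summaries use 200 seeds on the 849 × 9 preset; the normal-tail
check uses 10⁶ cells. Two documented behaviours are worth knowing:

* Under ALL-type 15% contamination, COT's sensitivity rises with
  intensity only up to ≈ 3 SD and then declines slightly: most subjects
  then carry an injected cell, while COT can only flag members of small
  clusters (a structural ceiling near 0.5), and at high intensity type-b
  spikes make contaminated trajectories mutually similar enough to form
  *non*-small clusters. COT is best read as an isolation detector for
  sparse, idiosyncratic trajectory anomalies.
* Clean-vs-contaminated membership agreement declines with intensity on
  average but is noisy run-to-run; single-seed sweeps (as in example 06)
  can be non-monotone.
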