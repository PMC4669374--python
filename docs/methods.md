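# Methods

This note records the models, parameter choices and numerical conventions
behind soilpah, and what the synthetic-data tests do and do not establish
about real data.

## Indices and their reading of the raw data

**CFU conversion.** `cfu = a · n · (100/%DM) · 10³` is applied per plate;
replicate aggregation (means of 3 plates) always happens downstream, never
inside the conversion, so plate-level variability remains available.

**CD (colony development).** The literature formula is written with daily
counts "expressed as a percentage of the total" and an outer factor of 100,
which read literally would yield values up to 10 000 while the index is
described as ranging 0–100. soilpah therefore treats the daily values as
proportions (0–1), giving `CD = 100 · Σ fᵢ/i ∈ (100/D, 100]` — the
range-consistent reading. Closed forms used as anchors: point mass on day
1 → 100; uniform over 10 days → 10·H₁₀ = 29.2897; point mass on day D →
100/D.

**EP (ecophysiological diversity).** Base-10 Shannon entropy of the daily
proportions with the standard convention 0·log 0 = 0. The log base is fixed
to 10 (EP ∈ [0, log₁₀ D], i.e. [0, 1] for the 10-day window); a natural-log
variant exists as an explicit option only.

**RS (soil resistance).** `RS = 1 − 2|D₀|/(C₀ + |D₀|)` is computed by
default from treatment means, because the published tables are means of 3
replicates; a replicate-paired variant (pair replicate k with control
replicate k, average the per-pair RS) is provided but not default. RS is
symmetric in the sign of the disturbance and strictly decreasing in its
magnitude; RS = 1 iff the treated value equals the control.

**SG/RI (Phytotoxkit).** A and B are pooled over the three replicate
plates: germination as total germinated-seed counts (scale invariance makes
counts vs percentages immaterial), root growth as the mean root length of
germinated seeds. Trials run at the single assay dose of 4000 mg kg⁻¹ DM.

## ANOVA, η² and letter displays

The design is balanced and fully crossed (4 types × 4 doses × 3
replicates; the shared dose-0 control is entered once per type column, the
faithful-to-tables reading even though it double-counts the control soil).
Sums of squares are computed by explicit mean subtraction; F statistics use
the error mean square; p-values come from the F distribution. Unbalanced
layouts are rejected rather than approximated — Type I/II/III distinctions
are deliberately out of scope. η² = 100·SS_term/SS_total; the four shares
sum to 100 exactly and are invariant under affine rescaling of the data.

Tukey homogeneous groups use the studentized-range quantile
(`scipy.stats.studentized_range`; a seeded Monte-Carlo estimator is
available as a fallback and cross-check). With equal group sizes the
"not significantly different" relation is a threshold graph on the sorted
means, so its maximal cliques are maximal runs of consecutive means
spanning ≤ HSD; each run receives one letter, giving the biconditional
"share a letter ⇔ not significantly different" by construction. Letters are
assigned from the smallest mean upward ('a' = lowest group), matching the
convention of the published tables; ties in means keep input order, and a
descending option exists. α defaults to 0.01.

**Replicate injection.** Published tables carry cell means only. For
replicate-requiring stages a deterministic zero-sum residual pattern
(+δ, −δ, 0) is injected into every cell, with δ chosen so the error term
takes a specified share of SS_total. This preserves cell means exactly and
is synthetic by construction: it supports closure and reconstruction
properties (e.g. with the error share fixed at the published 5.20 %, the
dose share of the count table reconstructs to ≈63, within two points of the
published 63.59 %), not recovery of the true replicate scatter.

## Synthetic-data generator

The generator emulates the study design — 4 PAHs × 4 doses × 3 replicates,
10-day colony observation — with parameters fixed once from the published
summary structure:

* **Colony series**: two strategist classes; fast (r) emergence
  (0.5, 0.3, 0.2) over days 1–3, slow (K) uniform over days 4–10,
  mixed with fast fraction 0.2. This puts the expected CD at
  100·Σ qᵢ/i = 26.85, inside the observed 26.4–27.3 band. Plate totals are
  Poisson around 120 colonies × a dose multiplier (1.00/1.56/2.08/2.63,
  the pooled published dose means relative to control — counts *increase*
  with dose), floored at one colony so the indices stay defined, then
  allocated multinomially across days.
* **Activities**: value = max(control − slope·dose, 0) × normal(1, CV)
  noise clipped at zero, CV = 0.05. Control means (18.25 / 8.63 / 2.76)
  and per-PAH slopes are the published 0→4000 mg kg⁻¹ endpoints; count
  slopes are negative (stimulation). At CV = 0 the configured slopes are
  recovered exactly through fitted dose means, and the urease columns
  reproduce RS ≈ 0.25–0.28 at 4000 mg kg⁻¹.
* **Phytotoxkit**: per-seed Bernoulli germination and zero-truncated
  normal root lengths (10 seeds × 3 plates). Germination probabilities
  and treated/control root-length ratios are back-derived from the
  published inhibition percentages; control root means (50/40/45 mm, sd
  5 mm) are typical of 3-day assays with these species.

All randomness flows from a single integer seed through spawned
`SeedSequence` substreams, one per plate/cell, so partial re-runs are
stable and identical seeds give byte-identical CSVs.

**What the generator does not emulate**: mechanistic PAH degradation,
temporal population dynamics, correlated replicate structure, non-linear
dose responses, or plate crowding/colony merging. Passing parameter-recovery
tests therefore demonstrates that the pipeline computes its statistics
correctly under the assumed structure, not that the structure describes any
particular real soil.

## Numerical conventions

* Report rounding is half-up at table precision (2 decimals for activities
  and counts, 3 for RS, 2 for r, 1 for inhibition percentages). Two
  published text values (11.6, 1.6 % germination inhibition) appear
  truncated from 11.65/1.65 rather than rounded; soilpah rounds half-up and
  accepts the ±0.1 divergence. Similarly some published column averages
  (24.87, 1.91, 1.93) are truncations of 24.8775/1.9175/1.9375.
* All-zero colony series, non-positive controls, zero-variance correlation
  inputs, unbalanced layouts and constant-response ANOVA inputs raise typed
  errors rather than returning NaN; the degenerate all-constant ANOVA is
  flagged on the result object.
* Tolerances: daily fractions sum to 1 within 1e−12; SS decomposition is
  validated against a brute-force oracle at 1e−8 over 100 random balanced
  designs and against `statsmodels.anova_lm`.

## Known reproduction limits

* **Resistance grid.** Recomputing the published RS grid from the published
  enzyme means reproduces most cells within ±0.003 (rounding of the printed
  inputs), but not all. The phenanthrene–urease column (printed 0.164,
  0.091, 0.065) recomputes to ≈0.786, 0.353, 0.238, and four dehydrogenase
  cells (naphthalene 2000/4000, anthracene 1000, pyrene 1000) recompute to
  0.726/0.563/0.977/0.998 against printed 0.847/0.687/0.956/0.981. Like the
  printed correlation coefficients (e.g. 0.98 for naphthalene counts where
  the mean-level value is 0.988), these evidently derive from
  replicate-level data that were not published. `reproduce-tables` reports
  them as documented discrepancies, and the corresponding strict test is
  allowed to fail loudly rather than being silenced.
* **η² and CD/EP levels.** The published η² table and per-treatment CD/EP
  values cannot be recomputed exactly without the raw replicates/daily
  counts; they are covered by the approximate-reconstruction property and
  by the generator's calibration band only.

## Problem sizes

Property suites run on small randomized instances (balanced designs up to
4×4×5, 100 instances; exhaustive entropy checks over all compositions of
≤6 colonies on ≤4 days; cohorts of 48 plates), which keeps the whole suite
in the tens of seconds while exercising every code path at full design
size.
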