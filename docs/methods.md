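# Methods

This note documents the statistical model behind `pepdiff`, the choices made
where the design was genuinely open, what the synthetic cohorts emulate, and
the limits of what passing tests demonstrate.

## Data model and filters

The unit record is a *candidate match*: one proposed correlation of one MS/MS
spectrum to one peptide sequence at one charge state (+2 or +3), carrying a
fit score, the precursor intensity in arbitrary counts, sample metadata
(condition, patient, step-gradient fraction 1–10), a protein accession and a
gene symbol. Post-translational modification text is carried as an opaque
optional field and ignored by every statistic. A *treatment* is one of 26
condition × search-channel cells (13 conditions × {TRYP, STYP}), numbered so
that odd ids are the plain-tryptic channel.

Two filters precede all counting:

* **Intensity floor** — precursor ≥ 10⁴ counts, *inclusive*. The floor is the
  instrument-noise cutoff below which correlations are unreliable; it is a
  config value (`min_intensity`).
* **Best-hit collapse** — exactly one candidate per spectrum survives:
  maximal score, ties broken by lower charge, then lexicographically smaller
  peptide, then smaller accession. The tie-break is a package convention
  chosen purely for determinism: it makes every downstream count invariant to
  input row order, which the suite asserts. Each retained spectrum is
  attributed to exactly one accession (the winning row's), so entity counts
  are conserved: they sum to the treatment total at every rollup level.

## Frequency contrast

For a contrast of treatment A against comparator B with filtered-spectrum
totals nᴬ, nᴮ, the raw A count *a* is rescaled to *a*′ = *a*·nᴮ/nᴬ — the
direction is a design choice; placing both groups on B's sampling depth keeps
B's raw count meaningful in the denominator of

    χ² = (a′ − b)² / (b + 1)

which is referred to the upper tail of χ²(1). The +1 pseudo-count keeps the
score finite when the comparator count is zero, at the price of calibration:
under a no-effect simulation the score's exceedance rate over the χ²(1) 5%
critical value is roughly 3× nominal (measured by the suite and the
acceptance script), because a one-cell statistic with a pseudo-count
denominator does not standardize the difference by its sampling variance. The
classical Pearson 2×2 proportion statistic (entity vs rest, A vs B margins,
no continuity correction) is provided as `classical_chi2` strictly as a
calibration reference; it holds its nominal level in the same simulations.
The pseudo-count score is also asymmetric in (A, B) — swapping labels changes
it — and the suite asserts that asymmetry rather than pretending symmetry.

An alternative depth measure — totals of redundant candidate rows instead of
filtered spectra (`correction="correlation_totals"`) — is exposed and yields
closely similar factors because redundancy is roughly uniform across
treatments.

p-values are converted to Benjamini–Hochberg q-values within one analysis
family, defined as one rollup level × one search channel (the two channels
are analyzed side by side, not pooled). Gene-level results may be produced
either by counting at gene level directly or by averaging per-accession χ²
within a gene symbol (`gene_mean_chi2`, reported with the accession count);
the package computes the per-accession score on corrected counts, with raw
counts preserved in the output for audit. Candidate selection uses strict
inequalities (Δ > 9 and χ² > 9 by default, with a stricter 15/15 variant),
matching the wording "greater than" in the rule it implements.

## Intensity ANOVA

Raw precursor intensities span several decades and are approximately
log-normal; base-10 logs are therefore the analysis scale (the suite checks
that strongly log-normal raw draws fail Shapiro–Wilk while their logs pass).
Each retained PSM contributes one observation — the observation unit visible
in published per-treatment Ns — with a per-patient-mean mode available for
sensitivity analysis. Normality is assessed per treatment group by
Shapiro–Wilk with groups capped at 5000 by seeded subsampling; groups with
n < 3 or zero spread are skipped and flagged.

One-way ANOVA on raw observations goes through an OLS cell-means fit with a
sequential (Type I) decomposition; `anova_from_summary` reconstructs the same
strata from per-group (mean, sd, n) summaries via

    SS_treat = Σ nᵢ(ȳᵢ − ȳ)²,   SS_resid = Σ (nᵢ − 1) sdᵢ²

and is property-tested to agree with the raw-data fit to 1e-9 relative
whenever the summaries are exact. Groups with sd = 0 and small n participate
through their mean and n, contributing zero within-group SS. The two-factor
model (treatment + peptide, no interaction) uses Type I sums of squares with
treatment entered first — on an unbalanced design the order matters, and this
matches the default sequential table of the R environment such analyses are
usually run in. A constant peptide factor collapses to the one-way model with
a warning; a factor level confined to a single cell is reported as possibly
confounded, not fatal.

All-pairs comparisons use the Tukey–Kramer HSD statistic with the pooled
residual mean square and the studentized-range quantile computed numerically
(scipy, accurate to well below 1e-6). Letters come from the insert-and-absorb
compact-letter-display algorithm with letters allocated in descending-mean
order; since letter *identity* is convention-dependent, tests assert only the
sharing relation, which is proved (by an all-pairs oracle) to be exactly the
complement of pairwise significance.

### The bundled QSER1 summary table

`pepdiff.datasets.load_qser1_summary()` carries the published per-treatment
(mean, SD, N) table for QSER1 log10 intensities (24 groups, 832
observations). Two rows of the available rendering of that table are
typographically ambiguous; the bundled values are the unique reading
consistent with the published ANOVA strata (treatment df 23, residual df 808,
SS ≈ 113.0/239.9, F ≈ 16.55), which the reconstruction reproduces to four
significant figures.

## Exclusivity screen

A peptide is called exclusive to a condition when its pooled (TRYP + STYP)
count is ≥ `min_count` there and zero in every other condition. The default
floor of 3 is a package choice: it prevents a single spectrum from producing
a call while remaining permissive for sparsely sampled peptides; raising it
can only shrink the call set (asserted as anti-monotonicity). Distinct-patient
support is reported alongside, so single-patient artifacts are visible.
Conditions can be excluded from the "elsewhere" check (e.g. the ice-cold
baseline or a matched control being pooled with the target).

## Synthetic cohorts

The generator emulates the sampling structure of a multisite plasma study:

* 13 disease/control conditions with 9–26 patients each (defaults fixed per
  condition), 10 sub-fractions per patient;
* per-run spectrum counts drawn negative-binomially (dispersion 5) rather
  than Poisson, reflecting patient-to-patient variability;
* log10 intensities normal with mean 4.6 and sd 0.5, truncated (redrawn, not
  censored) at the 4.0 detection floor, so the intensity threshold removes
  nothing unless the floor is lowered deliberately;
* redundant candidate rows appended with probability 0.2 per spectrum
  (≈1.2 candidates/spectrum, the ratio observed in the emulated study's
  reported totals), always with strictly lower scores, so the best-hit
  filter's correct output is known by construction;
* an ice-cold condition in which only a configurable fraction (default 0.5)
  of the gene panel is detectable;
* planted effects with ground truth: fold-enriched gene rates, additive
  log10-intensity shifts, and condition-exclusive peptides.

The per-fraction sampling depth (default mean 150) and the panel size
(default 200 genes × 3 peptides × 2 accessions) are free parameters; the
defaults generate a full cohort of ~350k candidate rows in about two seconds,
and the targeted experiments below use smaller explicit configs. What the
simulator does **not** model: fragmentation physics and search-engine score
distributions, retention time, shared peptides between genes, correlated
patient effects, batch/site effects, and ex vivo degradation kinetics.
Passing recovery tests therefore demonstrates that the statistics recover the
effects they are defined to detect under clean sampling assumptions — not
that real cohorts of this size would yield the same power.

## Verification experiments

The acceptance layer (tests and `scripts/acceptance.py`) recomputes:

* the QSER1 ANOVA reconstruction and its Tukey letter separation of breast
  (treatments 5, 6) from ovarian (treatment 9);
* depth-correction and χ² arithmetic under the published totals
  455,426/498,616, against independent arithmetic at 1e-12 relative;
* the χ²(1) upper tail at 60 (< 1e-4);
* brute-force oracle equivalences (best-hit argmax, BH step-up, count
  conservation, summary-vs-raw ANOVA, Tukey letter relation);
* seeded recovery: 10 genes at 10-fold enrichment and ~100 expected counts
  (two 15-patient conditions, 30 spectra/fraction) all rank in the χ² top 20;
  a +0.8 log10 shift with ~25 observations/group (five 9-patient conditions,
  single channel) separates by Tukey letters in ≥ 18/20 replicates; 10
  planted exclusive peptides are recovered with recall and precision 1.0 at
  min_count 3;
* null calibration on 20 no-effect cohorts (two 9-patient conditions, 60
  spectra/fraction, ~4000 tests): the classical 2×2 statistic's empirical
  type-I rate stays within two binomial standard errors of 0.05, while the
  pseudo-count score's exceedance rate is recorded and is ~3× larger.

Problem sizes were chosen as the smallest designs that make these checks
statistically sharp; all randomness flows from the harness seed.

## Known limitations

* The pseudo-count χ² is a screening score, not a calibrated test; its
  p/q-values should be read as rankings (the package documents and measures
  the inflation rather than hiding it).
* Protein inference is out of scope: each PSM carries one accession and one
  gene symbol from the search output; shared-peptide reassignment and
  parsimony grouping are not performed.
* Search-engine XML ingestion is not implemented; the canonical input is the
  tab-separated candidate table (a column-name dialect map accommodates
  third-party exports).
* No score floor is applied beyond the intensity threshold and best-hit
  collapse; if a search engine emits unreliable low-scoring winners they are
  counted.
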