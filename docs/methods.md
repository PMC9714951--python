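# Methods

This note documents the statistical procedures `cimpkit` implements, the
synthetic-cohort model used to test them, the tunable parameters with their
defaults and rationale, numerical conventions, and known limitations.

## The analysis

### Filtering

β-values (methylated / (methylated + unmethylated) signal, in [0, 1]) enter
as a probes × samples matrix with `NA` for undetected calls. Two filters
precede every analysis:

* **Detection masking** — a call whose detection p-value is ≥ α (default
  0.01, *inclusive* at the threshold) becomes `NA`. When no detection-p
  matrix is available (e.g. processed public deposits), pre-existing `NA`s
  stand in and masking is skipped.
* **Completeness** — only probes with zero `NA` across an explicitly named
  *core cohort* survive. The core set is a required parameter, never
  inferred from the columns present, because which samples define
  completeness is a study design decision. Both filters pass surviving
  values through bit-identically.

### Variability clustering and region enrichment

"Most variable" probes are ranked by across-sample standard deviation
(ddof = 1); the statistic is configurable but SD is the default, the common
450K practice. Ordering is deterministic: descending SD, ties by ascending
probe ID. Samples are clustered on the selected submatrix with Euclidean
distance and average linkage (scipy); results carry the merge table, leaf
order, and a Newick export. CpG-island enrichment of any probe set against
a universe is a one-sided Fisher exact test on the island vs non-island
2×2 table; per-region fold enrichment is selected-fraction over
universe-fraction. Shores and shelves are merged into one stratum because
they are reported jointly throughout.

### Volcano differential methylation

Per probe, Δβ = mean(tumor β) − mean(normal β) and a two-sample p-value;
a probe is *hyper* when Δβ ≥ +δ and p < α, *hypo* when Δβ ≤ −δ and p < α
(defaults δ = 0.4, α = 0.01, no multiple-testing correction — the raw-p
cutoff is the published rule). The groups are cohort-level tumor and
normal sets (the matched samples are cohort-matched, not all
patient-paired, so a paired test is not applicable). Because methylation
studies rarely name their test, three are exposed: Welch t (default),
Student t, and Mann–Whitney; survivor counts can be reported under each.
Probes with zero variance in both groups get p := 1 by convention and are
never called, even if the group means differ — a deliberate conservative
treatment of degenerate input.

### TS-Hyper probes, genes, and expression concordance

A probe is **tumor-specific hypermethylated (TS-Hyper)** for a cohort when

1. β ≤ 0.2 in *every* cohort normal (inclusive), and
2. mean tumor β − mean normal β ≥ 0.4 (inclusive).

Each cohort is called against its own normals. Genes with ≥ 2 island
TS-Hyper probes are *potentially methylated* (a probe annotated to several
genes credits each). A methylated gene is *concordantly downregulated*
when its tumor:normal expression ratio (raw-scale means) is < 0.6667
(strict) with Welch-t p < 0.05 (strict) on log2(x+1). Genes missing from
the expression matrix or with zero normal mean are reported unevaluable,
not errors. Cross-cohort overlaps first intersect the cohorts' probe
universes (a probe only counts where it was assessable everywhere), then
compute exact per-set, pairwise, all-way, union, and Venn-region counts.

### Marker panels and classification

Panel candidates are island probes with β > 0.5 (strict) in at least
`min_high_count` positive samples (default: all) **and** β < 0.2 (strict)
in *all* negative samples — no occupancy relaxation on the negative side.
Candidates are ranked by Welch-t p-value between the groups (or by mean
difference), ties by probe ID, and the top k (default 25) kept. For a
target platform that measures only a probe subset, selection is re-run
inside that universe with a relaxed positive occupancy (the cross-platform
use case).

A sample is scored by its mean β over the panel probes measurable in it
(absent or `NA` probes shrink the denominator; below 50 % coverage the
sample is *unscorable*). Classification: CIMP-panel mean < 0.2 → non-CIMP;
≥ 0.35 → CIMP, then subtype-panel mean ≥ 0.35 → subtype-A-like else
subtype-B-like; anything between the cutoffs → indeterminate. The
0.2 / 0.35 cutoffs are working defaults placed between the empirically
tight non-CIMP cloud (< 0.2) and the CIMP cloud (> 0.5) of panel averages;
they are parameters, not constants.

### Hypermethylation burden

The reference set is every island probe with β < 0.2 (strict) in *all*
normal samples. A tumor's burden is the count (and fraction) of reference
probes with β > 0.5 (strict). Burden is regressed on tumor size with
ordinary least squares (Pearson r, r²) and on age with a log-linear
("exponential") fit, back-transformed to amplitude·exp(rate·age).
Only primary tumors enter covariate fits (metastases and thrombi are
scored but excluded via the sample-sheet `is_primary` flag); tumors
missing a covariate are dropped pairwise and the drop is logged.

## The synthetic-cohort model

The generator produces β, annotation, sample sheet, expression, and a
planted-truth record. Its structure:

* **Probe baselines.** Each probe has a stable baseline: a constitutively
  methylated stratum (30 % of probes, all samples) drawn from the
  methylated state Beta(20, 4), the rest from the unmethylated state
  Beta(2, 20). These shape pairs describe the *across-probe* distribution
  of baseline levels; individual measurements scatter around the baseline
  with Gaussian technical noise (SD 0.03, clipped to [0, 1]), the way
  array replicates behave. Modelling the states per-cell instead would
  contradict how real island probes behave under "all normals ≤ 0.2"
  rules: Beta(2, 20) puts 5.8 % of independent draws above 0.2, which
  would break every all-normals clause on a fifth of probes.
* **Susceptibility.** CIMP hypermethylation targets normally-unmethylated
  probes, so the susceptible pool is the non-constitutive probes with
  baseline ≤ 0.15 (≈ 84.5 % of unmethylated probes).
* **Region weighting.** A tumor with burden fraction *b* hypermethylates
  susceptible island probes at rate *b*, shore/shelf probes at 0.4·*b*,
  open-sea probes at 0.1·*b* (weights 10:4:1). Burden is therefore stated
  on the island scale — the same scale as the burden statistic the
  pipeline measures.
* **Cohort structure.** Each CIMP cohort has a *core* target set planted in
  every tumor (rate = the cohort's burden-range floor), partly drawn from
  a shared CIMP pool (rate 0.02) so cohorts overlap; each tumor adds
  private targets up to its drawn burden *b* ~ Uniform(cohort range).
  Defaults mirror a renal-syndrome study: HLRCC-like 15 tumors / 4 normals
  with b ∈ (0.10, 0.50); SDHB-like 6/4 with b ∈ (0.02, 0.30); three quiet
  cohorts (5/3, 4/0, 4/0) with b = 0.
* **Universe vs sample randomness.** Probe-level attributes (regions, gene
  map, baselines, core sets) derive from a dedicated `universe_seed`
  substream. Two cohorts simulated with different `seed` values share
  probe semantics — which is what lets panels trained on one cohort
  classify an independently drawn one, the cross-cohort validation the
  method is designed for.
* **Covariates.** Tumor size = 0.5 + 18·b + N(0, 0.3) cm, floored at
  0.3 cm — CIMP burden linearly couples to size with realistic measurement
  noise. Ages are Uniform(19, 63) and independent of burden. Non-CIMP
  tumor sizes are Uniform(1, 8) cm.
* **Expression.** Per-gene baselines are log-normal (ln-mean 5, ln-SD 1)
  with per-cell log-normal noise (ln-SD 0.25). Genes are blocks of ~3
  island probes covering 75 % of island probes. Genes with ≥ 2 core island
  probes in a cohort are downregulated in that cohort's tumors by a factor
  drawn log-normally around 0.4 (ln-SD 0.15).

What the generator does **not** emulate: probe cross-hybridization,
SNP-affected probes, FFPE degradation, batch effects, cell-type
heterogeneity, or any correlation structure along the genome. Passing
benchmarks therefore demonstrate the correctness and statistical behavior
of the pipeline's rules under the assumed signal model — not robustness to
those real-data artifacts, which must be handled upstream.

## Benchmark battery and problem sizes

`scripts/acceptance.py` (and `tests/test_acceptance.py`, which runs the
same battery) computes:

* **Oracle equivalence** — TS-Hyper calling, panel candidate selection,
  reference identification, and burden counting compared with per-probe
  pure-Python loops on 100 random 1,000-probe × 16-sample matrices; exact
  set equality expected.
* **Planted-truth recovery** — 20 study-scale cohorts (20,000 probes,
  15+6+13 tumors, 11 normals): pooled sensitivity of TS-Hyper calling
  against cohort cores and false-call rate among non-core probes; maximum
  absolute error of measured vs planted burden fractions. 50 cohorts for
  the size-link slope: the fitted burden~size coefficient is compared,
  within 2 standard errors, against the model-implied regression
  coefficient k·var(b)/(k²·var(b)+σ²) scaled by the replicate's
  reference-set measurement factor (ratio of measured to planted burden —
  the benign dilution introduced by reference-set contamination, known
  from the planted truth).
* **Classification transfer** — panels trained on one cohort seed (top 25
  CIMP probes at full occupancy; top 25 subtype probes at ≥ 13/15)
  classify 20 held-out seeds; accuracies are pooled over all 900 samples /
  420 CIMP tumors so the binomial estimates are stable.
* **Enrichment** — with 10:4:1 planting, the top-1 %-variable set's island
  Fisher test at p < 0.01 across 20 replicates; with uniform 1:1:1
  planting, the median island fold (expected ≈ 1). Recovery and enrichment
  replicates redraw both the sample seed and the probe universe so they
  are genuinely independent; classification keeps the universe shared
  between train and test, since panel transfer on a common platform is the
  property under test.
* **Boundary semantics** — dedicated edge fixtures for every threshold's
  inclusivity: detection p ≥ 0.01 masked; TS-Hyper ≤ 0.2 and ≥ 0.4
  inclusive; reference < 0.2, burden > 0.5, panel > 0.5 / < 0.2, and
  expression ratio < 0.6667 strict.

These sizes keep the full battery under a minute on one CPU while leaving
each statistical check comfortably powered.

## Numerical conventions and edge cases

* All threshold comparisons follow the stated inclusivity exactly; see the
  boundary battery for the executable definition.
* Undefined test p-values (NaN from degenerate input) are replaced by 1.
* Ranking ties (equal SD, equal p) break by ascending probe ID, making
  every ordering deterministic. Sample-order permutations can swap probes
  whose SDs are equal only up to floating-point summation order.
* Fisher tests are exact, not approximated; the hypergeometric tail is the
  reference in tests.
* Empty panel selection warns and returns an empty panel (downstream
  classification then refuses, with a clear error, rather than scoring on
  nothing).
* The exponential burden fit requires strictly positive burdens and at
  least 3 complete pairs; the covariate must vary.

## Limitations

* No IDAT decoding or normalization (SWAN/BMIQ/noob) — the pipeline starts
  from processed β-values.
* The volcano and expression tests are configurable precisely because the
  canonical choices are unsettled in the field; printed survivor counts
  shift slightly between test choices.
* Classification cutoffs were chosen from the separation the panel rules
  themselves enforce (negatives < 0.2, positives > 0.5); cohorts with
  genuinely intermediate methylation will land in the `indeterminate`
  class by design rather than being forced to a side.
* Burden–size coupling is treated purely as an observed regression; no
  causal claim is modelled.
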