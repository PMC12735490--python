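# Methods

## The synergy statistic and its null model

For a fiber mixture blended in equal proportions (25% each of four
fibers), the additive expectation of any SCFA measure for a donor is the
arithmetic mean of that donor's four single-fiber concentrations; a 25%
share of each fiber contributes a 25% share of its individual output.
Synergy is the relative excess of the observed mixture concentration
over this expectation, in percent. The statistic is donor-specific:
each donor serves as their own control across substrates, which removes
between-donor differences in overall fermentation capacity.

For *derived* total-SCFA rows (total = acetate + propionate + butyrate)
the additive expectation is evaluated as the sum of the three per-acid
expectations. Algebraically this equals the mean of the four fiber
totals; evaluating it this way keeps the total's null internally
consistent with how the total itself is built, so a zero-effect dataset
yields synergy of exactly 0 rather than floating-point dust. For
independently measured totals (which may include minor acids),
`total_expectation="mean_of_totals"` averages the fiber total rows
directly.

### Filtering

Three uniform reliability gates are applied per record:

| gate | default | rationale |
|---|---|---|
| measurement error | \|Obs − Exp\| ≤ 0.5 mM → excluded | the excess is within GC measurement error; its sign is noise |
| detection limit | min(Obs, Exp) < 1.0 mM → excluded | a ratio against (or of) a sub-detection value is unreliable |
| minimum group size | n < 3 retained → statistics suppressed | no inference from one or two donors |

The source description joins the first two tests with an ambiguous
"and"; this implementation excludes a record when **either** test fires
(`combine_rule="any"`), since either condition alone makes the ratio
unreliable, with `"all"` available. When both fire, the
measurement-error status is reported. Zero expectation is its own
status (`excluded_zero_expected`) rather than an infinite synergy, so
summaries stay finite.

### Donor classification

Donors are labelled `synergy` when their retained total-SCFA synergy
exceeds 0% (the simplest reading of "exhibiting synergy"; the threshold
is a parameter). Donors whose total record was filtered fall back to
the mean of retained acid-level synergies; donors with nothing retained
are `unassigned`. Note that at the emulated effect scale (mean 33%,
SD 20%) only ~5% of donors fall below 0, so a 34-donor cohort often has
zero to two `no_synergy` donors; downstream group contrasts then report
suppression rather than fabricating a comparison.

## Group statistics

* **Mixture vs individual fibers** — all 10 pairwise substrate
  contrasts via the studentized range on a randomized complete block
  layout: the donor effect is removed before the residual mean square
  (error df (n−1)(k−1)), honouring the repeated-measures design; a
  pooled-residual variant (`blocked=False`) is available and agrees
  with standard Tukey HSD. Donors with any missing substrate cell are
  dropped and logged.
* **Observed vs expected** — paired two-tailed tests (t by default,
  Wilcoxon signed-rank as option) per (condition × SCFA) cell, with BH
  correction across all emitted tests as a single family (up to 16; the
  conservative reading of a correction applied "across" these tests).
  These tests run on the raw observed/expected pairs with only the
  n ≥ 3 gate: the measurement-error/detection filters define which
  synergy *percentages* are reportable, not which concentration pairs
  exist, and filtering pairs by the size of their difference would
  condition the test on its own effect and destroy its calibration
  (verified: with the filter, null rejection would be far from nominal;
  without, it is 5.1% at α = 0.05 over 2000 simulated families).
* **Synergy comparisons** — across conditions: unpaired Welch tests per
  condition pair within each SCFA family (filtering yields unequal n);
  within condition: paired tests between acids on donors retained for
  both. Holm–Šidák step-down adjustment per family.

Degenerate paired inputs are given their limiting values: zero-variance
differences with zero mean → statistic 0, p = 1; with nonzero mean →
±∞, p = 0 with a warning.

### Multiple-testing adjustments

BH (step-up, `min(1, min_{j≥i} m·p_(j)/j)`) and Holm–Šidák (step-down,
`min(1, max_{j≤i} 1−(1−p_(j))^(m−j+1))`) are implemented directly from
their definitions in plain float arithmetic; the test suite verifies
bitwise agreement with brute-force references and 1e-12 agreement with
statsmodels.

## Alpha diversity and associations

Shannon entropy is computed in nats (the log base is a convention;
evenness is base-invariant, and base 2 is an option), richness is the
observed taxon count, and evenness is Pielou's H/ln(richness), missing
for single-taxon samples. No rarefaction or coverage correction is
applied; raw proportions are used. Δ-metrics are post − baseline.

Spearman correlations use average ranks for ties; for n ≤ 9 the
two-sided p-value is exact, from full enumeration of the n! rank
pairings (cached permutation tables make this cheap), and asymptotic
above. Association grids pair each synergy measure with each feature,
drop donors pairwise per cell, report cells with fewer than 3 complete
pairs or constant inputs as missing-with-reason, and annotate
significance per cell at α = 0.05 *without* multiplicity adjustment by
default (heatmap-annotation style; BH across the grid is one flag).

## Differential abundance

A deliberately transparent simplification of bias-corrected
compositional testing: per-sample sampling-fraction offsets are the
median over taxa of the sample's log count (pseudocount 1) minus a
per-taxon reference, and groups are compared per taxon by a Welch test
on offset-corrected log counts; the log fold change (natural log,
positive = enriched with synergy) is the difference of corrected group
means, with BH across tested taxa.

Two choices matter and were validated numerically:

* the **reference is the per-taxon median across all samples**
  (label-free), not a per-group mean: a group-specific reference
  absorbs its own group's average depth and leaves a common
  between-group depth shift in every taxon's contrast — exactly the
  bias the correction must remove — inflating null rejection to ~15%;
  the global median reference restores 5.0% calibration and full
  between-group bias correction;
* **medians, not means, on both axes**, so a minority of truly
  differential taxa (and any single sample's depth change) cannot
  drag the offsets.

Taxa present in fewer than 10% of samples in both groups are excluded;
taxa absent from one entire group are reported as structural zeros (a
fold change is not estimable without stronger assumptions) rather than
tested.

## Co-occurrence networks

Within a stratum (≥ 5 samples), Spearman correlation matrices are
computed over relative abundances of prevalence-filtered taxa. An edge
is kept when BH-adjusted significance across all taxon pairs passes
α = 0.05 **and** |ρ| ≥ 0.6 — thresholds in line with common
co-occurrence practice, both exposed in `NetworkConfig`. Node
importance is degree (edge count; betweenness optional); hub ranking
breaks ties by summed |ρ| of incident edges, then lexicographic taxon
id, so rankings are deterministic. Networks export to GraphML
(Cytoscape-importable) and edge-list TSV and re-import losslessly.

## The synthetic-data generator

**Fermentation.** Single-fiber concentrations are log-normal:
per-acid base medians (acetate 40, propionate 15, butyrate 15 mM per
fiber — realistic 12-h in vitro batch-fermentation magnitudes, chosen
once since no numeric baselines are published) scaled by condition
factors (< 1 for the disease groups, which run lower than healthy
controls), fiber factors (pectin strongest), a shared per-donor random
effect (log-SD 0.30) and residual cell variation (log-SD 0.25). The
mixture concentration is the per-donor mean of the four recorded fiber
values times (1 + δ/100), with δ ~ Normal(33, 20) percent drawn once
per donor (per-acid δ available for stress tests); donor-level synergy
with acid-to-acid variation emerging from noise and filtering matches
how the phenomenon is reported. Additive Gaussian measurement noise
(SD 0.1 mM, truncated at 0) applies to every recorded concentration —
GC error lives on the concentration scale. Totals are exact sums of
the three acids.

**Taxa counts.** Dirichlet-multinomial per sample: a shared
concentration vector (uniform 10 per taxon by default), multiplied by
each enriched taxon's fold-change in the synergy group, library sizes
log-normal (median 3×10⁴, log-SD 0.3). The uniform concentration of 10
keeps overdispersion moderate so log-scale abundances sit close to
their compositional expectations; with small concentrations, digamma
effects would bias log fold-change recovery through the generator, not
the estimator.

**What the generator does *not* emulate.** Real communities are uneven
with phylogenetically structured correlations; the Dirichlet-multinomial
plants *no* taxa-taxa coupling, so co-occurrence networks on generator
output are correctly empty (network recovery is demonstrated on
latent-factor communities with a planted hub/module instead). The
generator's observed mixture concentration mechanically contains δ, so
synergy-vs-absolute-SCFA grids show positive association on synthetic
data by construction; an empirical absence of such correlation is a
property of real data, not of the method. Passing tests demonstrate
statistical correctness of each stage against planted truth, not that
real fermentations satisfy the model.

## Numerical and design notes

* Exact Spearman enumeration switches to the asymptotic p at n = 10
  (9! = 362 880 pairings is the practical ceiling).
* The zero-effect, zero-noise dataset yields bitwise-zero synergy
  because generator and analysis evaluate the four-fiber mean and the
  acid sums with identical operation order.
* Per-stage seeds derive from one global seed via `SeedSequence.spawn`,
  so stages are independently reproducible.
* Monte-Carlo problem sizes in the test suite (500 cohorts for
  parameter recovery, 2000 null families for calibration, 200 seeds for
  planted recovery) were chosen so that Monte-Carlo error is well inside
  each tolerance on a single core.

## Known limitations

* The differential-abundance stage is a documented simplification — no
  iterative bias estimation, no covariates, no structural-zero
  inference; published log-fold-change magnitudes also depend on an
  unstated log base, so only sign and order are comparable.
* The synergy/no-synergy cutoff (0%) is an analysis choice the source
  material does not pin down; at the emulated effect scale the
  no-synergy group is typically near-empty and group contrasts are
  suppressed accordingly.
* Whether the published cohort mean synergy was computed before or
  after the reliability filters is not stated; this pipeline reports
  the filtered estimate (the unfiltered one is one flag away), and the
  ±0.5 mM band around zero excess introduces a small (≈ +0.3 point)
  upward truncation bias at the emulated base levels.
* No blank-fermentation baseline subtraction, no rarefaction, no
  beta-diversity or phylogenetic metrics, no mechanistic fermentation
  or cross-feeding model.
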