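# fibersynergy

Analysis pipeline for quantifying **synergistic short-chain fatty acid
(SCFA) production by dietary-fiber mixtures** in in vitro fecal
fermentations, and for exploring the microbial signatures associated
with that synergy.

## The scientific problem

When a blend of structurally diverse fibers (e.g. apple pectin, barley
β-glucan, fructooligosaccharides, sorghum arabinoxylan in equal parts)
is fermented by a donor's fecal microbiota, the resulting SCFA
(acetate, propionate, butyrate) can exceed what the individual fibers
would predict. For an equal-proportion four-fiber mixture the additive
null model is the per-donor mean of the four single-fiber
concentrations,

```
Expected_additive = (SCFA_fiber1 + SCFA_fiber2 + SCFA_fiber3 + SCFA_fiber4) / 4
```

and synergy is the percent excess of the observed mixture output over
that expectation:

```
Synergy (%) = (Observed_mixture − Expected_additive) / Expected_additive × 100
```

Records are filtered with uniform reliability thresholds — excess within
measurement error (|Obs − Exp| ≤ 0.5 mM) or concentrations below the
1.0 mM detection limit are excluded, and groups with fewer than 3
retained values carry no statistics. Around this statistic the package
implements:

* **group statistics** — donor-blocked Tukey contrasts of the mixture vs
  each fiber; paired observed-vs-expected tests per condition and SCFA
  type with Benjamini–Hochberg correction; synergy comparisons across
  health conditions (Welch) and between acids (paired) with Holm–Šidák
  adjustment;
* **alpha diversity** (Shannon, richness, Pielou evenness) at baseline
  and post-fermentation and Spearman association grids between synergy,
  diversity and absolute SCFA (exact permutation p-values for n ≤ 9);
* **bias-corrected differential abundance** between donors with and
  without synergy (median log-ratio sampling-fraction offsets, Welch
  tests on corrected log counts, natural-log fold changes, BH q);
* **taxa–taxa co-occurrence networks** per synergy stratum (Spearman
  edges at BH q < 0.05 and |ρ| ≥ 0.6, degree-ranked hub taxa, GraphML /
  edge-list export);
* a **synthetic-data generator** that injects known per-donor synergy
  (mean 33%, SD 20% by default, matching the cohort scale it emulates:
  10 healthy controls and 10 Parkinson's, 7 Crohn's, 7 ulcerative
  colitis donors) and plants known taxon enrichment, so every stage is
  validated against ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with known truth:

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_synergy.py
python analysis/03_fiber_stats.py
python analysis/05_differential_abundance.py
```

`02_synergy.py` prints (seed 0):

```
records: 136, retained: 130
filter statuses: {'retained': 130, 'excluded_measurement_error': 6}
total-SCFA synergy: mean 29.5% +/- 18.0% (median 29.6%, max 64.9%)
donor labels: {'synergy': 33, 'no_synergy': 1}
```

i.e. of 136 donor × SCFA records, 130 pass the reliability filters; the
cohort-mean total-SCFA synergy estimate is 29.5 ± 18.0% against an
injected donor-level mean of 33% with SD 20% (a 34-donor cohort draw),
and 33 of 34 donors are classified as exhibiting synergy.
`05_differential_abundance.py` then recovers every planted enrichment
on the designated 20/20-donor benchmark, in the right order and with no
false depletions:

```
benchmark (20/20 designated groups): tested 40 taxa; 5 enriched at q < 0.05
  taxon_003: planted ln-fold 1.74, estimated lfc 1.62 +/- 0.06, q=6.37e-23
  taxon_007: planted ln-fold 1.39, estimated lfc 1.18 +/- 0.08, q=2.67e-13
  ...
significantly depleted taxa: 0 (none were planted)
```

The same analyses are available as a library (`fibersynergy.synergy`,
`.stats`, `.diversity`, `.association`, `.diffabund`, `.network`), as a
single orchestrated run (`fibersynergy.pipeline.run`, config in
YAML/JSON), and as a CLI (`fibersynergy simulate|synergy|stats|...`).
`analysis/07_deposited_data.py` applies the synergy quantification to a
real deposited fermentation table in the canonical CSV schema.

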