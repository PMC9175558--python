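# suppscreen

Analysis pipeline for a chemical **suppression screen** in a *Saccharomyces
cerevisiae* model of succinate dehydrogenase (SDH) loss — the enzyme whose
familial inactivation drives paraganglioma. In SDH-loss yeast, accumulated
succinate competitively inhibits the 2-ketoglutarate–dependent dioxygenase
Jlp1p, which is essential for growth when isethionate (ISE) is the sole
sulfur source. Growth of `sdh∆` strains on ISE therefore reports dioxygenase
function, and a compound that selectively restores that growth is a
candidate suppressor of oncometabolite toxicity.

The package is written for screening labs and computational biologists who
need the full analysis chain behind such a screen: plate-reader data
modeling, per-compound Z scoring with exclusion filters, dose–response
selectivity validation with error propagation, differential proteomics, and
succinate:2-ketoglutarate (2KG) ratio analysis — all driven by a seeded
synthetic-data generator with planted ground truth.

## The statistics at the core

**Screen scoring.** Each compound occupies a single `sdh1∆`/ISE well; each
plate carries 4 vehicle (DMSO) control wells. At every timepoint the
screening-window statistic is

```
Z = 1 − 3(σₚ + σₙ) / |µₚ − µₙ|
```

with µₙ, σₙ the mean and sample s.d. of the plate's controls and, because a
single well has no s.d., the *mock s.d. rule* σₚ := σₙ. A compound is a
**hit** when Z > 0 (with µₚ > µₙ, i.e. growth stimulation) at ≥ 6 of 7
reads over 24 h. Compounds formulated with sulfate are excluded — they feed
the sulfur-scavenging pathway directly and bypass Jlp1p — as are compounds
forming colored solutions that offset the OD600 reading.

**Validation.** Hits are retested across 4 strains (WT, `sdh1∆`, `sdh2∆`,
`jlp1∆`) × 2 media (ammonium sulfate vs ISE). The endpoint effect is the
percent growth change `pct = 100·(t − u)/u` with first-order error
propagation `err = 100·√((s_t/u)² + (t·s_u/u²)²)`, and per-cell significance
from Tukey HSD at α = 0.05. A *selective suppressor* stimulates both
`sdh∆` strains on ISE only; a significant `jlp1∆` rescue on ISE flags a
sulfur **bypass suspect** instead.

**Omics and metabolites.** Differential protein abundance uses Welch t-tests
on log2 abundances with Benjamini–Hochberg adjustment and the dual rule
*adjusted P < 0.05 and |log2FC| > 1.5*; the two mutant-vs-WT comparisons are
summarized by a Venn partition and a fold-change correlation. Metabolite
tables yield per-sample succinate:2KG ratios and strain fold-changes, tested
by balanced two-way ANOVA (strain × treatment) with Tukey HSD on cell means.

## Worked example

Simulate the screen at study conditions and call hits (also available as
`suppscreen all --seed 0 --out results/` from the shell):

```sh
python analysis/01_simulate_screen.py --seed 0 --out results
python analysis/02_score_and_call_hits.py --seed 0 --out results
```

```
simulated 16 plates: 1280 experimental wells, 64 vehicle controls, 9408 OD600 readings
26 hits of 1280 compounds (20 positives removed by formulation exclusions)
compound_id  summary_z  n_positive  is_hit  excluded exclusion_reason          name
      C0247   0.697334           6    True     False             none compound-0247
      C0347   0.635224           6    True     False             none compound-0347
      ...
```

All 26 planted suppressors (+15% growth capacity on ISE) are recovered;
every sulfate-formulated and colored compound that scored positive is
removed by the exclusion filters, not by the Z threshold. `summary_z` is
the median Z across the 7 reads; `n_positive = 6` because the t = 0 read
carries no growth separation yet.

Downstream stages read the same seed and report, e.g.
(`analysis/04_proteome_differential.py`, `analysis/05_metabolite_ratios.py`):

```
significant: 986 (sdh1) vs 1040 (sdh2); union 1083, shared 943 (87%), unique 43 / 97
fold-change correlation r = 0.939
strain treatment  mean_ratio   sd  n
  sdh1 untreated       11.41 1.69  3
  sdh1      DMAE        7.22 1.60  3
  ...
strain x treatment interaction p = 1.01e-04
```

The mutant succinate:2KG ratio is ~10-fold the WT ratio and the treatment
(modeled on DMAE, which lowers mutant succinate only) pulls it partway back
— the significant strain × treatment interaction is the statistical
signature of a mutant-selective metabolic correction.

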