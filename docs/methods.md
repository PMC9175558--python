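# Methods

This note documents the models, parameter choices, and numerical decisions
behind the `suppscreen` package, and what its synthetic benchmarks do and do
not establish about real screen data.

## Growth model and strain calibration

Per-well OD600 is a sum of one or two logistic terms plus additive Gaussian
noise truncated at zero:

    OD(t) = od0 + cap1·expit(rate1·(t − mid1)) [+ cap2·expit(rate2·(t − mid2))] + ε,
    ε ~ N(0, noise_sd²)

The double-logistic form is the minimal curve family with an identifiable
inter-phase deceleration — the diauxic shift between fermentative and
oxidative growth. No functional form is asserted for the real curves; this
is a modeling choice for the generator. Units: time in hours, OD
dimensionless, rates in 1/h.

Default strain × medium kinetics are calibrated **qualitatively**: in
ammonium-sulfate (AS) medium all four strains reach similar 24 h density,
with WT and `jlp1∆` diauxic (intact respiration) and the SDH-loss strains
single-phase (fermentative only); in isethionate (ISE) medium the ordering
is WT > `sdh1∆` ≈ `sdh2∆` ≫ `jlp1∆`, with `jlp1∆` near-flat because its
sulfonate dioxygenase is deleted. No quantitative OD values are claimed.

ISE kinetics saturate early (mid1 = 2 h, rate1 = 1.5/h): sulfur-limited
cultures are modeled as reaching their density ceiling within the first
assay reads. This is a deliberate generator design: the screen's hit rule
demands Z > 0 at ≥ 6 of 7 reads, which is only attainable when the
treated/control separation exists from the second read onward — the regime
the original assay operated in. With slow-developing separation the 6-of-7
rule has essentially no power at the screen's noise level, so the planted-
recovery benchmarks would measure the calibration, not the scoring code.

Noise is homoscedastic across wells (sd 0.01 OD by default, the scale of
technical replicate scatter in a plate reader); a single noise model keeps
the mock-s.d. rule exact in expectation.

## Compound effects

Planted effects scale the logistic capacities by (1 + magnitude) when the
well's (strain, medium) is in the effect's target set:

- **suppressor** — +10–20% (default +15%) in {`sdh1∆`, `sdh2∆`} × {ISE}
  only; the selective phenotype the screen seeks.
- **sulfate_bypass** — default magnitude +1.0 in every strain and medium:
  a formulation that donates sulfate relieves the sulfur limitation itself,
  rescuing even `jlp1∆` on ISE. The magnitude is intentionally large; it is
  what makes the bypass-suspect verdict detectable in a 4-replicate assay.
  These compounds carry `contains_sulfate=True` in the generated library,
  so exclusion logic — not the Z threshold — must remove them.
- **toxic** — negative magnitude (default −0.5); exercises the requirement
  that hits stimulate growth (µₚ > µₙ), since inhibition also separates
  from controls and would otherwise score.
- **colored** — constant +0.3 OD offset, no growth change; absorbance of
  the compound itself. Detection is via the library's `colored_solution`
  flag (visual inspection in practice); no spectral inference is attempted.

Screen layout: compounds fill columns 1–10 row-major; vehicle controls
occupy the last column (the published layout is unstated; the position is
configurable). Single experimental wells per compound force the mock-s.d.
rule to be exercised everywhere.

## Screen statistic and hit rule

The per-timepoint statistic is the screening-window Z,
`1 − 3(σₚ+σₙ)/|µₚ−µₙ|`, with sample (n−1) standard deviations, controls
pooled per plate, and σₚ := σₙ for single wells. Z is undefined (NaN, with
an `undefined` flag) at zero separation; it is never ±∞. The displayed
equation in the source assay is available only as an image; the form used
here is the conventional screening statistic consistent with every printed
property (Z ≤ 1, Z > 0 as the separation criterion, the mock-σₚ rule).
Ranking uses the median Z across reads (ties broken lexicographically by
compound id); the published single-value ranking statistic is otherwise
unspecified.

## Percent change and error propagation

`pct = 100(t−u)/u`; the error is first-order (delta-method) propagation of
independent treated/untreated errors. The source describes propagation
without a formula; the first-order form is standard and is validated
against a 10⁶-draw Monte-Carlo s.d. to within 5% relative in the
sd/mean ≤ 0.1 regime (beyond that regime the 1/u nonlinearity makes the
first-order error an underestimate). Callers choose s.d. or s.e. (`se=True`
divides by √n); the screen uses s.d. throughout.

## Diauxic detection

The smoothed growth rate (centered moving average, window 3, of the first
difference) must show two local maxima ≥ `min_phase_rate` (default
0.02 OD/h) separated by a valley below half the smaller maximum; the shift
time is the valley position. Peaks at the series boundary do not count.
The parameters are implementation choices — the phenomenon is identified by
eye in practice — and detection is invariant to additive OD offsets.

## Statistics core

- One- and two-way ANOVA use the classical balanced sum-of-squares
  decomposition with p-values from `scipy.stats.f`; the decomposition is
  cross-checked against `statsmodels` OLS `anova_lm` in the tests.
  **Only balanced complete two-way designs are accepted** (the analyzed
  designs are balanced); unbalanced data is a hard error rather than a
  silent Type-I/II/III choice.
- Tukey HSD uses `scipy.stats.studentized_range` (vetted numerical
  integration, ≤ 1e-6 absolute error) with the Tukey–Kramer standard error;
  for k = 2 the adjusted p equals the pooled t-test p exactly. On two-way
  designs Tukey is applied to the strain × treatment cell means.
- Multiple testing: Benjamini–Hochberg step-up via statsmodels. BH is the
  documented choice where only "adjusted P" is specified. Note that BH is
  *not* idempotent in general (re-adjusting [1.0, 0.25] → [1.0, 0.5] →
  [1.0, 1.0]); the suite asserts the true invariants (never decreasing,
  capped at 1, order-preserving).
- Degenerate inputs resolve explicitly: zero residual variance gives F = 0,
  p = 1 when the effect sum of squares is also zero, else F = ∞, p = 0.
- Stars: * p<0.05, ** p<0.01, *** p<0.001.

## Proteome simulation and differential analysis

Log2 abundances are Gaussian (sd `noise_sd`, default 0.25) around a
protein base level ~ N(10, 2); differential proteins carry a signed true
log2FC of magnitude 2.5 by default, ~90% down in the mutant. The default
partition — 991 shared, 24 unique to the first comparison, 77 to the
second, out of 6000 detected proteins — mirrors a proteome in which SDH
loss remodels ~1100 proteins, ~91% of them shared between the two mutant
strains. (The source text swaps the two unique-count labels relative to
their own set sizes, 1015 and 1068; this package reports the
arithmetic-consistent assignment: 1015 − 991 = 24, 1068 − 991 = 77.)

Observed log2FC is the log2 ratio of group means after flooring: zeros are
replaced by half the smallest nonzero abundance in the matrix, and such
proteins are flagged `floored` so the large nominal fold-changes of
all-or-nothing proteins stay auditable. The test is Welch's t on log2
abundances (no test is named in the source; Welch is robust to the
unequal variances that arise near the floor), BH-adjusted, with the dual
threshold adjusted-P < 0.05 and |log2FC| > 1.5 — "adjusted" being the
stricter of the two printed variants. Fold-change correlation is Pearson by
default (Spearman by flag).

A direction-split subtlety: the Pearson correlation between the two
comparisons' fold-changes depends on the null fraction. At the full 6000-
protein scale r > 0.93; restricted to mostly-differential subsets the
mean-centering of the skewed direction split lowers r below 0.9, which is
why the correlation benchmark runs at full scale.

## Metabolite simulation and ratio analysis

Defaults: succinate 150 µM in WT, 5× in mutants (the elevation is stated
as "up to" five-fold; 5 is a calibration choice, not a reproduction
claim); 2KG 120 µM in WT, halved in mutants; treatment (modeled on DMAE)
lowers mutant succinate by 40% and leaves WT untouched; 3 replicates;
concentrations Gaussian with 10% coefficient of variation. Choline is
included as a relative-quantitation metabolite (raised ~8.5× by treatment)
to exercise the rule that relative-unit metabolites may enter folds and
ANOVA but never cross-metabolite ratios, which require commensurate units.
Ratio summaries report s.d. over the replicates.

## Problem sizes in the benchmark suite

The planted-recovery and calibration checks use: the full 1280-compound
screen; 6000-protein matrices for stochastic recovery and 1500-protein
noiseless matrices for exactness; 200 seeded replicates for metabolite fold
recovery; 10⁴ null replicates for ANOVA size; 10⁵ permutations for the
Tukey oracle; 10⁶ Monte-Carlo draws for error propagation. The Tukey-vs-
permutation comparison runs on an exchangeable (null) fixture, where the
permutation distribution is a valid reference, with tolerance 0.03 covering
Monte-Carlo error plus permutation discreteness at n = 15; under a planted
shift only the star-level conclusions are compared, since exchangeability
fails there. The null type-I band for the metabolite interaction test is
[0.025, 0.075] over 1000 replicates (±3.6 binomial s.d. around 0.05).

## What the synthetic benchmarks do not show

The generator omits several features of real plate data: edge-well
evaporation and plate-position effects (no B-score/loess normalization is
implemented, matching the source analysis), heteroscedastic or
multiplicative OD noise, carry-over between reads, compound
autofluorescence beyond a constant offset, and any mechanistic coupling
between growth, proteome, and metabolome — the three data layers are
simulated independently. Passing the planted-recovery suites therefore
demonstrates correctness of the scoring, exclusion, and inference logic
under the stated statistical structure, not robustness to artifacts real
screens may contain. Background (blank-well) subtraction is off by default
and available as a switch.

## Other design decisions

- Long-format CSV is canonical on disk; wide plate-grid CSV is read-only.
  Well coordinates are letter rows / 1-based columns; time is decimal
  hours (minutes accepted via a dialect flag).
- Whether µₚ − µₙ was signed or absolute in the original calculation is
  unstated; the implementation uses |µₚ − µₙ| and enforces direction
  separately (µₚ > µₙ) when counting positive reads.
- The selectivity classifier is dose-agnostic: any tested dose may satisfy
  the pattern, since the effective dose per strain is not specified.
- Edge wells are not excluded and no evaporation correction is applied, as
  none is described for the source assay.
- All seeds are explicit function arguments or config fields; there is no
  global random state. Pipeline stages draw child seeds from per-stage
  `SeedSequence` spawns so a stage subset reproduces the full run's data.
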