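# Methods

`cqdiff` implements the complete decision pipeline for a small case–control
screen of circulating miRNAs measured by qPCR: given a wide table of
quantification-cycle (Cq) values for an ~84-assay plasma panel on two matched
patient groups, it answers whether any miRNA's relative abundance differs
between the groups, after explicit quality gates. This note documents the
models, the defaults and why, the numerical choices, and the limits of what
the synthetic-data tests demonstrate.

## Data model

A `CqMatrix` is a samples × assays matrix of Cq values (PCR cycles; lower Cq
means more template). "Not detected" is a first-class missing state (`NaN`),
distinct from any numeric value: in plasma panels it almost always means the
template concentration was below the limit of detection, not that the
measurement failed. Present values must lie in (0, 45]; 45 cycles is the
customary instrument ceiling. Each assay carries exactly one role — `target`,
`reference`, `hemolysis_marker` or `spike_in`. An assay may still serve two
purposes through configuration: miR-23a-3p is a reference *and* the constant
marker of the hemolysis pair, which is configured by id, not by role.

## Quality gates

**Spike-ins.** Synthetic controls (UniSp2/4/5 for isolation, UniSp6 for
reverse transcription) are added at fixed concentrations, so their Cq should
be tight across samples. The report flags any sample whose spike Cq deviates
from the cohort median by more than a window (default ±2 cycles). No absolute
Cq bounds are imposed — acceptable spike levels are chemistry-dependent.

**Hemolysis.** Red-cell lysis floods plasma with miR-451a while miR-23a-3p is
stable in blood, so dCq = Cq(miR-23a) − Cq(miR-451a) rises with contamination
(contamination lowers the miR-451a Cq). A sample is flagged when dCq exceeds
7 cycles *strictly*, the conventional cutoff. Flagged samples are retained by
default — low-grade hemolysis is often unavoidable in clinical collection and
the flag is informational; `drop_hemolyzed=True` (CLI `--drop-hemolyzed`)
excludes them instead.

**Low-input samples.** A sample whose mean reference Cq is far above the rest
carries too little RNA and would produce spurious missingness. Because an
ad-hoc visual exclusion is not reproducible, two explicit rules are provided:
a robust z-score on the per-sample mean reference Cq, |x − median| /
(1.4826·MAD) > 3.5 (default), and a gap rule (mean exceeds the next-highest
sample by > 3 cycles). With MAD = 0 only samples actually deviating from the
median can flag. Samples with no detected reference at all are flagged
`no_reference_signal`. Flagged samples are excluded before the assay filter,
so missingness denominators use the retained samples only.

**Assay filters.** A target assay is excluded when its missing fraction
strictly exceeds 0.5 ("more than half the samples"); reference, hemolysis and
spike assays are exempt but reported. Manual exclusions (e.g. an assay with
non-specific amplification on the melt curve — a wet-lab call this package
takes as input, never recomputes) are applied idempotently with logged
reasons.

## Normalization and fold change

Relative expression is `2^-(Cq(miRNA) − mean reference Cq of the sample)`,
with the arithmetic mean over the sample's *detected* reference Cq values
(the number used is logged; a partial reference dropout does not fail the
sample). The construction makes expression exactly 1 when an assay sits at
the reference mean, and makes any global per-sample Cq offset cancel
identically — the property the synthetic generator exploits to verify the
implementation to machine precision.

Fold change per assay is the quotient of arithmetic group means of
normalized expression, cases over controls, on complete cases (no
imputation; a geometric-mean option exists behind a flag). An assay with an
entirely missing group is marked non-evaluable.

## The Yuen–Welch permutation test

With 10 samples per group and heavy-tailed expression ratios, the test
statistic is Yuen's robust generalization of Welch's t: for trim proportion
γ (default 0.10), g = ⌊γ·n⌋ observations are removed from each tail for the
trimmed mean, and the standard error uses the Winsorized variance s²w
(tails replaced by the nearest retained order statistic, divisor n − 1):

    T = (x̄t − ȳt) / √(d_x + d_y),   d_j = (n_j − 1) s²w_j / (h_j (h_j − 1)),

h_j = n_j − 2g_j. At γ = 0 this reduces exactly to Welch's t, which the test
suite verifies to 1e-12 against an independent implementation.

Significance comes from a label permutation null: group labels are permuted
without replacement B times (default 1000), T recomputed each time, and

    p = (1 + #{|T*| ≥ |T_obs|}) / (B + 1),

the add-one estimator, which is strictly positive and slightly conservative.
An exhaustive enumerator (`exhaustive_permutation_test`) provides the exact
p for small groups and serves as the Monte-Carlo oracle. Degenerate cases:
identical pooled values give p = 1; a permutation with zero Winsorized
spread contributes T = 0 on a tied difference and ±∞ otherwise (counted as
maximally extreme).

Each assay's permutations run on an independent RNG stream spawned from the
single root seed (default 123) in assay order, so per-assay p-values are
reproducible and unchanged by dropping other assays. Reproducing another
software stack's exact permutation draws is not attempted; borderline assays
can shift by roughly ±1 count in a screen.

Benjamini–Hochberg adjustment (step-up, via statsmodels, NaN-aware) spans
all tested assays. **Classification uses the raw permutation p**, not the
adjusted one: down iff FC < 0.67 and p < 0.10, up iff FC > 1.5 and p < 0.10,
all boundaries strict. In a pilot-scale screen the BH-adjusted values rarely
clear any threshold; they are reported alongside so the reader sees the
multiplicity cost. α = 0.10 (not 0.05) is the conventional pilot-screen
choice; both FC thresholds and α are configurable.

## Propensity matching

Case–control selection uses a main-effects logistic propensity model
(scikit-learn, unpenalized). If the fitted scores perfectly separate the
groups — the logistic MLE then does not exist — the fit falls back to a
ridge-penalized model with a warning, keeping scores strictly inside (0, 1).
Constant covariates are dropped; samples with missing covariates are dropped
from matching (no imputation), both with warnings. Matching is greedy 1:k
(default 1:1) nearest-neighbor without replacement, cases processed in
descending score order with input-order tie-breaking (documented because
greedy results are order-dependent), distance on the probability scale by
default (`logit_distance` optional), optional caliper. Balance is reported
as standardized mean differences, SMD = (m̄c − m̄k)/√((s²c + s²k)/2), before
and after matching; zero pooled variance yields SMD 0 on equal means and a
non-evaluable NaN otherwise.

## Synthetic data: what it emulates and what it does not

The generator mirrors the screen's geometry: 84 miRNA assays (3 references,
the miR-451a hemolysis marker, 80 targets), 4 spike-in channels, 10 cases vs
10 controls. Per miRNA cell,

    Cq(s, a) = baseline_a − δ_a·[s case] − sample_effect(s) + ε,

so a true log2 fold change δ is exactly −δ cycles — the normalization
identity is exact by construction. Defaults, chosen once as realistic for a
plasma focus panel: target baselines ~ Normal(28, 3) cycles; technical noise
sd 0.5 cycles; per-sample global shift sd 0.5 cycles (absorbed by the
reference mean); LOD ceiling 37 cycles with censoring applied after noise,
so missingness is mechanistic, not missing-at-random; reference baselines
29/30/24; miR-451a baseline 20, putting the uncontaminated hemolysis dCq at
4 cycles — the level expected of non-hemolyzed plasma and ≈4 SD below the
flag threshold, so the deterministic dCq rule achieves 100% sensitivity and
specificity when contamination is injected by shifting a sample's realized
dCq past the threshold; spike-ins at 100-fold (log2 100 ≈ 6.64-cycle) steps
with technical noise only. Covariates (age, sex, NIHSS, stroke subtype) are
drawn at study-plausible levels; a separate cohort simulator induces genuine
confounding for matching tests by selecting cases with covariate-dependent
probability.

Not emulated: amplification-efficiency differences between assays, plate
position effects, inter-plate calibration, melt-curve behavior, and any
resemblance to particular patients' values. Passing recovery tests therefore
demonstrates the *pipeline's* correctness under its stated model, not
biological validity of any marker.

One calibration subtlety: all assays of a sample share the reference-channel
technical noise (the mean of three reference assays' ε enters every
normalized value), so test outcomes are positively correlated *within* a
panel even under the global null. Marginal calibration is exact (measured
null rate 0.093–0.100 at α = 0.10 across panel batteries), but the dispersion
of per-panel hit rates exceeds the binomial; calibration checks therefore
treat the panel, not the assay, as the sampling unit.

## Problem sizes and numerical choices

The self-contained validation battery runs at: 1000 random instances for the
Welch reduction (agreement to 1e-12); exhaustive-vs-Monte-Carlo comparison
at B = 20000 for groups ≤ 5; 2000 null simulations (10 vs 10, B = 1000) for
type-I error at α = 0.05, expected in [0.04, 0.06]; 100–200 synthetic panels
for fold-change recovery (median within 0.15 of truth; medians are taken
over panels where the assay is evaluable, since a strongly depleted assay
can fall entirely below the LOD in a rare panel); 100 panels for the
down-classification rate of a δ = −2 assay (≥95%); 200 confounded cohorts
for balance improvement (≥90%). Ties in permutation counting use exact
`>=` comparison; trimming uses ⌊γ·n⌋ per tail; BH handles missing p-values
by excluding them from the family size.

## Design choices where the design was open

- The pipeline is organised around its procedural stages; the
  transform/fit-shaped pieces additionally expose scikit-learn-style
  estimators (`CqNormalizer`, `DifferentialExpressionTest`,
  `PropensityMatcher`) so they compose with sklearn pipelines, while the
  module-level functions remain the primary surface for the screening
  workflow itself.
- Arithmetic (not geometric) group means for fold change — the headline
  definition in this field's reports; geometric offered as an option.
- Complete-case analysis throughout; no imputation rule is defensible at
  n = 10 with LOD-mechanistic missingness.
- The studentized statistic (not the raw trimmed-mean difference) is
  permuted — the standard choice for unequal variances.
- Missing-value sentinels (`NA`, `Undetermined`, blank, …) are configurable
  because qPCR export dialects vary; wide samples-as-rows orientation is
  canonical with a transpose flag for assay-row exports.

## Known limitations

Greedy matching is not optimal matching; with few controls per case the
pairing can be improved by optimal assignment (out of scope). The
permutation test needs ≥2 complete cases per group and loses resolution
below ~5 per group (p is then better taken from the exhaustive enumerator).
Efficiency-corrected quantification (per-assay amplification efficiencies)
and inter-plate calibration are out of scope: the intended design is a
single-plate panel.
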