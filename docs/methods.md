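# Methods notes

## Scope and model assumptions

The package analyses three data types produced by CHC/attractiveness
studies in *Drosophila*: per-compound MS intensities, two-choice trial
records (trajectories or bout lists), and qPCR cycle thresholds. It starts
downstream of instrument processing — peak picking, compound
identification, and video blob tracking are out of scope; inputs are
already tabulated intensities, positions, bouts, and Ct values.

### Relative quantitation

Raw intensity of compound *i* in sample *s* is modelled as
`x_si = e_i · a_si`, with `e_i` an unknown compound-specific detection
efficiency constant across samples and `a_si` the biological signal. The
per-sample normalization `x̃_si = x_si / Σ_j x_sj` (sum over identified
hydrocarbons only) removes any factor that multiplies a whole sample, but
compound-specific efficiencies do **not** cancel across compounds: relative
*changes* between groups are interpretable, absolute levels and
between-compound comparisons are not. Compounds not flagged as identified
hydrocarbons are excluded from the denominator and dropped. The one common
oxygenated profile component (C27H54O2) is treated as identified by
default, switchable per descriptor.

Normalized shares are compositional: they sum to 1 per sample, so
injecting an effect into some compounds necessarily shifts the shares of
all others, and an effect that multiplies every compound equally is
invisible after normalization. Tests and examples account for this.

### ln transform and zeros

Analyses run on `ln x̃`. Zero relative intensities (chromatographic
non-detection is treated as true absence, not missing-at-random) are
floored at ε = half the smallest positive normalized intensity in the
table: `ln max(x̃, ε)`. Values at or above ε map exactly (so x̃ = 1 gives
0); ε is recorded in the table metadata. The floor (rather than an
additive pseudo-count) keeps the transform the identity-on-ln for all
detected values.

### Per-compound ANOVA and multiplicity

Two-factor ANOVA with genotype and age as categorical factors plus their
interaction, fitted per compound on the ln scale via OLS with Type II sums
of squares. Type II is the convention for the unbalanced case; all
conventions coincide on balanced designs, which is what the generator
produces and what the oracle fixtures use. Compounds with zero residual
degrees of freedom are flagged, their p-values set missing, and excluded
from the Holm correction. No automatic outlier removal; callers can drop
samples or compounds explicitly. The Holm step-down is implemented
directly so per-rank thresholds can be reported, and is cross-checked
against the statsmodels implementation in the tests.

### Genotype main effects and chain-length regression

"Main effect across ages" is the unweighted mean of per-age group means
(equal cell weighting), and requires both genotypes measured at the same
ages. Percent change is undefined (flagged, dropped from regressions) when
the control mean is zero. The chain-length regression is plain OLS of
percent change on carbon count; carbon counts include methyl branches
(2-MeC26 counts 27). Because shares renormalize, an injected ln-slope of
β per carbon appears as a percent-change slope slightly below 100·β — the
mutant denominator grows when long chains are up-weighted — which is why
recovery tests allow a margin around the small-effect value.

### PCA + ANCOVA

PCA is computed on the compound **correlation** matrix: compounds are
standardized to unit variance so abundant compounds do not dominate, and
the spectrum of the correlation matrix (numpy `eigh`) gives variance
fractions that sum to 1 over all components. Zero-variance compounds are
dropped with a log entry. Scores are the standardized data projected on
the eigenvectors; loadings are eigenvectors scaled by the square root of
their eigenvalues. Each retained component gets an ANCOVA (genotype
factor, age continuous, interaction); the interaction term is reported
separately so "aging shifts both genotypes in parallel" can be asserted as
a non-significant interaction. Whether to run PCA on normalized or
ln-normalized shares is a user choice; both states are accepted,
ln-normalized being the default used in examples (matching the ANOVA
scale).

## Preference assays

Dwell scoring counts a frame when the distance to a target is ≤ 3 mm
(boundary inclusive); frames with missing coordinates are dropped from
numerator and denominator. Circles separated by ≤ 2r are an error (the
trial cannot be scored). Video trials with total target time strictly
under 50 s are excluded; totals of exactly 50 s are kept. Live-assay bouts
count only when strictly longer than 20 s; the live assay has no
minimum-total rule.

Wilcoxon signed-rank vs 50%: zero differences dropped; exact distribution
for n ≤ 25 when the absolute differences are tie-free, otherwise the
normal approximation with continuity correction (the exact distribution
assumes distinct ranks).

The stratified permutation test flips each trial's two treatment labels
independently with probability ½ — randomization confined within trials
and hence within replicates — recomputing the pooled statistic (mean
preference over kept trials by default; median by flag) for each
randomization. Tail probabilities use the add-one rule
`(1 + #{null ≥ obs})/(n + 1)` with ties counted as extreme, guaranteeing
p ∈ (0, 1]; the exhaustive-enumeration oracle in the tests uses raw
proportions. An alternative `pooled-within-replicate` scheme permutes the
label multiset over all 2m dwell-time slots of a replicate (a trial can
then draw two identical labels, scoring 0 or 100 for that draw); the
phrase "randomized among flies within a replicate" is ambiguous between
the two readings, so both are provided and the per-trial flip is the
documented default. Video (30 min) and live (10 min) trials are scored by
different rules and should not be pooled into one permutation analysis.

## qPCR

Technical replicates are averaged to one Ct per (condition, biological
replicate, gene) before differencing — how technical replicates were
combined is rarely stated in publications; averaging per extraction is the
natural reading. Manipulated and control biological replicates are paired
by label when the label sets match, otherwise each manipulated replicate
is compared to the mean control ΔCT (switchable). The z-test uses the
standard normal despite small n, the conventional choice in ddCt reports;
a t-variant is available behind a flag. Degenerate cases: zero variance
with zero mean gives p = 1, zero variance with nonzero mean gives p ≈ 0,
both flagged.

## Synthetic-data generators

The generators emulate the statistical structure the analyses assume, with
all randomness drawn from one explicit seed per call, and return a
ground-truth record of every injected parameter.

**CHC tables** — log-normal intensities:
`raw = e_i · exp(ln a_i + g_i·[mutant] + β(c_i − c̄)·[mutant] + δ·(age − age₀) + N(0, σ))`.
Log-normal noise matches the analysis's ln-scale normality assumption;
detection efficiency is a fixed per-compound multiplier constant across
samples, making normalization meaningful and absolute levels
unrecoverable. LDI-MS positional variability has no published
distributional form and is folded into the per-sample noise. Defaults (the
study conditions): 26 compounds spanning C21–C29 in a composition like a
female fly profile (alkanes, 7- and 9-monoenes, 7,11- and 5,9-dienes,
2-methyl alkanes, one oxygenated compound), 2 genotypes × 4 ages
(6/23/37/48 d) × 3 replicate extractions, σ = 0.3 ln units (typical
between-extraction scatter), age drift 0.01/day, mutant chain slope
0.05/carbon, no uniform genotype effect. Baselines and efficiencies are
drawn per compound from the seed unless supplied.

**Trajectories** — a discrete-time two-state process (at-target vs
wandering), not a physical walk: only dwell times enter the analysis.
Visit and wander bout lengths are exponential (mean visit 10 s; wander
mean set so the expected in-circle fraction equals `dwell_fraction`, 0.3
by default); each visit goes to the manipulated target with probability
`true_preference_pct/100`; wandering positions are uniform over the arena
excluding both circles, and visit positions are jittered inside the
circle. Defaults: 30 min at 2 frames/s, 55 mm circular arena, targets
18 mm apart and 8.5 mm from the wall (midpoints of the conventional
15–20 mm / 7–10 mm placement), 3 mm scoring circles. What it does not
emulate: courtship micro-behaviour, wall-following, or tracking noise —
so passing recovery tests validates the scoring and inference chain, not
any claim about real male movement statistics.

**Ct tables** — `Ct = baseline(gene) − ln(expr)/ln 2 + N(0, σ_ct)` with
ln(expr) = 0 in controls and the injected ln fold change under
manipulation; the reference gene is constrained to zero fold change.
Defaults: rp49 reference plus four synthesis genes, 2 conditions × 3
biological × 5 technical replicates, σ_ct = 0.15 cycles.

## Problem sizes in tests and the acceptance script

Null calibrations use 40 tables × 26 compounds (1040 ANOVA p-values;
marginal rejection rate checked against the exact binomial 99% interval
and uniformity by Kolmogorov–Smirnov) and 500 no-preference experiments of
12 trials at 600 s observation with 2000 randomizations each — sizes
chosen to make Monte-Carlo error small relative to the tolerances while
keeping the default run quick. The acceptance script uses 20 tables, 200
behavioural experiments, and 30,000 randomizations for the single-fixture
checks. Within-table p-values share a normalization denominator and are
therefore weakly dependent; the 200-table check confirms this dependence
is negligible for the calibration bands used.

## Known limitations

- Compositional dependence means per-compound tests are not independent;
  Holm controls family-wise error regardless, but joint interpretations
  across compounds should be made on the PCA components.
- The permutation schemes assume the two dwell times within a trial are
  exchangeable under the null; systematic side biases are not modelled
  (the alternating-placement design they motivate is a data-collection
  concern upstream of this package).
- ddCt assumes equal amplification efficiency across genes; no standard
  curves or efficiency corrections are implemented.
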