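# chctools

Analysis toolkit for studies linking genetic manipulations to cuticular
hydrocarbon (CHC) pheromone profiles and sexual attractiveness in
*Drosophila*. It covers the three quantitative tracks such studies run —
mass-spectrometric CHC profile statistics, two-choice preference assays,
and qPCR of CHC-synthesis genes — together with seeded synthetic-data
generators that emulate each data type with known ground truth, so every
statistical procedure can be validated against injected effects and
calibrated against its null.

## Who this is for

Behavioural geneticists and chemical ecologists who have per-compound peak
intensities (GC/MS chromatographic peaks or intact-fly LDI-MS ion
signals), tracked male trajectories or hand-timed courtship bouts from
two-choice trials, and qPCR cycle thresholds — and want the corresponding
statistics done reproducibly from Python.

## The methods

**Relative quantitation.** Detection efficiency is compound-dependent in
both GC/MS and LDI-MS, so absolute amounts are unrecoverable. Each sample's
intensities are divided by the summed intensity of all identified
hydrocarbons in that sample: `x̃ᵢ = xᵢ / Σⱼ xⱼ`. Any per-sample
multiplicative factor — detection efficiency, extraction yield, laser
positioning — cancels exactly.

**Profile statistics.** Per compound, a two-factor ANOVA of ln-relative
intensity on genotype × age (Type II sums of squares), with a
Holm–Bonferroni step-down over compounds (compare the k-th smallest p to
α/(m−k+1), stop at the first failure) and the chance expectation `m·α`
reported alongside. Genotype effect profiles (difference and percent change
of mean normalized intensity, main effect averaged with equal weight per
age) feed an OLS regression of percent change on carbon-chain length and
cross-manipulation correlations. Correlation-matrix PCA summarizes whole
profiles; per retained component an ANCOVA with genotype, age, and
genotype×age tests whether aging shifts the genotypes in parallel.

**Preference assays.** A video trial's dwell time is the number of frames
within 3 mm of each target divided by the frame rate; preference is
`100·t_manip/(t_manip + t_ctrl)`; trials with under 50 s of total target
time (2.8% of a 30-min recording) are excluded. Live trials sum courtship
bouts strictly longer than 20 s. The no-preference null (50%) is tested by
a one-sample Wilcoxon signed-rank test and by a replicate-stratified
permutation test: treatment labels are randomized within trials (each
trial's labels flip with probability ½, so randomization never crosses
replicates), the pooled statistic is recomputed for each of 30,000
randomizations, and tail probabilities are read off the pooled null with
the add-one rule `p = (1 + #extreme)/(n + 1)`.

**qPCR.** ΔCT = Ct_gene − Ct_reference per condition and biological
replicate (technical replicates averaged first), ΔΔCT = ΔCT_manip −
ΔCT_control, fold change `2^−ΔΔCT` reported as `ln FC = −ΔΔCT·ln 2`, with a
z-test of the replicate mean against zero.

## Worked example

```bash
python examples/preference_assay.py
```

```
40/40 trials kept (exclusion: total target time < 50 s = 2.8% of the 30 min recording)
mean preference for the manipulated female: 64.8% (true value 65%)
Wilcoxon vs 50%: W = 4, p = 5e-08 (normal-approx, n = 40)
stratified permutation test (30,000 randomizations): one-sided p = 3.3e-05
live bout list: 25 s vs 30 s courtship -> preference 45.5% (bouts of <= 20 s do not count)
```

Forty simulated 30-min trials with a true 65% preference for the
manipulated female: every trial clears the 50 s exclusion rule, the scored
mean recovers the injected preference, and both tests reject the
no-preference null decisively. `examples/chc_profile_analysis.py` and
`examples/qpcr_fold_change.py` walk the other two tracks the same way
(profile ANOVA + Holm + chain-length regression + PCA/ANCOVA, and ddCt
fold-change recovery).

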