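# Methods

This note documents the models, defaults, and design choices behind
`neurometab`, and what the synthetic test conditions do and do not
establish.

## Synthetic data model

The generator emulates the inputs of a 145-subject (60 MCI / 85 control)
imaging-metabolomics study with planted, recoverable structure.

**Gray matter.** Each subject's volume is a probability map on a
32 × 32 × 22 grid: a 2-voxel low-probability shell (0.05) around an
interior at base probability 0.70, plus i.i.d. voxel noise
(sd 0.03). Five ellipsoidal regions of 150 voxels each (axis-aligned,
nearest-voxel digital balls — star-shaped, hence 26-connected) are planted
in the interior. Each (subject, region) pair receives a shared
random offset (sd 0.06) representing anatomical variation, and MCI subjects
lose `atrophy_effect` = 10% of the base probability inside regions. The
across-subject mean map thresholded at 0.3 yields a 14,112-voxel mask.

Why these numbers: the voxel-level case/control effect size is
d ≈ 1.0, large enough that the pre-specified VIP ≥ 2 with > 2% mean
difference rule recovers regions at study-scale n, while the per-region
anatomical variance keeps between-region correlation low (≈ 0.25) so that
planted communities are separable. With atrophy set to 0 the selection rule
is calibrated (see "Null behavior").

**Metabolomics.** 2,500 LC-MS features with triplicate intensities.
Feature log2 abundance is N(16, 1.5) plus unit-variance subject noise.
Twelve signal features per region add β·z_r, where z_r is the standardized
region-mean GM and β is set so the population correlation equals the
feature's coupling, drawn uniformly in 0.60 ± 0.22 with random sign. The
spread matters: replication is summarized by a regression of validation on
training correlations, which is only informative when true correlations
vary across signal pairs. Batch structure is a per-feature location shift
(centers ±0.4 log2 units for two batches, per-feature jitter sd 0.3);
replicates carry multiplicative lognormal noise at CV 0.15. Missingness:
2% of replicate cells at random; 5% of features lose 35% of their cells in
both groups (these must be excluded by the missingness filter); 2% lose 30%
of MCI cells only (group-structured; these must be retained and imputed);
2% of features get population replicate CV 2.5 (their 3-replicate sample CV
has median ≈ 0.9, above the 0.75 filter — note a 3-replicate sample CV
badly underestimates a heavy-tailed population CV, which is why the planted
value is far above the threshold). A left-censoring mode
(`censored_missing`) exercises intensity-dependent missingness.

**m/z and pathways.** Signal features take m/z = compound mass + adduct
offset (M[1+] −0.000549, M+H +1.007276, M+Na +22.989218 Da) with ≤ 2 ppm
jitter; 100 background features match decoy compounds the same way; the
rest are uniform on the 85–1275 scan range. The compound database holds the
60 signal compounds plus 140 decoys in 25 pathways; the planted pathway is
10 compounds, all mapped to signal features of one region. Retention times
are uniform 20–300 s and carry no signal.

All randomness flows from one seed through `SeedSequence` children per
stage; identical configs are byte-identical.

## Statistical components

**Preprocessing order.** CV filter → replicate-correlation filter →
median summarization → ComBat → missingness filter/imputation → log2 +
quantile normalization. ComBat requires (near-)complete data yet the
cascade's missingness handling comes after batch correction, so ComBat runs
on summarized log2 values with missing cells excluded from the
empirical-Bayes estimation, then back-transforms. The "< 20% missing"
rule is read as *retain if below threshold in at least one diagnosis
group* (a `require_both_groups` switch gives the stricter reading), and
half-minimum imputation is per feature (`global_half_min` switches to the
table minimum).

**ComBat.** Parametric empirical-Bayes location/scale adjustment: features
are standardized by pooled residual variance; per-batch feature means get a
normal prior and per-batch scales an inverse-gamma prior, both fit by
method of moments; shrunken effects are removed and the grand means
restored. Its simulation behavior matches the Bioconductor reference:
a planted 2.0 log2 shift collapses to the sampling-noise floor of the batch
means (mean residual |difference| ≈ 0.1 at n = 50/batch — no method can
go below that floor), and a 4:1 variance ratio returns to ≈ 1 up to
residual F-noise.

**PLS-DA.** NIPALS partial least squares on mean-centered, unit-variance
voxels with diagnosis coded ±1 (fit via scikit-learn's `PLSRegression`).
Component count 1–5 chosen by stratified 3-fold CV maximizing balanced
accuracy, ties to the smaller model, refit on all data. VIP is normalized
so mean(VIP²) = 1; for one component it reduces to √p·|w_j|/‖w‖, which the
tests use as a closed-form oracle. Percent difference uses the control mean
as baseline, positive = lower GM in cases; only the positive direction is
integrated, the negative direction is an artifact bin.

**Cutoff rule.** cutoff = min over voxels of (max over metabolites of |r|
among pairs with p < α). Edges use |r| ≥ cutoff: with a strict inequality
the voxel that defines the minimum would be orphaned, defeating the rule's
purpose. Voxels with no pair passing α are excluded from the minimum with
a warning.

**Communities and centrality.** Multilevel (Louvain) modularity
maximization on |r|-weighted edges via igraph, seeded and deterministic;
exhaustive partition enumeration provides the oracle on graphs ≤ 8 nodes.
Eigenvector centrality is the per-component Perron vector of the weighted
adjacency, normalized to max 1 per component (power iteration is the test
oracle; note bipartite adjacencies need a diagonal shift to make power
iteration converge). The cluster summary defaults to *edge-linked*
metabolite counting — a metabolite counts in every community containing one
of its voxel partners — which is how a published total of 816 links can
exceed 463 distinct metabolites; hard-partition counting is a mode switch.

**Enrichment.** Features → compounds by adduct mass match at 10 ppm;
features collapse to unique compounds before counting so multiple adduct
features of one compound cannot inflate the overlap. Fisher p is the exact
right-tail hypergeometric. The permutation p is the add-one empirical
estimator (1 + #{perm ≤ obs})/(1 + B), B = 100 by default: it is
exact-level, bounded below by 1/(B+1), and conservative under heavy ties
(k = 0 pathways sit at p = 1). A Gamma-fit mode was considered and
rejected: at the 0.05 level both make identical decisions on desk-scale
instances, and the empirical estimator has no fitting failure modes.

**Replication.** Per-stratum training size is round-half-up(0.67 · n),
which reproduces the published 40/57/20/28 split exactly. The training
integration reuses the full-data voxel set and cutoff (as the original
sensitivity analysis did); a fully nested re-selection is possible by
re-running the pipeline on the training subjects only.

**Annotation thresholds.** The original study judged contiguity by eye; the
formalization here (largest 26-connected component ≥ 50% of voxels and
majority atlas label ≥ 50%) is a documented reconstruction, configurable
per call.

## Null behavior and calibration

With `atrophy_effect = 0`, `coupling = 0` and no anatomical variance
(`region_effect_sd = 0`), the selection rule keeps ≤ 1% of mask voxels
(the VIP ≥ 2 tail joint with the > 2% mean-difference rule at study-scale
n). With the default anatomical variance left in, null counts are
*overdispersed*: a whole region's shared random effect can align with the
diagnosis labels by chance and push all its voxels over threshold together,
so occasional runs select a few percent. This is a property of spatially
correlated data, not of the implementation; tests bound the structureless
null at 1% and the correlated null at 5%. Null permutation p-values for the
planted pathway stay at the nominal 5% rate (bounded with binomial slack),
and permuted-label PLS-DA accuracy is 0.5 ± 0.05.

The percent-difference rule is only binding when group means are estimated
precisely; at very small cohorts (~20/group) its threshold falls inside the
sampling noise of the group means and the null selection rate rises. Null
calibration claims therefore refer to study-scale cohorts.

## What passing tests do and do not show

The generator produces blocks of voxels with a common signal, linearly
coupled lognormal features, location-only batch effects, and
missing-at-random cells (plus simple structured modes). Real data differ
in ways not modeled: spatial autocorrelation from smoothing, non-Gaussian
GM distributions, correlated metabolite modules independent of the brain,
intensity-dependent missingness everywhere, retention-time drift, and
isotope/adduct redundancy. Recovery at the default conditions shows the
pipeline is implemented correctly and calibrated — not that the original
cohort's specific findings would replicate.

## Problem sizes

Default conditions: 145 subjects, 14,112 mask voxels (~750 planted),
2,500 features (60 signal), 25 pathways. The full end-to-end run takes
roughly 15 s on one CPU; the complete test suite under a minute. Unit
tests use a down-scaled grid (22 × 22 × 16, two regions, 300 features)
with the same generative model.
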