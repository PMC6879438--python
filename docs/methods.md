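# Methods

This note documents the models, numerical conventions and design choices
behind `mclrad`, in the order the pipeline runs them.

## Segmentation

A lesion mask is the seed voxel's connected component (26-neighbour
connectivity by default, 6 optional) of voxels with SUV ≥ f·SUVmax, with
the fixed fraction f = 0.41 by default. SUVmax here is the maximum over
the *current* region, and the threshold is iterated to a fixed point:
start from the seed value, grow the component, update the maximum, and
repeat until the region's maximum stops increasing. Because the region
maximum is non-decreasing and bounded, the iteration terminates, and the
result is independent of which in-lesion voxel was seeded — including
the degenerate fraction f = 1.0, which converges to the argmax voxel(s).
The TMTV is the union of per-seed masks; touching lesions merge, and
components are relabelled on the union.

A background floor (default SUV 1.0) rejects seeds placed on background;
it never enters the threshold itself, so masks are exactly invariant to
global intensity rescaling. Externally drawn masks can be supplied
directly to the feature extractor in place of region growing.

The 41% threshold is defined per lesion (per seed component), not from a
global SUVmax — the standard reading, flagged here because either
convention exists in practice.

## First-order features

SUVmean and SUVmax are over the masked voxels; TMTV (mL) is the voxel
count times the voxel volume; TLG is computed literally as the product
TMTV × SUVmean (the identity is bit-exact, and asserted in tests).
SUVpeak is the maximum over masked voxels of the mean SUV in a 1 mL
sphere centred on the voxel; the sphere is realized as the set of voxel
offsets whose centres lie within the sphere radius (7 voxels at
5.5 × 5.5 × 3.3 mm spacing) and is clipped at grid edges.

## Co-occurrence texture

Grey levels come from fixed-bin-number quantization of the masked SUV
range: level = min(G, ⌊G·(x − min)/(max − min)⌋ + 1), G = 64 by default;
a constant region maps to level 1 everywhere. Co-occurrence counts are
accumulated for ordered in-mask voxel pairs separated by distance-1
offsets along the 13 unique 3-D directions (unique up to sign among the
26 neighbours), then symmetrized by adding the transpose. Offsets live
in voxel-index space; the physical anisotropy of the grid is ignored, as
co-occurrence radiomics conventionally does.

Each of the 16 features (Entropy, Homogeneity, Contrast, Correlation,
Angular second moment, Difference entropy, Difference variance, Inverse
difference moment, Sum average, Sum entropy, Sum variance, Cluster
prominence, Cluster shade, Maximum probability, IMC1, IMC2) is evaluated
per direction on the normalized matrix and arithmetically averaged over
directions with at least 20 voxel pairs (`min_pairs`); directions below
the minimum are excluded from the average, and a region with no valid
direction raises. Entropies use log base 2 (configurable), and zero
cells are omitted from entropy sums — the exact p→0 limit — rather than
guarded by an additive ε. Degenerate matrices (one occupied level)
define Correlation = 1 and IMC1 = IMC2 = 0.

Two consequences worth stating: absolute Entropy grows with G, so a
cut-off such as 3.5 is only meaningful on the binning/log-base scale it
was derived on; and Homogeneity/IDM are the inverse-difference forms
bounded in (0, 1].

## ComBat harmonization

The parametric empirical-Bayes variant of the classical location–scale
batch correction. Features are standardized per feature by the grand
mean (batch-size-weighted) and pooled residual variance from a
batch-design least-squares fit; per-batch location γ̂ and scale δ̂² are
estimated on the standardized scale and shrunk toward batch-level priors
(normal for γ, inverse-gamma for δ² with moment-matched
hyperparameters) by the usual coupled iteration, run to an absolute
change < 1e-6 (cap 500 iterations). The adjustment is
(z − γ*)/δ* mapped back to the original scale. Preconditions: ≥2
batches, each of at least `min_batch_size` (default 3) rows, no missing
values, no zero-variance feature (rejected by name). An optional
covariate design can protect biological variation during
standardization; it is off by default. The non-parametric variant is out
of scope.

Because every batch is mapped to the *pooled* scale, absolute group
differences change when batch scale effects exist; standardized effect
sizes are what harmonization preserves (the test suite asserts Cohen's d
retention, and F-test removal of injected batch effects in ≥90% of 100
simulations).

## MIPI, MIPI-b and metabolic risk

MIPI = 0.03535·age + 0.6978·1[ECOG ≥ 2] + 1.367·log₁₀(LDH/ULN) +
0.9393·log₁₀(WBC in 10⁶/L); MIPI-b adds 0.02142·Ki-67(%). Cutpoints
5.7/6.2 (MIPI) and 5.7/6.5 (MIPI-b) give categories 1 (low), 2
(intermediate), 3 (high). WBC is accepted in the clinical 10⁹/L unit
and converted internally. All constants sit in a config dataclass and
can be overridden.

Metabolic risk dichotomizes SUVmean and Entropy at their cut-offs
(defaults 3.55 and 3.5) and votes: both above → high; both at-or-below →
low; one of each → intermediate. Ties at a cut-off count as *below* it.
The two-category variant folds intermediate into low. MIPI-m / MIPI-bm
shift the MIPI category by +1 (high), −1 (low) or 0 (intermediate),
capped at 1 and 3.

## Survival analysis

Kaplan–Meier curves, the k-sample log-rank test and Cox
proportional-hazards fits are delegated to lifelines behind the module
interface; the median is the smallest time with S(t) ≤ 0.5 (undefined if
never reached), p-values are two-sided, and no multiplicity correction
is applied. Cox models use group indicators against a reference level
with Wald intervals; ties are handled by Efron's approximation (the
library standard — simulated event times are continuous, so this choice
is immaterial here). Fits that fail to converge, diverge, or see zero
events raise instead of returning estimates.

ROC cut-offs maximize Youden's J over midpoints between adjacent sorted
unique values ("value > cutoff" is positive); ties in J break toward the
higher sensitivity. The AUC is the Mann–Whitney rank statistic with ties
counted half.

## Association and MLP prediction

Pearson and tie-corrected Kendall tau-b correlations, univariate
logistic regression (Newton MLE, Wald CIs — matching conventional
statistics-package output), and forward selection by likelihood-ratio p
(entry at p ≤ 0.05, candidates restricted to univariately significant
features; singular candidate designs are skipped). Note that unadjusted
stepwise entry at p = 0.05 admits one spurious feature in roughly a
quarter of null candidate sets — inherent to the procedure, not a bug.

The MLP is a single hidden layer of tanh units (default width 4,
minimum 3) with a softmax-equivalent logistic output, trained by
back-propagation (Adam, initial learning rate 0.01, ≤2000 epochs) with
early stopping on a 10% inner slice of the training split. Each of the
five repetitions draws a fresh outcome-stratified 70/30 train/validation
split (stratification avoids empty-class validation sets at n ≈ 100)
and a fresh weight initialization; inputs are standardized on the
training split only. Reported metrics: validation AUC (rank statistic)
and train/validation accuracy at probability 0.5, summarized as median
and range over repetitions. The default learning rate is raised above
the library default because at these sample sizes the optimizer
otherwise reaches the early-stopping patience before leaving its
initialization.

## Synthetic cohorts

The generator defines the study conditions for all simulation-based
tests.

**Volumes.** Grid 48 × 48 × 32 voxels at 5.5 × 5.5 × 3.3 mm; a smooth
background in SUV ≈ 0.5–1.5; 1–3 ellipsoidal lesions per patient with
semi-axes 8–20 mm (an error is raised if a lesion cannot fit the field
of view). Lesion interiors are Gaussian random fields — white noise
smoothed with a Gaussian kernel of the patient's correlation length,
restandardized — with the patient's target mean uptake and noise SD 1.0;
the per-lesion seed point is the hottest lesion voxel. `noise_sd = 0`
yields exactly constant lesions (downstream Entropy 0, ASM 1).

**Latent biology.** SUVmean_true ~ U(1, 7); a heterogeneity score
z ~ U(0, 1) maps reciprocally to the correlation length range (3–15 mm,
short = heterogeneous) and to Entropy_true = 2.5 + 1.9z + N(0, 0.1).
These ranges reproduce a realistic MCL cohort profile (mean SUVmean
≈ 3.8, mean Entropy ≈ 3.4 with roughly a quarter of patients above both
signature cut-offs).

**Outcome model.** Two-year progression probability
p₂ = expit(−7.20 + log(1.272)·SUVmean + log(5.070)·Entropy); the
intercept was calibrated once by simulation so the expected progression
fraction is 37.2% under the default covariate distributions. Event
times are exponential with rate λ = −log(1 − p₂)/24 ·
exp(hazard_log_hr · step), where step ∈ {0, 1, 2} is the true
metabolic-risk category: with `hazard_log_hr = 0`, P(T ≤ 24) = p₂
exactly, making the binary and time-to-event endpoints mutually
consistent; a nonzero `hazard_log_hr` imposes an exactly proportional
hazard between adjacent risk steps. When no logistic coefficients are
configured the rate is `baseline_hazard · exp(hazard_log_hr · step)`.
Censoring is independent exponential with its rate solved (Brent) so the
expected censored fraction equals `censor_rate` under the realized
hazard distribution. The two-year flag uses the uncensored event time
(complete two-year follow-up, as an inclusion-criterion-style
assumption).

**Clinical covariates.** Age ~ N(64.5, 10.8); ECOG categorical with 6.5%
≥ 2; WBC and LDH log-normal (≈30% LDH elevated at ULN 245 U/L); Ki-67 ~
100·Beta(1.5, 3); Ann Arbor stage and blastoid flags at cohort-typical
frequencies. Scanner batches follow the five-scanner 43/41/10/10/3
distribution by largest-remainder rounding with random placement; batch
effects are linear per-feature distortions x → scale·x + shift applied
at the *feature* level — where ComBat operates — not by simulating
scanner physics.

**Feature-level mode.** Large simulated cohorts skip imaging: a
measured-feature table is drawn directly from the latent biology plus
extraction noise, with the full extraction column schema. Its joint
distribution is a parametric sketch; image-path runs produce the same
schema from actual segmentation and extraction. Entropy in feature-level
mode lives on the cut-off scale (≈2.4–4.5), while image-path Entropy
lives on the G=64 binning scale — the two modes are not mixed within a
run.

**Reproducibility.** All draws come from substreams
`default_rng([seed, patient_index, stream])` of one master seed, so any
patient's volume can be regenerated in isolation and cohorts are
bit-identical across runs; the pipeline manifest records SHA-256 hashes
of every artifact to verify it.

## What the synthetic tests do and do not show

Passing tests demonstrate that each algorithm implements its definition
(oracle equivalence), that parameters injected into the generator are
recovered at the stated tolerances, and that the full pipeline detects a
built-in metabolic-risk effect with high power while staying calibrated
under the null. They do not validate the clinical effect sizes
themselves: the generator's distributions are simplified (no PET noise
texture or reconstruction artefacts, no respiratory motion, uncorrelated
covariates, exponential times), so cohort-level numbers produced here
characterize the *method*, not MCL biology.

## Problem sizes

Default problem sizes were chosen to give stable Monte-Carlo estimates
at desk scale: oracle comparisons on 100 random ≤8³ volumes; ComBat
recovery at n = 200/batch; logistic recovery at n = 5000 with 200
coverage replicates; Cox bias over 200 replicates of n = 1000 per true
hazard ratio; end-to-end power over 25 cohorts of n = 500 (100 cohorts
for the null arm, whose ~5% rejection rate needs a smaller standard
error relative to the 10% bound).
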