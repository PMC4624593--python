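# Methods

## Problem and model

`clinomics` identifies genes, micro-RNAs, and proteins whose molecular
profiles associate with a clinical phenotype in a multi-platform tumor
cohort. The statistical core is a penalized multiple linear regression of an
integer-encoded clinical outcome y on the integrated space of molecular
features:

    minimize over (b0, b):
        (1/2n) * sum_j (y_j - b0 - x_j' b)^2
        + lam * ( alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 )

The L1 term enforces sparsity (most features get exactly zero weight), the L2
term stabilizes the solution under the strong inter-feature correlation
typical of multi-omics data (copy number, expression, and methylation of the
same gene are far from independent). This is deliberately a *linear* model
even for ordinal and binary outcomes: the outcome encoding (stage I-IV to
1-4, binary to 0/1, categorical one-vs-rest to 0/1) turns every clinical
parameter into a numeric response, and candidate discovery only uses the
fitted coefficients for ranking, never for calibrated prediction.

## Pipeline stages

1. **Clinical consolidation.** Clinical tables from multiple sources are
   merged by union of records; any pairwise disagreement between non-missing
   values for the same sample and parameter makes the merged value missing
   (NA) and is logged. The strictest rule (no majority vote) was chosen
   because an arbitration rule for 3+ sources cannot be validated without the
   original records; it is also the only rule that is order-independent and
   idempotent.
2. **Outcome encoding.** Ordinal parameters encode as consecutive integers
   starting at 1 in level-list order; binary parameters as 0/1 with the
   *first* metadata level mapping to 0 (the codomain is fixed by convention,
   the orientation is not — a metadata-driven order keeps runs reproducible,
   and flipping it only flips coefficient signs); categorical parameters are
   analysed one-vs-rest, the selected class encoding to 1. Samples without a
   value are excluded from that run, with the reason recorded.
3. **Preprocessing.** Gene symbols are updated against a static nomenclature
   snapshot (never a live service); mutation records collapse to a gene x
   sample indicator where any non-silent variant (classification outside
   Silent/Intron/3'UTR/5'UTR/IGR/RNA) counts; the two methylation array
   generations merge on common probes with the newer assay winning shared
   samples; samples are restricted to those measured on every platform of
   the analysis group; features missing in >= 3% of samples are dropped
   (the threshold is configurable; the boundary is inclusive) and remaining
   gaps are median-imputed; each feature is rescaled as
   `g_hat = g / (sd(g) + sd_10)` where `sd_10` is the platform's 10th
   percentile of feature standard deviations — the additive offset keeps
   near-constant features from exploding into outliers. Methylation stays at
   probe level (probes carry a probe-to-gene annotation used only for entity
   tagging), so one gene may contribute several methylation rows.
4. **Integration.** Platform blocks are row-concatenated with
   (entity, platform, feature) row tags. The gene-oriented group is
   restricted to a vetted cancer-gene target list to favour driver signal
   over passenger noise; miR and protein groups keep all features because
   those panels are already pre-selected by the assays. Each block is then
   multiplied by one scalar setting its mean per-feature standard deviation
   to 1. The platform-scale statistic is a genuinely open design point; a
   single recorded scalar per block was chosen because it equalizes platform
   influence without reweighting features within a platform, and it is
   exactly invertible.
5. **Penalty selection.** 10-fold cross-validation with a seeded random
   partition; the penalty grid is 100 log-spaced values from `lambda_max`
   (the smallest all-zero penalty, computed from the stationarity conditions)
   down to `1e-3 * lambda_max`; ties on the CV curve keep the largest
   penalty. The mixing weight defaults to `alpha = 0.5` and is configurable;
   association sparsity is a modelling choice, not an estimate.
6. **Scoring and bootstrap aggregation.** Within a fit, the m selected
   features are ranked by |coefficient| (ties broken lexicographically by
   tag) and scored linearly, `(m - r + 1)/m`; an inverse-rank alternative
   (`1/r`) is available behind a switch. An entity's score sums its features'
   scores across platforms. The cohort is resampled with replacement B times
   (up to 2,000; the bundled studies use 100), the CV-penalized fit is
   recomputed per resample, and entities are ranked by mean score with
   absent-as-zero, reporting selection frequency (fraction of resamples with
   a positive score) and score variance. Both the full-data fit's scores and
   the bootstrap aggregate are exposed, since either is a defensible final
   ranking; the bootstrap table is the default because it carries the
   stability information.
7. **Post-hoc testing.** The outcome is dichotomized (ordinal: encoded
   levels 1-2 versus 3 and above; binary: 0 versus 1; custom partitions
   accepted). Each candidate is tested per platform: Fisher's exact
   (two-sided, hypergeometric tail summation with relative tolerance 1e-7)
   for mutation and copy number — for copy number, "altered" means amplified
   (call > 0) when the candidate's association is direct and deleted
   (call < 0) when inverse — and the two-sided Mann-Whitney-Wilcoxon test
   for continuous platforms (exact null when both groups have <= 8
   observations and no ties — the enumeration bound keeps the exact branch
   cheap — otherwise the tie- and continuity-corrected normal
   approximation). Raw P-values are Bonferroni-multiplied by the number of
   *candidates* in the analysis (not candidate x platform tests) and capped
   at 1; retention requires corrected P below 0.01. All tests are two-sided
   because the null is "no difference", directionless. By default every
   candidate is tested on every platform that measures it; a flag restricts
   testing to the platforms that supported the candidate in the ranking.

## Solver

The elastic net is solved by cyclic coordinate descent with soft
thresholding, an explicit intercept, and warm starts along the decreasing
penalty path. Convergence requires the largest per-sweep coefficient change
(intercept included) to fall below 1e-7; full sweeps alternate with
active-set sweeps, and convergence is only declared after a full sweep.
Features are not standardized inside the solver — all scaling is owned by the
preprocessing stage, so coefficients refer to the normalized feature values.
The penalized objective is recorded after every sweep and is non-increasing
by construction (asserted in the test suite). For near-ridge mixes the
`lambda_max` formula floors alpha at 1e-3 so a finite path exists. Penalty
paths inside *bootstrap resamples* stop at `1e-2 * lambda_max` rather than
1e-3: a with-replacement resample contains about 63% distinct samples, an
effectively under-determined regime in which the weakly-penalized tail is
both numerically slow and statistically meaningless; the shorter path is the
standard convention for that regime. Full-data fits keep the 1e-3 tail.

Numerical conventions fixed throughout: sample standard deviations use the
n-1 denominator; percentiles and quartiles use linear interpolation between
order statistics; the CV fold partition, bootstrap resampling, and every
synthetic draw run from one seeded `numpy` Generator stream per operation.
`bootstrap_rank` first puts samples and features into canonical (sorted)
order, so the ranking is invariant to the order the data arrived in.

Degenerate inputs: a constant outcome yields the all-zero solution with the
intercept at the constant; an all-constant matrix is rejected at
normalization (zero denominator); empty dichotomization groups, empty sample
intersections, and an empty methylation probe intersection are errors, not
silent empties.

## Synthetic cohorts

The generator emulates the structure the model assumes: a latent continuous
severity score `y = sum_k beta_k z_k + eps`, `eps ~ N(0, noise_sd^2)`, over a
sparse set of planted features, observed only through discretized clinical
labels. Continuous platforms draw Gaussian features with per-feature scales
log-uniform on [0.5, 20] (wide enough that the sd-based normalization has
observable effect); copy number draws GISTIC calls {-2..2} with probabilities
(0.05, 0.2, 0.5, 0.2, 0.05); mutations are Bernoulli with per-gene rates
uniform on [0.02, 0.3]. `z_k` is the planted feature's *standardized* value:
with heterogeneous scales, raw-value effects would make planted signal
strength an artifact of the drawn scale, whereas standardized effects give
every planted feature the same nominal strength regardless of platform.
Clinical labels are cut from y with balanced quantile cuts (ordinal and
categorical) or a median split (binary), so level frequencies differ from
equal proportions by at most one sample. Degradation injects cell-level
missingness (never on planted features, keeping the truth record fully
observed), per-platform sample dropout, and contradictory duplicate clinical
records emitted as a second source.

What the generator does *not* emulate — and hence what passing tests do not
establish about real cohorts: mutational signatures, segmental copy-number
correlation along the genome, realistic expression covariance, batch
effects, survival outcomes, or informative missingness. Recovery results on
these cohorts demonstrate the pipeline's correctness under its own model
assumptions, not field performance.

## Bundled study sizes

The recovery study uses 400 samples, 300 features over three platforms
(RNASEQ 150 / CNV 100 / MUT 50), 10 planted unit effects, unit noise,
`alpha = 0.5`, and B = 100 bootstrap resamples; the null-control study runs
20 seeded replicates of the same dimensions with nothing planted, fitting by
CV and testing the full-data candidates post-hoc. These sizes keep a full
run on a single CPU in minutes while leaving the planted/unplanted margin
wide (planted selection frequencies reach 1.0 against an unplanted 95th
percentile around 0.8).

## Known limitations

- Candidate counts depend on the CV-selected penalty, which is noisy on flat
  CV curves; the bootstrap selection frequency is the stabler signal.
- The linear model treats ordinal level gaps as equal; a proportional-odds
  model would be the principled alternative but would not feed the
  rank-scoring machinery.
- Bonferroni across candidates is conservative when platforms are correlated.
- The one-scalar-per-block platform normalization is one of several
  defensible conventions; the recorded factors make any alternative
  recoverable.
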