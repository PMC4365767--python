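# Methods

This note documents the statistical model behind each pipeline stage, the
design decisions taken where several defensible choices existed, what the
synthetic-array generator does and does not emulate, and the numerical
conventions that affect results.

## Signal model and QC

Each marker yields methylated (M) and unmethylated (U) fluorescence
intensities; Type I probes read both signals in one colour channel (red or
green by design), Type II probes read M in green and U in red. The
methylation fraction is `beta = M / (M + U + offset)` with the customary
offset of 100 intensity units, which stabilises dim probes and bounds beta
strictly below 1. The offset is configurable.

**Background correction.** Per sample and colour channel, the background
level is a low quantile (default the 5th percentile, configurable) of the
negative-control intensities; every intensity becomes
`max(I − b, 1)`. The floor of 1 keeps intensities positive and downstream
logs finite.

**Detection P values.** The background distribution per sample and channel
is summarised by the median and the normal-consistent MAD (×1.4826) of the
negative controls. A probe's total signal M + U is tested against the upper
tail of a Normal whose mean and spread are summed over the channels the
probe reads (both channels for Type II; twice the design channel for
Type I). Spreads are added, not root-square-summed — the convention of the
standard array-processing tool — and both the estimator and the combination
rule are parameter-isolated. The tail is evaluated as the double-precision
complement `1 − Φ(z)`, which cannot represent values below machine epsilon
(2.22e-16): the reported matrix is floored there so that log-scale
diagnostics never hit zero, while masking compares the raw complement
(which underflows to exactly 0 for saturating probes) against the
threshold. This preserves the semantics of the stringent threshold
P < 1e-16, which lies *below* the representable floor: only probes whose
tail underflows pass it.

**Call rates, sex check, outliers.** Sample call rate = fraction of
non-missing markers; samples below 98% (strict inequality) are excluded.
In the pipeline the headline call-rate filter is computed on autosomal
markers, because female samples are structurally missing on Y and would
otherwise be penalised for biology rather than quality; the sex-chromosome
streams apply their own call-rate filters. The sex check compares recorded
sex with the Y-marker call rate (mismatch if a female exceeds 0.5 or a male
falls below 0.5; both cutoffs configurable — the midpoint was chosen in the
absence of a sharper convention). Outlier rates use Tukey fences
(Q1 − 1.5 IQR, Q3 + 1.5 IQR) with linearly interpolated ("type 7")
quartiles; the convention matters and is therefore stated.

## Quantile normalisation

QN-I6 stratifies intensities into six pools — Type I M red, Type I U red,
Type I M green, Type I U green, Type II green (M), Type II red (U) — and
quantile-normalises each pool across samples. The reference distribution is
the mean of per-sample empirical quantile functions on a common grid of
length n_markers; complete samples are replaced rank-for-rank, samples with
missing values use interpolated fractional ranks, and tied values receive
the mean of the reference values over their rank span (computed exactly by
averaging within tie groups, which makes the operation deterministic and
idempotent). Missing entries stay missing. Any per-sample monotone
distortion of a pool's intensities — channel gains, scanner-response
nonlinearity — is removed exactly; marker-specific batch shifts are not,
which is precisely the gap Control Probe Adjustment fills. Autosomes and
sex chromosomes are normalised in separate runs with separate pools.

## Control Probe Adjustment

One feature per (non-negative control probe, colour channel); zero-variance
features are dropped with a log entry. Features are centred and scaled to
unit variance (control categories span very different intensity magnitudes;
scaling is a flag, correlation-PCA being the default since the covariance
alternative lets bright categories dominate), decomposed by SVD, with a
deterministic sign convention (largest-magnitude loading positive). The
leading k = 30 scores join every downstream design. No log-transform is
applied by default (exposed as an option). Thirty components is deliberate
overkill relative to the handful of true technical factors; the cost is a
mild loss of degrees of freedom, the benefit is robustness to how many
factors a given dataset actually has.

## Cell composition

Houseman-style constrained projection: per sample, minimise
`||y − B₀ w||²` subject to `w ≥ 0`, where y are the sample's betas at the
reference markers present on the array (absent reference markers are
dropped with a logged count; markers missing in a sample are dropped for
that sample) and B₀ is the cell-type reference. No sum-to-one constraint is
imposed: the measured total white-cell count enters the regressions as its
own covariate, so the projection need only capture relative composition.
The solver is non-negative least squares (active-set); rank deficiency of
the intersected reference falls back to a pseudo-inverse with clipping, and
a warning.

## Adjustment, residual PCA and association

Per-marker OLS of beta on the covariate design (intercept, age, sex
indicator, six estimated cell fractions, measured total count, 30 control
PCs) yields residuals with the original missingness; markers sharing a
missingness pattern are solved in one least-squares call, which is
algebraically identical to marker-wise fits. Constant covariates (e.g. sex
inside a single-sex stream) are dropped automatically. Residual PCA runs on
complete markers only, on the covariance (residuals are already centred and
share a scale); PCs 1–5 join the design.

The direct association model is a per-marker logistic regression of the
phenotype on beta plus the full covariate set, Wald test on the beta
coefficient, fitted by Newton–Raphson with a warm start at the
covariates-only solution. Non-convergence (including separation, which
manifests as divergence or a singular Hessian) flags the marker and reports
a missing P rather than aborting.

**Two-stage shortcut.** Regressing the phenotype on each marker's
covariate-adjusted residual alone collapses the per-marker model to two
parameters, which vectorises across all markers (closed-form 2×2 Newton
steps). With the covariates-only linear predictor carried as an offset,
the shortcut reproduces the direct model essentially exactly
(R² ≈ 0.999996 on 2,000 markers at n = 500) because the residuals are
orthogonal to the design. Two variants are exposed deliberately:

* *with offset* — matches the direct model, including its finite-sample
  Wald behaviour; used when the question is "what would the full model
  report?" (e.g. the shortcut-validation study);
* *without offset* (default in `permutation_null`) — under label
  permutation the intercept + residual model is exactly calibrated, whereas
  the direct model carries a genuine small-sample Wald inflation of order
  q/n (≈5–10% when 40 covariates meet 500 samples; negligible at
  population scale). Null calibration studies therefore use the pure form.

**Inflation and permutation null.** λ = median(χ²₁ quantile at 1 − p) /
0.45494. Phenotype labels are permuted jointly across markers (preserving
inter-marker correlation); each permutation records λ and the sorted
−log10 p vector, from which per-rank 2.5%/97.5% envelopes are formed. The
independence-restoring check permutes each marker's values independently
across samples (missingness travels with values), destroying inter-marker
correlation while preserving marginals exactly. The epigenome-wide
significance threshold is Bonferroni α/n rounded down to a power of ten
(0.05/470,000 → 1e-7).

**Replicate regression.** Duplicate pairs are compared by regressing the
0/1 replicate label on beta with pair fixed effects (the paired form:
the marker coefficient is identified from within-pair differences and the
residual variance reflects technical noise only), optionally with 30
control-PC covariates; Wald t tests use the full-model degrees of freedom,
which are few (n − n_pairs − 31) by construction of the design.

## Synthetic-array generator

The generator is the package's test bed and defines the conditions under
which the pipeline's properties are demonstrated. Per sample, cell
proportions follow a Dirichlet with blood-like means (granulocytes ~60%)
and concentration 15, giving realistic between-person spread; marker-level
base betas are bimodal (modes near 0 and 1); a fraction of markers
(default 30%) carries per-cell-type logit offsets, and the 500 reference
markers are strongly discriminative (between-cell-type range ≥ 0.3). True
betas add age and sex effects on small marker subsets, distance-decaying
within-cluster noise (logit SD 0.2, correlation exp(−d/400 bp)) emulating
the local correlation of CpG neighbourhoods, and independent logit noise
(SD 0.15).

The technical layer is where the pipeline's targets live, and it has three
deliberately distinct components per chip (12 samples round-robin):

* **channel gains** — a shared log-brightness factor (SD `batch_sd`, default
  0.3) plus channel-specific dye factors (half that SD); multiplicative,
  hence removed exactly by intensity-space QN;
* **scanner response** — a per-channel power-law exponent perturbation
  (SD (4/15)·batch_sd); monotone per channel (QN-removable) but
  channel-asymmetric, so it distorts betas marker-specifically and
  measurably degrades duplicate concordance — giving QN something real
  to fix;
* **chemistry factors** — five independent per-chip factors (SD
  (2/3)·batch_sd) with marker-specific loadings on the logit scale,
  mirrored multiplicatively in the control probes (each control category
  loads mainly on one factor). These survive QN and are what Control
  Probe Adjustment removes. Five factors rather than one keeps the
  realised batch contrast of a small duplicate experiment from being a
  single scalar draw, which would make its inflation factor wildly
  seed-dependent.

Independent multiplicative measurement noise (log SD 0.08) on each M and U
signal is the non-batch technical layer; it is redrawn for technical
replicates, while true betas (biology) are shared. Female samples emit only
background signal at Y markers, so detection-P masking reproduces the
sex-check contrast. Negative controls are background draws; total
intensities are LogNormal around 3,000 against a background around 100,
placing detection failures in the realistic sub-percent range.

What the generator does **not** emulate: real 450K manifest content, probe
sequences, SNP-overlap artefacts, cross-hybridisation (flags are assigned
at random 1% rates), X-inactivation dosage structure, and spatial
within-chip position effects. Passing tests therefore demonstrate the
pipeline's statistical behaviour under the assumed noise structure, not
performance on any particular real dataset.

## Study protocols and problem sizes

The calibration and validation studies run at desk scale, chosen to keep
each study inside a few minutes while staying in the statistical regime the
method was designed for:

* permutation-null studies: 500 samples × 2,000 markers × 200 label
  permutations; the median per-permutation λ is the reported quantity.
* duplicate study: 36 pairs (three chips per batch side), 4,000 markers;
  the reported control-PC-adjusted λ is the mean over nine independent
  simulation rounds, because the per-round value inherits the variance of
  the ~6 chip-level batch draws (SD ≈ 0.045) and a single round would be
  dominated by that draw. A no-batch control run shows the adjusted λ sits
  within a few hundredths of 1, the residue decomposing into mild
  overfitting deflation (30 PCs against 5 residual df) and incomplete
  removal of the logit-scale chemistry nonlinearity.
* spike staircase: 400 samples × 4,000 markers, 20 markers spiked at
  0.3 SD (half on M, half on U), scored by the fraction of spiked markers
  in the top 20, averaged over 10 seeds. The spiked fraction (0.5%) is
  kept small because residual PCs will learn a spike that occupies several
  percent of the array and adjust it away — an overcorrection regime the
  population-scale original (100 of 470,000 markers) never enters. At
  fewer than ~400 samples, chance correlations between the phenotype
  permutation and the ~800 cluster factors rival a 0.3 SD spike and crowd
  the top-k list; the study size keeps clear of that small-n artefact.
* local correlation: 300 samples × 3,000 markers in 4 kb clusters, pairs
  up to 5 kb, the 25% most variable markers (the default 5% of a desk-scale
  array leaves too few pairs for the distance regression), sliding 300 bp
  mean; the adjustment effect is the slope of per-pair Δr on distance.

## Numerical conventions

* Quartiles: linear interpolation (type 7). MAD scaled by 1.4826.
* λ denominator: χ²₁ median 0.4549364231.
* PCA sign: largest-|loading| positive. NNLS tolerance: solver default
  (well below 1e-8); weights asserted nonnegative to 1e-8.
* Logistic Newton: tolerance 1e-9 (direct) / 1e-8 (vectorised), iteration
  caps 50/40, linear predictors clipped at ±30 for overflow safety.
* Ranking ties in spike scoring: ascending p, then descending |coef|,
  then marker id — fully deterministic.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; rerunning any stage with the same inputs is
  bit-identical.

## Known limitations

* The chemistry batch effect acts linearly on the logit scale, but the
  control-PC adjustment is linear on the beta scale; with very few chips
  the unremoved curvature leaves replicate-regression λ a few hundredths
  above 1. This mirrors the real-data situation, where control probes are
  proxies rather than exact measurements of the bias.
* Detection P assumes a Normal background; heavy-tailed negative controls
  would make the stringent threshold slightly conservative.
* The permutation envelope is pointwise (per rank), not a simultaneous
  band.
* Sex-chromosome streams run with the autosomal machinery on marker
  subsets; dosage-specific models (e.g. X-inactivation mixtures) are out
  of scope.
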