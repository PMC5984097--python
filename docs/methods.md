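# Methods

This note records the models implemented in `brainpad`, the calibration
choices behind the synthetic-cohort generator, and what the tests do and do
not establish about real data.

## Age model

**Kernel.** Features are the concatenated grey- then white-matter voxel
vectors. The similarity matrix is the Gram matrix of dot products divided
by the feature count (`scale_by_dim=True`), which keeps the hyperparameters
comparable across voxel resolutions. Feature columns are centred at the
training means by default (`center_features=True`): phantom (and real)
tissue maps share a large common template, and without centring that
template dominates the kernel as a rank-one component and degrades
conditioning. Both choices are estimator parameters, since conventions here
vary between implementations.

**Likelihood and optimization.** Ages are mean-centred; the covariance is
`σ_f² K + σ_n² I`. `K` is eigendecomposed once, so each marginal-likelihood
evaluation and its analytic gradient are O(n). Optimization is L-BFGS-B on
`(log σ_f², log σ_n²)` with two documented starts — `σ_f²` matched to
`var(y)` on the kernel scale, `σ_n² ∈ {0.1, 1}·var(y)` — and generous box
bounds; a floor of `1e-8·var(y)` keeps `σ_n²` positive. Negative kernel
eigenvalues within `1e-6·trace(K)/n` are treated as round-off and clipped;
anything larger raises a numerical error rather than being silently
repaired. Zero-variance targets short-circuit to a constant predictor.

**Prediction.** `σ_f² K_* α + ȳ`, with `α` solving
`(σ_f² K + σ_n² I) α = y − ȳ`. No refitting and no age-bias correction is
applied to test cohorts. Consequently predictions shrink toward the
training mean by roughly `var(signal)/(var(signal)+error²) ≈ 0.89`: in a
test cohort ~36 years older than the training mean this shows up as a
systematic ≈ −4 y offset in mean test-cohort brain-PAD. This is the
expected behaviour of an uncorrected brain-age model and is deliberately
left uncorrected; analyses that depend on the *spread* of brain-PAD
(survival, fitness associations) are unaffected by a constant offset.

**Cross-validation.** Ten folds by default, seeded, stratified by age
decile (stratification stabilises fold metrics in age-diverse samples
without biasing them); each fold is predicted by a model whose
hyperparameters are re-optimized on the remaining folds, and metrics are
pooled over held-out predictions rather than averaged over folds. `R²` is
reported as the squared Pearson correlation. The permutation test reshuffles
age labels only and reports `(1 + #{permuted ≥ observed})/(n_perm + 1)`.

## Synthetic cohorts

The generator defines ground truth for every downstream estimator; all
draws descend from `SeedSequence` children of one seed, so identical
configurations give identical cohorts.

**Training ages.** The configured mean/sd/range (36.95, 18.12, [18, 90])
are treated as *observed* moments of the bounded sample. No truncated
normal on [18, 90] attains sd 18.12 at mean 36.95 (its maximum there is
≈17.5), so ages are drawn from a moment-matched Beta on the range —
Beta(0.54, 1.52) scaled to [18, 90] — whose young-adult-heavy shape is
typical of pooled public MRI repositories. Degenerate sd 0 yields constant
ages; infeasible (mean, sd, range) combinations raise a configuration
error.

**Phantom maps.** Each subject's maps are
`template + brain_age × loading + noise`, clipped at zero, with the
template and the signed loading pattern fixed per seed (the loading is
rescaled to exactly `loading_norm`, default 1 map-unit/year). Latent brain
age is `age + δ`, with `δ ~ N(0, 5 y)` in the healthy training sample. The
pair (δ sd = 5, total prediction error 6.31) is a joint calibration: the
reported error triplet is internally Gaussian-consistent
(5.02/6.31 ≈ √(2/π), 0.94² ≈ 0.88), and the voxel-noise default solves

    train_pad_sd² + m²·(1 + p/n_train) = prediction_noise_sd²,
    voxel_noise_sd = m · loading_norm,

where `m` is the error of the oracle decoder (projection on the loading)
and the `(1 + p/n)` factor accounts, to leading order, for having to learn
the decoding direction from n training maps with p voxels. Default voxel
counts are 500 GM + 500 WM — large enough for the high-dimensional regime
to matter, small enough for desk-scale runs — and configurable upward.

**Test cohort.** Ages `N(72.67, 0.73)`; δ per sex from
`N(4.29, 8.58)` / `N(−1.29, 7.87)`, independent of age. The phenotype
table's `brain_pad` column carries δ (the latent, "measured-by-construction"
brain-PAD) until an imaging pipeline overwrites it with model predictions.
GM and CSF volumes are linear in δ with opposite signs (−2.0 / +2.5 ml per
year) plus noise; WM volume is pure noise. DNAm age is
`age + N(−3.4, 6.1)`, telomere length per sex
(`N(3912.3, 711.7)` male, `N(4045.5, 711.7)` female, base pairs), both
independent of δ, matching the reported null cross-correlations between
ageing biomarkers. Morbidity flags (prevalences 26.9% CVD, 10.2% diabetes,
6.9% stroke, 49% hypertension), APOE-e4 (28%), smoking, childhood IQ,
social class and education are generated independently of δ, so the
null-association battery is null by construction.

**Fitness outcomes.** Each standardized outcome is
`β·z(δ) + γ·(male − p) + ε` with γ the raw male–female gap (taken from the
cohort descriptives: grip +1.49, FEV₁ +1.18, walk time −0.35, fluid-g
−0.05, allostatic +0.24 sd). The residual variance is chosen in closed form
so the *realized* outcome has unit variance, accounting for the covariance
between the sex term and the sex difference in δ. With this construction
the sex-adjusted standardized regression recovers β exactly in expectation
— the alternative of fixing the residual at `√(1−β²)` and adding the sex
effect on top would attenuate every recovered β by `1/sd(y)` and make the
generator inconsistent with its own recovery targets. The allostatic-load
outcome additionally spawns 11 raw components (fibrinogen, lipids, HbA1c,
CRP, IL-6, BMI, systolic blood pressure) correlated ρ=0.85 with the latent
outcome, signs set so the analyzer's composite (z-scores, HDL reversed,
mean, re-standardized) tracks it with r ≈ 0.98. Blood pressure enters as
systolic; the direction map is user-overridable. Fitness residuals are
drawn independently across outcomes — their mutual covariance is not part
of the design and none of the analyses depend on it.

**Survival.** Event times are exponential with rate `λ₀·exp(η)`, the
simplest baseline consistent with proportional hazards (Cox estimation is
baseline-agnostic). The default linear predictor is
`ln(1.061)·δ + ln(1.02)·(age−ā) + ln(1.8)·male`; the age and sex terms are
small enough not to dominate and configurable, and `hazard_terms` can
redirect the hazard onto any generated column (e.g. GM volume at
ln(0.991)/ml) for volumetric-recovery experiments. Censoring is
administrative, uniform on 5.4–7.9 y. `λ₀` is calibrated per cohort by
root-finding on the closed-form expected death count
`Σᵢ (1 − E_C[exp(−λ₀ e^{ηᵢ} C)])` against the target (73), so the expected
event count is exact given the realized covariates; the Monte-Carlo death
fraction matches this expectation within simulation error (tested).

## Survival estimation

Cox regression maximizes the Efron-tied (default; Breslow available) log
partial likelihood by Newton–Raphson with step-halving on internally
standardized covariates; convergence requires relative log-likelihood
change < 1e-9 and gradient norm < 1e-6. Standard errors come from the
inverse observed information; Wald CIs are reported on the HR scale.
Monotone likelihood (perfect separation) is detected after convergence —
diverging standardized coefficients or collapsing observed information —
and raised as an error rather than returning boundary estimates.
Proportional hazards are checked (reported, not enforced) via the Pearson
correlation of Grambsch–Therneau-scaled Schoenfeld residuals with event
time. The Kaplan–Meier estimator uses Greenwood variance; tertile curves
split at the empirical 33.3%/66.7% quantiles and drop the middle tertile by
default for a high-vs-low contrast.

Model comparison scores each Cox model's linear predictor against
deceased-by-ascertainment status with the Mann–Whitney AUC and compares
correlated AUCs by the DeLong method. Scoring a survival model with a
binary AUC ignores censoring-time information; it is the default because
ascertainment is near-complete administrative follow-up in this design, and
a cumulative/dynamic variant at a fixed horizon (cases: events before the
horizon; controls: followed beyond it; earlier-censored subjects dropped)
is available behind `method="cumulative_dynamic"`.

## Association suite

Standardized regressions z-score outcome and exposure in-sample (binary
covariates enter unstandardized) and report two-sided t-test p-values; the
FDR family is exactly the five fitness outcomes (Benjamini–Hochberg,
q=0.05), while morbidity/life-course tests are reported uncorrected. The
rank-sum statistic W is the rank-sum of the *first* group (the convention
matters when quoting W); the null distribution is exact — a subset-sum
dynamic programme over doubled midranks, so ties are handled without
enumeration — when both groups have ≤ 12 members, and a tie- and
continuity-corrected normal approximation otherwise. Two-sided exact p is
`min(1, 2·min(P(W≤w), P(W≥w)))`. Hierarchical variance partitioning is the
LMG decomposition (incremental R² averaged over all predictor orderings,
computed from all 2^k subset fits) and refuses k > 8 predictors; each
predictor's `joint` share is its marginal R² minus its independent share,
and independent shares sum to the full-model R² by construction.

## What the tests show — and don't

Passing tests establish that each estimator recovers the generator's ground
truth at the study's sample sizes and that the exact-arithmetic oracles
(dual ridge ≡ GP mean, brute-force partial likelihood, product-limit by
hand, BH step-up, rank-sum enumeration, pair-counting AUC, partitioning
identity) hold. The phantom is deliberately minimal: a single linear
spatial pattern with i.i.d. voxel noise. It contains no anatomy, no spatial
autocorrelation, no scanner or site effects, no registration error, and no
non-linear ageing; real-data accuracy will be worse and site-confounded in
ways these tests cannot reveal. Likewise the exponential baseline hazard
and administrative censoring are idealisations — adequate for testing a
baseline-agnostic estimator, not a claim about real mortality dynamics.
Quantities that depend on the shape of real data distributions (the printed
rank-sum W, the exact attenuation of the fully adjusted hazard ratio, the
absolute AUC levels of the biomarker models) are reproduced qualitatively,
not numerically.

## Problem sizes

Defaults used by the test suite and acceptance script: the full-scale
phantom pipeline runs once (n=2001, p=1000, 10-fold CV); hazard-ratio and
fitness-beta recovery use 200 replicate cohorts of n=669; sex-specific
brain-PAD, DNAm-PAD and the accuracy triplet use 50 replicates; the
biomarker-combination property uses 100 replicates. These sizes put every
Monte-Carlo standard error well below the tolerance being asserted while
keeping a full run in the minutes range on one core.
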