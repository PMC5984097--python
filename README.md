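# brainpad

Brain-predicted age as an ageing biomarker: a Gaussian-process age
regressor on voxelwise structural neuroimaging features, the
brain-predicted age difference (**brain-PAD**) it yields, and the survival
and fitness analyses that give that number epidemiological meaning.

The package is aimed at researchers in imaging epidemiology and biomarker
development who want a tested, reproducible implementation of this pipeline
— either to run on their own pre-segmented grey/white-matter maps and
phenotype tables, or to study the statistical behaviour of the design on
fully synthetic cohorts with known ground truth.

## The model

Each subject's normalised grey- and white-matter maps are concatenated into
a feature vector `x ∈ R^p`. Rather than regressing in voxel space, subjects
are projected into an `n × n` similarity matrix of dot products
`K_ij = x_i·x_j / p` (the linear kernel), and chronological age `y` is
modelled by Gaussian-process regression with covariance

    C = σ_f² K + σ_n² I,     y centred at ȳ.

Hyperparameters `(σ_f², σ_n²)` maximize the log marginal likelihood (a
single eigendecomposition of `K` makes each evaluation O(n)); the
predictive mean for a new subject is `σ_f² k_*ᵀ α + ȳ` with dual weights
`α = (σ_f² K + σ_n² I)⁻¹ (y − ȳ)` — identical to dual-form ridge
regression at `λ = σ_n²/σ_f²`. For one subject,

    brain-PAD = brain-predicted age − chronological age,

so positive values mean an "older-appearing" brain. Downstream, brain-PAD
enters Cox proportional-hazards models of all-cause mortality (Efron ties,
Newton–Raphson on the partial likelihood), Kaplan–Meier tertile curves,
sex-adjusted standardized regressions on fitness outcomes with
Benjamini–Hochberg FDR control, hierarchical variance partitioning against
conventional volumetric measures, and AUC comparison (DeLong) of nested
biomarker models combining brain-PAD with DNA-methylation-predicted age and
telomere length.

Because the cohorts behind the original analyses are access-controlled, the
package ships a seeded synthetic-cohort generator
(`brainpad.CohortGenerator`) that reproduces the study's statistical
structure: a training sample of n=2001 (observed age mean 36.95 y, sd
18.12 y, range 18–90), a narrow-age test cohort of n=669 (352 male / 317
female, age 72.67 ± 0.73 y) with sex-specific brain-PAD distributions
(+4.29 ± 8.58 y male, −1.29 ± 7.87 y female), five fitness outcomes with
configurable standardized effects, an exponential proportional-hazards
mortality process calibrated to ~73 expected deaths under uniform 5.4–7.9 y
administrative censoring, and molecular biomarkers generated independently
of brain-PAD.

## Worked example

```python
from brainpad import (CohortGenerator, GeneratorConfig, SimilarityGPRegressor,
                      kfold_cv, prediction_metrics, cox_fit)

gen = CohortGenerator(GeneratorConfig(seed=11))
train = gen.training_sample()           # 2001 subjects with phantom maps
X, age = train.features(), train.phenotypes["age"].to_numpy()

print(kfold_cv(X, age, k=10, seed=0))
# PredictionMetrics(pearson_r=0.9401, r_squared=0.8837, mae=4.82, rmse=6.03, n=2001)

model = SimilarityGPRegressor().fit(X, age)
test = gen.test_cohort(images=True)
pred = model.predict(test.features())
print(prediction_metrics(test.phenotypes["age"], pred))
# PredictionMetrics(pearson_r=0.071, r_squared=0.005, mae=6.86, rmse=8.66, n=669)

fit = cox_fit(test.phenotypes, ["brain_pad", "age", "male"])
print(fit.summary.loc["brain_pad", ["hr", "hr_ci_low", "hr_ci_high", "p"]])
```

Reading the numbers: ten-fold cross-validation on the age-diverse training
sample shows the model tracks chronological age closely (r≈0.94, i.e. ~88%
of age variance explained, mean absolute error ≈5 years). Applied to the
narrow-age older cohort the correlation with chronological age collapses by
design — everyone is ~73 — while the prediction spread (sd ≈8.7 y) is an
order of magnitude wider than the chronological spread (0.73 y): that
spread *is* the biomarker. The Cox row reports the mortality hazard ratio
per year of brain-PAD with its 95% CI (≈1.06 under the default generator,
i.e. a ~6% higher death rate per "older-looking" year of brain age).

A command-line pipeline wraps the same stages:

```bash
brainpad simulate --seed 1 --out run/
brainpad train    --cohort run/ --out run/
brainpad predict  --cohort run/ --model run/model --out run/
brainpad associate --cohort run/ --out run/
brainpad survive  --cohort run/ --out run/
brainpad report   --out run/
```

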