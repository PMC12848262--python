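# permquant

Quantifying intestinal hyperpermeability ("leaky gut") in cattle — or any
species with a known creatinine excretion rate — from **sequential spot
urine samples** after an oral dose of the indigestible, nonmetabolizable
marker Co-EDTA. Total urine collection, the gold standard for marker
recovery, is labor-intensive and risky; `permquant` implements the
spot-sample alternative: model the urinary Co:creatinine ratio over time,
integrate the fitted curve, and scale by the near-constant daily creatinine
output to recover total marker excretion. The package also provides the
downstream group statistics linking serum inflammatory markers
(haptoglobin, LBP, FABP2, TNF) to the quantified permeability, and a
synthetic-cohort generator so the whole pipeline is testable end to end
without animal data.

## The model

Post-dose Co:creatinine ratios follow a surge function

```
f(t) = A exp(−k₁ t) · exp(−B exp(−k₂ t))
```

with amplitude `A` (mg Co/mg creatinine), lag shape `B`, elimination rate
`k₁` (1/d) and onset rate `k₂` (1/d). All animals are fitted jointly as a
nonlinear mixed-effects model — individual parameters log-normal around
population values, `log θᵢ = μ + ηᵢ`, `ηᵢ ~ N(0, diag(ω²))`, proportional
residual error by default — estimated by SAEM (stochastic-approximation EM
with Metropolis-within-Gibbs sampling of the random effects). Model
adequacy is checked with normalized prediction distribution errors (npde):
Shapiro–Wilk normality, Wilcoxon signed-rank zero-location, and a
chi-square unit-variance test.

Each animal's total urinary Co (mg) is then

```
total Co = AUC[0, 1.5 d] × BW (kg) × 29 mg creatinine/kg/d
```

where the AUC of the empirical-Bayes curve is computed by the trapezoidal
rule (an incomplete-gamma closed form serves as the analytic oracle), and
dividing by the elemental Co dose (6.9 g per 50 g Co-EDTA) gives the dose
fraction recovered — the permeability index. Outcomes are analyzed by 2×2
factorial ANOVA (treatment × breed) and each serum marker by ANCOVA on Co
excretion with marginality-respecting backward elimination (drop the
highest-order term with the largest p > 0.05 until only significant terms
remain).

## Worked example

```bash
permquant simulate --seed 1 --out cohort        # synthetic 12-heifer study
permquant run --urine cohort/urine.csv --serum cohort/serum.csv \
              --seed 1 --out results
cat results/report.txt
```

```
permquant pipeline report
config digest: c7ea3ae88611   seed: 1
animals fitted: 12 (excluded: 0)   converged: True
population fixed effects: A=0.1169, B=3.865, k1=2.766, k2=14.2
npde adequacy p-values: shapiro=0.641 wilcoxon=0.418 variance=0.898
mean total urinary Co: 269.9 mg (3.91% of the 6900 mg Co dose)
ANCOVA hp_ug_ml: covariate eliminated
...
```

Reading the report: the population-typical curve peaks a few hours
post-dose (`k₂ ≫ k₁`) and has decayed to near zero by 36 h; all three npde
p-values are well above 0.05, so the fitted model is consistent with the
data; the cohort excreted on average ~270 mg Co, i.e. ~3.9% of the dose —
the expected few-percent urinary recovery for this marker. The per-animal
numbers are in `results/excretion.csv`, term-level ANOVA/ANCOVA tables in
`results/stats.json`, and `results/npde.csv` holds one decorrelated
residual per observation.

The same steps are available as library calls (`generate_cohort`,
`fit_population`, `compute_npde`, `cohort_excretion`, `factorial_anova`,
`ancova_stepwise`), and `anova_from_summary` re-analyzes published 2×2
tables from cell means and a pooled SEM alone.

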