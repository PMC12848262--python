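# Methods

## Excretion curve and units

The urinary Co:creatinine ratio after an oral Co-EDTA bolus is modelled as
`f(t) = A·exp(−k₁t)·exp(−B·exp(−k₂t))`: a mono-exponential elimination
(rate `k₁`) gated by a saturating onset term (lag shape `B`, onset rate
`k₂`). The curve is positive, bounded by `A`, and has a single interior
maximum at `t* = ln(Bk₂/k₁)/k₂` whenever `Bk₂ > k₁`; otherwise it decays
monotonically. Time is handled in **days** internally (the I/O layer
converts sampling times given in hours) so the AUC carries units
(mg Co/mg creatinine)·day, which is what the creatinine-scaling formula
expects.

Substituting `u = B·exp(−k₂t)` gives the exact integral

```
∫₀ᵀ f dt = A/(k₂ B^(k₁/k₂)) · [γ(k₁/k₂, B) − γ(k₁/k₂, B e^(−k₂T))]
```

with `γ` the lower incomplete gamma function; `B = 0` reduces to the
elementary exponential integral and bypasses the `B^(k₁/k₂)` division.
Excretion scaling uses the trapezoidal estimator (default 10,001 uniform
points — discretization error ~1e−8 relative, far below any downstream
statistic); the closed form is kept as the independent oracle and for the
`t_end = ∞` option. The default integration window is [0, 1.5 d], the 36 h
sampling span: a few-percent dose recovery over that window matches the
historical total-collection results for this marker, and the infinite
window remains available where the tail matters.

## Population model and SAEM

Individual log-parameters are normal around population means with diagonal
covariance, `log θᵢ = μ + ηᵢ`, `ηᵢ ~ N(0, diag(ω²))` — the minimal
structure guaranteeing positive parameters; correlated random effects are
out of scope. The residual error model is proportional by default
(ratio data span two orders of magnitude over 36 h), with additive and
combined (`sd² = a² + (b·f)²`) selectable. The pre-dose t = 0 sample is
excluded from the likelihood by default: the model predicts
`A·exp(−B) > 0` at t = 0 while the true pre-dose marker level is zero, so
that sample establishes background rather than kinetics (`include_t0`
reverses this).

Estimation is SAEM:

- **Initialization** (deterministic): a pooled coarse grid over
  (B, k₁, k₂) with the amplitude profiled out analytically
  (`A = Σyg/Σg²`), then a per-animal log-scale least-squares refinement;
  ω² starts at 0.1, σ from pooled residuals.
- **E-step**: per iteration, 3 kernel sweeps of Metropolis-within-Gibbs —
  one independence proposal from the current population prior plus
  componentwise random walks whose scales adapt toward 40% acceptance
  during exploration and freeze afterwards.
- **SA/M-step**: sufficient statistics are smoothed with step 1 for 300
  exploratory iterations and 1/m for 100 smoothing iterations; μ, ω², σ
  update in closed form (the combined error parameters by a short
  Nelder-Mead inner step). During exploration ω² and σ may shrink at most
  5% per iteration; without this annealing, weakly informed components
  (B, k₂, whose information sits in only the three earliest samples) can
  collapse to zero variance and pin the chain.
- **Empirical Bayes**: per-animal posterior modes by Nelder-Mead from two
  starts (smoothed mean and final chain state).

Every Monte-Carlo draw for an animal comes from a stream keyed by its
`animal_id`, so results are reproducible for a given seed and insensitive
to cohort ordering (up to floating-point summation order). Convergence is
declared when the mean relative parameter change over the last half of the
smoothing phase falls below `tol = 1e−3`; that threshold sits well above
the ~5e−4 intrinsic Monte-Carlo scale of the statistic at the default
schedule but below the ~1e−2 scale of a drifting fit, cleanly separating
the two. Non-convergence is flagged, never silent.

With all random-effect variances truly zero the model degenerates to
pooled nonlinear regression; the suite checks that the SAEM optimum then
matches a direct least-squares fit (residual sum of squares within 10%,
σ̂ = √(RSS/N)).

## npde

Model adequacy uses normalized prediction distribution errors: `n_sim`
replicate datasets (default 1000) are simulated from the fitted model at
the observed design; per animal, observed and simulated vectors are
decorrelated with the inverse Cholesky factor of the empirical simulated
covariance; the rank of each decorrelated observation among its simulated
counterparts is mapped to a normal score via `(k + ½)/(n_sim + 1)`. The
pooled npde are tested for normality (Shapiro–Wilk), zero location
(Wilcoxon signed-rank) and unit variance (two-sided chi-square on
(n−1)s², the Fisher-style variance test). For the proportional error
model the decorrelation is done on the **log scale**: the shared lognormal
random effects induce a nonlinear within-animal dependence that a linear
decorrelation cannot remove on the natural scale (simulation showed the
variance test rejecting ~12% under a correct model), whereas on the log
scale the dependence is nearly additive and all three tests hold their
nominal level (measured 4–6% over 200 well-specified replicates). A
numerically singular simulated covariance triggers a marginal-standardization
fallback with a logged warning.

## Excretion quantification

`total Co (mg) = AUC × BW (kg) × creatinine rate`, with the creatinine
rate defaulting to 29 mg/kg BW/d (dairy-cattle value; configurable for
other populations), and
`dose fraction (%) = 100 × total Co / elemental Co dose` with the dose
defaulting to 6900 mg — the elemental Co content of a 50 g Co-EDTA dose
(0.138 g Co/g salt, treated as configuration data, not chemistry computed
here). The quantity is the total over the integration window; since
essentially all excretion happens within ~1.5 d, it is conventionally
quoted per day.

## Group statistics

Factorial ANOVA is an OLS fit of `response ~ A*B` with type II sums of
squares (identical to I/III in the balanced case), F-tested against the
residual mean square. `anova_from_summary` reconstructs the balanced 2×2
table from cell means and the pooled SEM of a cell mean alone, using
`MSE = n·SEM²`, `df_error = 4(n−1)` and the balanced SS formulas; it
round-trips exactly against the raw-data ANOVA and lets published summary
tables be re-analyzed.

ANCOVA starts from the full `A*B*covariate` model and removes terms
backward: among droppable terms (those not contained in a retained
higher-order term — marginality), the highest-order one with the largest
p > 0.05 goes first, one per step, until everything droppable is
significant. Two small-sample properties of this procedure at the 12-animal
design are worth knowing. First, since each interaction term is tested by
an exact 5%-level F test under its null, the probability that all four
interaction terms get eliminated is capped near 0.95⁴ ≈ 81% no matter how
strong the covariate effect is. Second, a spuriously significant
covariate-by-factor interaction locks the covariate into the final model
through marginality, so under a null covariate the *literal* retention
rate is ~20% even though the covariate survives on its own significance at
the nominal ~5% (these rates were verified by simulation, and the type II
tables verified against an independent R implementation). Users comparing
retention rates to a nominal α should count own-significance retention.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 2 breeds
(BW ~ N(362, 25²) and N(269, 21²) kg, truncated positive) × 2 aspirin
levels × 3 animals, spot samples at 0–36 h. Kinetic truth defaults —
A = 0.1220 mg/mg, B = 4, k₁ = 3/d, k₂ = 14/d, ω (SD) = 0.15/0.2/0.15/0.2,
proportional σ = 0.10 — were calibrated once through the closed-form AUC
so the typical curve peaks near 5 h, is near zero by 36 h, and mean dose
recovery is ≈3.6% at the design's mean body weight; these are stored as
named constants and not revisited. Serum markers are
`baseline + aspirin effect + breed effect (+ slope × true Co excretion for
TNF)` times log-normal noise whose CV combines a 12% assay component with
a per-marker biological component scaled to the magnitudes typical of
these assays. The t = 0 ratio is background noise (|N(0, 1e−4)| mg/mg).
Negative ratios are clipped at zero with a logged count (only the additive
error model produces them at realistic settings).

What the generator does **not** emulate: covariate effects on the kinetic
parameters (breed and treatment act only on markers, matching the
analysis), between-occasion variability, assay censoring/limits of
detection, non-constant creatinine excretion, and any aspirin
pharmacology. Passing recovery tests therefore demonstrate that the
estimator recovers the truth *under the model's own assumptions* at the
study's size and noise level — they do not validate the kinetic model
against real cattle data.

## Problem sizes and numerical choices

Default SAEM runs (400 iterations, 12 animals) take well under a second;
the test suite's recovery study uses 20 seeded cohorts and the npde
calibration 200 replicates at `n_sim = 300`, chosen to give binomial
standard errors of ~1.5% on rejection rates while keeping the full suite
around a minute. The acceptance script's recovery study uses 10 cohorts
with `n_sim = 1000` for the npde on the first. Degenerate inputs are
handled explicitly: all-zero animals are excluded with a warning, B = 0
bypasses the incomplete-gamma branch, tied ANCOVA p-values break by term
order then magnitude, and ω² is floored at 1e−8 to keep the sampler
proper.
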