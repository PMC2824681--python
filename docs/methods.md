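# Methods

## Model

Each individual carries G biallelic SNP genotypes (coded 1/2/3 for the
reference homozygote, heterozygote and high-risk homozygote) and E
environmental exposure levels. Disease risk is a logistic function of the
exposures whose coefficients are selected by the genotype combination:

    R(g, x) = expit(alpha_g + sum_b beta_gb * x_b)

In the one-gene/one-environment case this reduces to three logistic curves,
one per genotype. The logit-linear form is the natural choice because the
slope of a logistic regression is the log odds ratio per unit of covariate —
which is exactly the epidemiological input the simulator accepts. Natural
logarithms throughout.

Assumptions: loci are sampled independently (no linkage disequilibrium),
environmental factors are mutually independent, and disease status is an
independent Bernoulli draw per individual given their risk. Exactly one
gene–environment pair is causal; all other factors are pure noise and never
enter the risk function.

## Parametrization

Inputs and their meaning (units in parentheses):

| parameter | meaning | default |
|---|---|---|
| N | sample size | required |
| m | overall disease frequency in (0,1) | required |
| model | GM / EM / GEM / AM / CUSTOM | required |
| RR31 | total-risk ratio aa : AA (>= 1) | 1 |
| W | inheritance weight in [0,1] | 0 |
| env OR | odds ratio per unit of causal exposure | 1 |
| P^G | genotype frequency triple per SNP | random allele freq in [0.1, 0.9], Hardy–Weinberg |
| P^E | exposure law per factor (normal / uniform / discrete) | standard normal |

The heterozygote relative risk is interpolated linearly on the relative-risk
scale, RR21 = 1 + W (RR31 − 1), the unique linear form with the recessive
(W=0 → RR21=1) and dominant (W=1 → RR21=RR31) endpoints; by construction
1 ≤ RR21 ≤ RR31. The conservation identity m = Σ P(i)·TR_i then fixes the
per-genotype total risks in closed form:

    TR_1 = m / (P_1 + P_2 RR21 + P_3 RR31),  TR_2 = RR21 TR_1,  TR_3 = RR31 TR_1.

If any TR_i ≥ 1 the inputs are jointly infeasible and the run aborts, naming
the offending quantity, before any sampling.

Coefficients per interaction model:

* **GM** — β = 0, α_i = logit(TR_i) in closed form.
* **EM** — requires RR31 = 1 (genetics must not alter risk) and OR ≠ 1;
  β = ln(OR) shared, one shared α root-solved so E_x[expit(α + βx)] = m.
* **AM** — β = ln(OR) shared, each α_i root-solved against its TR_i.
* **GEM** — the user's OR anchors the reference-genotype slope
  β₁ = ln(OR) (all risks are defined relative to genotype 1); the shared α is
  solved against TR_1, then β₂ and β₃ are solved one equation at a time.
  The system is solved sequentially rather than jointly because the equations
  triangularise exactly; the residuals are identical either way.

The expectation E_x[expit(α + βx)] is exact (a weighted sum) for discrete
exposures; for continuous ones it uses fixed 256-node Gauss–Legendre
quadrature — over [low, high] for the uniform, over mean ± 8 sd for the
normal (truncated tail mass ~1e-15) — with weights normalised to sum to one,
so a zero slope reproduces expit(α) exactly. Root finding is Brent's method
on the bracket [−50, 50] log-odds for intercepts ([−500, 500] for GEM
slopes); solutions are deterministic and verified to residual |TR − target|
< 1e-10, and the solved coefficients are re-validated against their
constraint pattern (equality tolerance 1e-9, dominated by the solver
tolerance).

Monotonicity of the total risk in β holds only when the exposure support is
nonnegative, so GEM accepts only environments whose numerical support starts
at 0 or above (uniform with low ≥ 0, discrete with min ≥ 0, normal with
mean − 8 sd ≥ 0); other specs are rejected with a suggestion to shift the
exposure scale. EM is rejected when RR31 ≠ 1 rather than silently ignoring
the genetic input.

## Sampling

One root seed expands into independent named streams (genotypes, exposures,
status) via `numpy` `SeedSequence.spawn`, so adding a factor of one kind never
perturbs draws of another. Genotypes are inverse-CDF categorical draws from
each SNP's frequency triple; exposures are i.i.d. draws from each factor's
law; status is affected iff a uniform [0,1) draw is strictly below the risk.
m is therefore an *expected* prevalence — the affected count is binomial,
not fixed. A `case_control_subsample` utility (convenience plumbing, not part
of the generation model) draws a fixed cases:controls design post hoc.

Datasets serialise to TSV with genotypes as risk-allele counts 0/1/2, the
true per-individual risk column optional behind a flag. Every run directory
also receives the echoed configuration, the solver provenance
(coefficients, target and achieved total risks, residual) and a log; all data
files are byte-deterministic in (config, seed). The log also records wall
time, which is informational and excluded from determinism guarantees.

## Validation layer

`summarize` recomputes from a finished dataset: empirical prevalence,
per-genotype affected fractions and their ratios, and per-genotype
maximum-likelihood logistic slopes of status on the causal exposure, each
with a z-score against its requested value. The logistic fit is a
self-contained two-parameter Newton–Raphson (convergence when the update norm
drops below 1e-8, steps damped to length ≤ 10 against quasi-separation);
keeping it in-repo makes the validation oracle auditable, and it is checked
against `statsmodels` in the test suite. Degenerate strata (empty or
one-class) yield flagged undefined slopes rather than errors.
`mc_total_risk` provides the sampling-based counterpart of the quadrature
total risk used as an independent cross-check.

## What the randomized test conditions emulate

Randomized specifications draw RR31 uniformly in [1, 5], W in [0, 1], m in
[0.02, 0.3] (typical complex-disease prevalences and moderate genetic
effects), allele frequencies uniformly in [0.1, 0.9], the environmental OR
log-uniformly in [1/3, 3], and exposure laws across the discrete, uniform and
normal kinds. Infeasible draws are rejected and resampled, mirroring how the
tool itself refuses infeasible input. Test sample sizes (2·10⁵ for marginal
recovery, 100 replicates of 5·10⁴ for slope-coverage, 300 replicates of
2·10³ for the null-association screen) were chosen so binomial sampling
error is small against the effects being checked.

The generator emulates idealised cohorts: Hardy–Weinberg genotypes,
independent loci and exposures, no missingness, no genotyping error, no
covariate measurement error, and a correctly specified logistic risk. Passing
tests therefore demonstrate internal consistency of the model, solver and
sampler — not robustness of downstream methods to the artefacts of real
data.

## Limitations

* The constraint-based solver covers only one causal gene × one causal
  environment; multi-factor risks require a user-supplied coefficient table
  (CUSTOM mode), for which no epidemiological back-calculation is attempted.
* No linkage disequilibrium, haplotypes, pedigrees or time-varying exposures.
* The link function is fixed to the logistic.
* GEM requires a nonnegative exposure support (see above).
* Exact case/control counts are available only through post-hoc subsampling,
  which discards the cohort-level prevalence interpretation.
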