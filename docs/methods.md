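# Methods

## Model and assumptions

The package analyses a 2-df chi-square test of independence on a 2×3
phenotype-by-genotype table in a case-control study that mixes error-free
("gold standard") labels with misclassified ("silver standard") labels.

Assumptions, in decreasing order of consequence:

1. **Conditional independence** of the observed label X and genotype given
   latent affection Z. Genotype may influence the EMR-derived label only
   through true disease status; differential genotyping error between label
   groups violates this and is out of scope.
2. **Gold labels are error-free** (φ_gold = θ_gold = 1). The confusion
   machinery accepts any (φ, θ), so a four-predictive-value generalisation
   is a small extension, but it is not exercised by the test suite.
3. **Hardy-Weinberg equilibrium at the margin**, bi-allelic autosomal locus,
   unrelated individuals, no covariates.
4. The genotypic risk model (prevalence k, homozygous relative risk RR_AA,
   mode-determined heterozygous risk) is over-specified: combinations
   forcing a penetrance above 1 are "unphysical" and rejected (strict
   inequality; exactly 1 is allowed). RR_AA < 1 is rejected rather than
   re-parameterised — recode the risk allele instead.

## Parameters

| symbol | meaning | canonical levels | default where one is needed |
|---|---|---|---|
| N_co | gold controls | 200, 1000, 5000 | — |
| R | gold controls per gold case | 1, 2, 4 | — |
| γ_ca | silver cases per gold case | 0, 1, 4 | — |
| γ_co | silver controls per gold control | 0, 1, 4 | — |
| φ | PPV of silver case label | 0.6, 0.8, 1 | 0.7 (EMR dementia criteria) |
| θ | NPV of silver control label | 0.6, 0.8, 1 | 1 (no silver controls) |
| m | risk-allele frequency | 0.05, 0.1, 0.3 | — |
| k | disease prevalence | 0.001, 0.01, 0.3 | 0.13 (late-onset dementia) |
| RR_AA | homozygous relative risk | 1, 1.4, 3, 9 | — |
| mode | inheritance | dom/rec/multiplicative | multiplicative |
| α | significance level | — | 0.05 (also reported: 5e-8) |

The full Cartesian grid has 4×3⁹ = 78 732 combinations; exactly 8
(m, k, RR_AA, mode) risk combinations — all with k = 0.3, RR_AA = 9 — are
unphysical, each replicated 3⁶ times over the nuisance axes, leaving
72 900 usable scenarios of which 19 683 (RR_AA = 1) are null.

## Non-centrality and power

λ is computed as Σₖ M₁M₂(m₁ₖ−m₂ₖ)²/Cₖ with Cₖ the genotype-column total of
the expected-count table. This closed form is algebraically identical to
the Pearson X² statistic evaluated on the expected-count table (rows
M₁·m₁ and M₂·m₂); the test suite enforces the identity to relative 1e-8 on
randomly drawn scenarios, so the composition of the misclassification
algebra (P → Q → mixed frequencies → λ) is self-verifying. Power is the
upper tail of the non-central chi-square(2, λ) at the central quantile
−2 ln α. Structurally empty genotype columns (m = 0 or 1) are dropped with
a warning and the reference df reduced.

∂λ/∂γ_ca is differentiated exactly by the chain rule (dM₁ = n_gc,
d(M₁m₁ₖ) = n_gc·qₖ, dCₖ = n_gc·qₖ with n_gc the gold-case count and q the
silver case-row frequencies), treating γ_ca as continuous. A central
finite difference with relative step 1e-6 is kept as an independent oracle;
agreement to relative 1e-5 is asserted on random scenarios.

## Simulation engine

Each replicate draws the case row from multinomial(M₁, m₁) and the control
row independently from multinomial(M₂, m₂) — case-control sampling
conditional on fixed group totals, matching the conditional-frequency
formulation of the asymptotics. Group totals are rounded to the nearest
integer for sampling (the canonical grid never produces fractions; rounding
is logged). Per-scenario seeds derive from `SeedSequence([master_seed,
index])`, so any grid subset reproduces bit-identically regardless of sweep
order.

The asymptotic approximation is scored at the 20th percentile of X²: 80%
of realizations exceed it, so it is the critical value at which power would
be exactly 80%, and the percentage error E(ω) = 100(q20_sim −
q20_asym)/q20_asym probes the approximation where a designer would use it.
Empirical quantiles use linear interpolation between order statistics. For
null scenarios q20_asym = −2 ln 0.8 ≈ 0.4463 in closed form. The default
replicate count is 500 per scenario; the full canonical sweep is a CLI
batch job, while tests and the acceptance script use stratified subsamples
(50 null scenarios × 200 reps for type-I calibration; 100 physical
scenarios × 500 reps for the E(ω)–λ relationship), sizes chosen to keep
the default suite fast while leaving Monte-Carlo error well below the
asserted margins.

Allelic odds-ratio attenuation is demonstrated by computing the allelic OR
(risk-allele vs other counts, Haldane-Anscombe 0.5 correction for zero
cells, logged) per replicate and comparing its median against the OR
implied by the gold-standard frequencies.

## Synthetic locus pools and bootstrap power

`make_locus_fixture` draws three genotype-count pools — gold cases from
**P**'s case row, silver cases from **Q**'s case row, gold controls from
**P**'s control row — so pools are exactly self-consistent with the
analytic model. It emulates per-locus hard-call genotype pools of a
real blended cohort (the default sizes 672/843/1854 mirror a realistic
gold-case/silver-case/gold-control split); it does **not** emulate
linkage structure, imputation dosage uncertainty, genotyping batch
effects, or ancestry stratification, so bootstrap results on fixtures
validate the resampling machinery, not robustness to those artefacts.

`bootstrap_power` resamples genotypes with replacement (a multinomial draw
from pool empirical frequencies) at sizes fixed by a gold-case budget:
gold cases = budget (default: gold pool size), controls = R×budget, silver
cases = γ_ca×budget, rounded and logged. The empirical 20th percentile of
X² over replicates (default 1000) is the power summary.

Two asymptotic references exist deliberately. `asymptotic_counterpart`
uses an *assumed disease model* — the comparison a practitioner makes, in
which systematic gaps reflect model misspecification and pool sampling
noise. `pool_asymptotic_q20` plugs the *realized pool frequencies* into
the same λ machinery; conditional on the pools it is the bootstrap's true
large-sample reference, so the self-consistency tests compare against it
to isolate finite-study-size error from pool noise. Because the R = 1
power decline is small relative to one run's Monte-Carlo error, slope-sign
checks average over independent pool draws and bootstrap runs.

## Concordance with logistic regression

The experiment asks whether the sign of the chi-square power slope
predicts the change in logistic-regression power when silver cases are
added (γ_ca: 0 → 1, 500 simulated studies per arm, change measured as the
raw sign of the difference in median likelihood-ratio statistics). For a
3-level categorical predictor the logistic LRT equals the G² deviance
2ΣO ln(O/E) of the 2×3 table — an exact identity, verified against an
iteratively fitted binomial GLM in the tests — which makes the experiment
immune to separation (empty cells contribute zero) and fast. An optional
bootstrap confidence interval declares "no change" for null scenarios.

Two design choices deserve emphasis:

* **Predictor evaluation point.** λ(γ_ca) is not monotone on [0, 1]
  everywhere, so the slope at the γ = 0 endpoint can mispredict a finite
  0 → 1 step even with infinite replicates. The predictor is therefore the
  slope at the interval midpoint γ = 0.5 (mean-value-theorem reasoning: the
  step sign equals the slope at some interior point, and the midpoint is
  its natural single-point summary).
* **Known divergence.** The simulated change in median G² tracks the
  Kullback-Leibler analogue of the non-centrality, which at high R and low
  φ can move in the *opposite direction* to the Pearson λ on which the
  analytic slope is built — most visibly in the (R = 4, φ = 0.6, RR_AA = 9)
  cell of the concordance table, where the experiment scores far below the
  other cells. This is a genuine property of comparing a Pearson-based
  design rule against likelihood-based inference with heavily contaminated
  case labels, not a simulation artefact: the package's own acceptance
  test exposes it, and it flattens the otherwise-expected trend of higher
  concordance at larger effect sizes. Practitioners planning logistic
  analyses should treat the chi-square slope as a heuristic in that corner
  of the design space.

The default subgrid crosses R ∈ {1,2,4}, φ ∈ {0.6,0.8}, RR_AA ∈
{1.4,3,9} (the experiment's cell axes) with mode × m ∈ {0.05,0.1,0.3} per
cell (162 scenarios), holding k = 0.01, N_co = 1000, θ = 0.8, γ_co = 0:
a single prevalence/size slice keeps the experiment inside the regime
where a 500-replicate median is informative. Any other slice can be
supplied as a CSV grid via the CLI.

## Numerical choices

* Genotype order is (aa, Aa, AA) in every array, table and file.
* Analytic paths carry counts as real numbers; only sampling rounds.
* Penetrances are returned un-clipped when unphysical, so error messages
  can name the offending genotype.
* Degenerate columns: dropped with df annotation and a warning, never
  silently imputed.
* All randomness flows through `numpy.random.default_rng` /
  `SeedSequence`; identical seeds give bit-identical results everywhere.
* Scenario grids and results round-trip through plain CSV ('.' radix)
  with `# key=value` reproducibility headers (tool version, master seed).

## Limitations

* No trend/allelic 1-df asymptotic power, no covariates, no related
  samples, no X-linked or multi-allelic loci, no non-HWE margins.
* Genotype error (as opposed to phenotype-label error) is not modelled.
* The silver-standard predictive values (φ, θ) are inputs, not estimates;
  in practice they must come from chart review of a double-phenotyped
  subset, and results are only as good as those values.
* Bootstrap power conditions on the observed pools; with pools no larger
  than the resampled study, pool sampling noise contributes irreducible
  non-centrality of its own.
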