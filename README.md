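# stochmet

Stochastic modelling of metabolite heterogeneity in single cells.

Clonal populations of cells can split into metabolically distinct
subpopulations even without genetic differences: fluctuations in the
expression of a metabolic enzyme propagate to the metabolite it produces.
`stochmet` models a single enzymatic reaction with reversible
Michaelis–Menten kinetics (substrate + enzyme ⇌ complex ⇌ metabolite +
enzyme, with first-order consumption of the metabolite) coupled to the
three-stage stochastic gene-expression model (promoter on/off switching,
transcription, translation, mRNA degradation, dilution by growth), and
asks: what does the stationary distribution of metabolite copy numbers
look like across a population?

It is written for systems and quantitative biologists who want to predict
metabolite variability from enzyme kinetics and (measured or modelled)
single-cell enzyme distributions, without running prohibitively expensive
stochastic simulations.

## The model in brief

Because substrate–enzyme binding (ms) is much faster than catalysis (s),
which is much faster than enzyme expression and dilution (tens of
minutes), the stationary metabolite distribution is a **Poisson mixture
model (PMM)**:

    P(n_p) = Σ_n  P(n_etot = n) · Poisson(n_p; λ(n)),
    λ(n)   = λ∞ / (1 + K/n),
    λ∞     = n_s k_cat k_1 / (k_rev k_−1),
    K      = k_c (k_1 n_s + k_−1) / (k_rev k_−1),

where n_etot is total enzyme (free + substrate-bound), whose distribution
P(n_etot) is the closed-form stationary law of the three-stage expression
model, and λ∞/K = ε·k_cat/k_c with ε the enzyme saturation.  Depending on
where the enzyme distribution places its mass relative to K, the mixture
is unimodal, bimodal (two distinct mechanisms: slow promoter switching
propagating enzyme bimodality, or a weakly expressed unimodal enzyme whose
zero state shuts production off), or multimodal.

The package provides:

* `params` — rate-constant containers, named presets of the reference
  parameter sets, effective kinetics (λ∞, K, ε) and timescale diagnostics;
* `gene_expression` — numerically stable evaluation of the three-stage
  stationary pmf, empirical and Gamma-derived enzyme distributions, pmf
  table I/O;
* `pmm` — the λ(n_etot) map, reduced birth–death propensities, and mixture
  assembly with explicit truncation accounting;
* `ssa` — exact Gillespie (direct method) simulation of the full reaction
  network, stationary histograms, and a finite-state master-equation
  oracle used by the tests;
* `modality` — peak detection and the bimodality (10%/10%) and
  multimodality (1e-4 absolute, 90% trough) classification rules;
* `sweeps` — regime maps over promoter switching parameters and over
  (λ∞, K), and the λ∞/K constraint line for measured turnover numbers.

A thin CLI (`stochmet pmm|simulate|classify|sweep-switching|sweep-kinetic|line`)
wraps these for shell use.

## Worked example

```python
from stochmet import (preset, effective_kinetics, three_stage_params,
                      three_stage_pmf, poisson_parameter, pmm_distribution,
                      PoissonParameterMap, classify)

rc = preset("table1")                      # nominal parameter set
ek = effective_kinetics(rc)
print(f"lambda_inf = {ek.lambda_inf:.1f} molecules, K = {ek.K:.1f} molecules, "
      f"epsilon = {ek.epsilon:.2f}")

enz = three_stage_pmf(three_stage_params(rc))
print(f"enzyme: mean = {enz.mean():.1f}, var = {enz.var():.1f}, "
      f"support 0..{enz.support_max}")

met = pmm_distribution(enz, poisson_parameter(rc))
lab = classify(met)
print(f"metabolite: mean = {met.mean():.1f}, var = {met.var():.1f}, "
      f"label = {lab.label}")

enz_low = three_stage_pmf(three_stage_params(preset("fig3_low")))
met_multi = pmm_distribution(enz_low,
                             PoissonParameterMap.from_effective(750.0, 10.04))
lab_multi = classify(met_multi)
print(f"low expression, K = 10.04: label = {lab_multi.label}, "
      f"peaks at {[loc for loc, _ in lab_multi.peaks]}")
```

prints

```
lambda_inf = 1080.0 molecules, K = 8.0 molecules, epsilon = 0.75
enzyme: mean = 81.0, var = 180.1, support 0..173
metabolite: mean = 980.6, var = 1220.1, label = unimodal
low expression, K = 10.04: label = multimodal, peaks at [0, 67, 124, 172, 215, 254, 556]
```

Reading it: at the nominal parameters the enzyme is abundant (mean 81 ≫
K = 8), so λ(n_etot) is saturated near λ∞ and the metabolite is a single
overdispersed peak near 981 molecules (variance 1220 > mean — mixtures of
Poissons are overdispersed).  With a weakly expressed enzyme and K ≈ 10,
individual Poisson modes at λ(1) ≈ 68, λ(2) ≈ 125, … no longer overlap:
the population splits into several metabolically distinct subgroups,
including a non-producing one (the peak at 0 is the probability of
carrying no enzyme at all).

Exact stochastic simulation of the same system (`simulate`,
`run_stationary_histogram`) reproduces these distributions; the test suite
quantifies the agreement in total variation distance against both
simulations and a finite-state master-equation solver.

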