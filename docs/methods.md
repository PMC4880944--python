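# Methods

## The model and the selection problem

`clockcv` compares Bayesian hierarchical phylogenetic models for
tip-dated (or simulated, contemporaneous) nucleotide alignments.  A
hierarchical model here is a triple:

* **Clock model** — how substitution rates vary across branches.
  *SC* (strict): one rate r for every branch.  *UCLN*: each branch
  draws its rate independently from a lognormal with real-space mean
  equal to the clock's mean rate and log-space standard deviation S.
  *UCED*: independent exponential draws (whose sd necessarily equals
  the mean).
* **Demographic model** — the coalescent tree prior.  *CSC*: constant
  population size N0.  *EGC*: exponential growth, N(t) = N0·e^(−r·t)
  with t measured backwards from sampling.
* **Substitution model** — JC or GTR, optionally with discrete-Γ rate
  heterogeneity across sites (4 categories by default, mean-of-slice
  discretisation).

Model selection is by **site-wise cross-validation**: alignment columns
are split at random into disjoint training and test sets (50/50 or
80/20).  Each candidate model is fitted to the training sites by MCMC;
1,000 posterior draws are then scored against the test sites — each
draw's chronogram is converted to a phylogram by multiplying branch
durations (years) with branch rates (subs/site/year), and the test-set
log-likelihood is evaluated under the draw's substitution parameters.
The primary score is the arithmetic mean of the per-draw test
log-likelihoods; the log-of-mean-likelihood is retained as a secondary
diagnostic.  The procedure is repeated over independent splits (one
split per replicate, shared by all models so contrasts are paired), and
the model with the highest grand-mean score wins; exact ties go to the
model with fewer free parameters.  Stepping-stone marginal likelihoods
provide the reference Bayesian method for comparison.

## Priors

All defaults are proper, as stepping-stone requires:

| parameter | prior | default |
|---|---|---|
| clock mean rate | lognormal | real-space median 10⁻³ subs/site/year, log-sd 1.5 |
| UCLN log-sd S | exponential | mean 0.3 |
| N0 | lognormal | median 1 (coalescent units), log-sd 2 |
| growth rate r | Laplace | location 0, scale 1 /year |
| GTR exchangeabilities | i.i.d. gamma | shape 2, scale 0.5 |
| base frequencies | flat Dirichlet | — |
| Γ shape α | lognormal | median 1, log-sd 1 |

Every prior is overridable per parameter, including by a point mass
(which pins the parameter and removes its moves).

A structural property worth knowing: for r < 0 the EGC genealogy
density is *defective* — the cumulative coalescent intensity is bounded,
so lineages may never coalesce — and the joint prior therefore tilts
the growth-rate marginal positive relative to its Laplace factor.  The
prior-validation tests account for this by rejection-sampling the joint
prior rather than comparing against the bare Laplace.

## MCMC

Plain Metropolis–Hastings over node ages (uniform slides within
parent/child bounds, a root-gap multiplier, a joint scale of all
internal ages), the clock parameters (multipliers; one branch-rate
multiplier at a time plus a joint rescale), demographic parameters
(N0 multiplier, Gaussian random walk on r), substitution parameters
(frequency exchange, exchangeability and α multipliers) and, when the
topology is free, narrow exchange.  Two compound moves matter for
mixing:

* **rate–age up/down** — multiply the clock mean (and branch rates) by
  m and divide internal ages by m.  Branch lengths in substitutions are
  invariant, so the move walks along the rate–time ridge that dominates
  the autocorrelation time when tips are contemporaneous.
* **UCLN sd rescale** — multiply S by m while holding each branch's
  standardised log-rate fixed, with the exact Jacobian.  This traverses
  the hierarchical funnel at small S that defeats componentwise moves.

Chains default to the study protocol: 10⁷ steps, sampling every 5,000,
10% burn-in, and an ESS rule — whenever any parameter's effective
sample size is below 200 the chain length is doubled and the sampling
interval doubled (retained count preserved), up to `max_doublings`;
exhausting the cap flags the trace rather than passing silently.  ESS
uses n/(1 + 2Σρ̂) with Geyer's initial monotone positive-pair
truncation; a constant series reports ESS 1 with a degeneracy flag
(pinned parameters are exempted from the doubling rule).

Starting state: the provided topology (fixed-topology analyses) or a
UPGMA tree on JC distances; scalars start at central prior values.

## Stepping stone

Power posteriors at β_k = (k/K)^(1/0.3) — the quantiles of
Beta(0.3, 1) — with K = 32 stones by default, each stone sampled with
the ordinary kernel for `chain_length` steps chained from the previous
stone, 10% of each stone discarded.  The estimator is
Σ_k logmeanexp_i[(β_{k+1} − β_k)·loglik_i].  Improper priors are
refused with an explanation.  Note that parameters held fixed
contribute no prior-normalisation term: the estimate is the marginal
likelihood over the *free* parameters, conditioned on the pinned ones.

## Simulators

The generators reproduce the validation study's conditions and are
first-class, tested code:

* **Coalescent chronograms** by intensity inversion: with k lineages at
  time t0, the waiting time solves [k(k−1)/2]·[Λ(t0+w) − Λ(t0)] = E,
  E ~ Exp(1), Λ(t) = (e^{rt} − 1)/(rN0).  Under CSC this reduces to the
  familiar exponential draws.  Validated by closed-form interval means,
  a probability-integral-transform check, and a distributional
  cross-check against msprime.
* **Root conditioning** by linear rescaling of all node ages to root
  age 100 years, which preserves relative node ages (the coalescent
  shape) exactly.
* **Branch rates**: SC 10⁻³ subs/site/year; UCLN mean 10⁻³, sd 10% of
  the mean (moment-matched to log-space parameters via
  S² = ln(1 + (sd/mean)²), M = ln mean − S²/2); UCED mean 10⁻³.
* **Sequences**: root states from the stationary distribution, evolved
  through per-branch transition matrices; JC for the study grids,
  GTR+Γ available.  The simulated N0 is never stated by the study; the
  package default is 50, which puts a 12–50-taxon CSC root age on the
  100-year scale.  EGC simulations use growth rate 0.25/year.

Simulated tips are contemporaneous (the study states no sampling
spread).  This means the data cannot calibrate absolute rates: the
posterior is flat along the rate–time ridge.  The desk-scale
experiments therefore pin the clock mean to the generating 10⁻³ — the
stand-in for the date calibration the empirical analyses have — and
what passing tests demonstrate is the ranking of *relative* rate and
shape signal, not absolute-rate estimation.  Real serially-sampled data
(supported via tip dates in labels) do not need the pin.

## Desk-scale problem sizes

The full grids (50 taxa, 5–15 knt, 10 replicates, 10⁷-step chains per
model per split) are reproducible via the CLI configs but are
cluster-sized.  The shipped experiments and the acceptance script use
a reduced scale chosen once: 12 taxa, 1,200 nt (1,000 and 4,000 nt for
the length-trend experiment), 5 simulation replicates (20 for interval
coverage), chains of 12,000 steps sampled every 15 with 10% burn-in,
300 posterior draws per score, one 50/50 split per replicate, fixed
(true) topology.  Analysis priors for these runs: clock mean pinned as
above; N0 ~ lognormal(median 50, log-sd 2), centred on the root-age
scale implied by the calibration.

## Numerical choices

* Rate matrices are normalised to unit expected substitution rate at
  stationarity, so branch lengths are always expected
  substitutions/site and duration×rate conversions carry units
  correctly.
* Pruning runs over compressed site patterns with per-pattern
  log-space rescaling every 8th internal node — far from double
  underflow even at 50 substitutions/site, without a per-node
  reduction.
* Γ category rates are the means of equal-probability quantile slices
  of Gamma(α, α), computed from the incomplete-gamma identity; the
  multipliers average to 1 by construction.
* Gaps and IUPAC ambiguity codes enter as all-ones partial vectors
  (fully missing).
* Credible intervals are equal-tailed quantile intervals, not HPD —
  deterministic and estimator-free; for unimodal marginals the
  difference is negligible.
* Newick serialisation orders children by smallest descendant tip name,
  so equal trees serialise byte-identically; branch rates are written
  as `[&rate=...]` comments.
* Seeds: one master seed expands through named `SeedSequence` streams
  (tree / rates / sequence / split / chain), recorded in run manifests.

## Known limitations

* The sampler is plain MH in pure numpy; the full study grids are
  feasible but slow on one core.  No adaptive proposals.
* Topology estimation uses only narrow exchange; for data with weak
  signal, fixed-topology analyses are recommended (and are what the
  scaled experiments use).
* UCLN/UCED mixing at very small sd relies on the funnel rescale move;
  extreme hierarchical geometries may still need longer chains than
  the ESS rule's default cap allows.
* The empirical tables' absolute scores depend on the original
  analyses' (unstated) priors and on external alignments, and are not
  reproduced here; only the selection logic over the printed values is.
* Distinguishing UCLN from UCED is genuinely hard at small scale; the
  desk experiments check the direction of the length trend, not the
  full-scale frequencies.
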