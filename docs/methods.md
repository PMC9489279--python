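# Methods

This note documents the statistical models, the numerical choices behind
the implementation, what the synthetic-data generator does and does not
emulate, and the package's known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Susceptibility calling

Ct (qPCR cycle threshold) is inversely proportional to log template
amount: "more virus" always means *lower* Ct. Non-detections are imputed
at Ct 40 (the run length) only where an operation needs a numeric value,
and the imputation is logged.

* **Within-strain spread.** σ_w = sqrt(mean over strains of the sample
  variance (ddof = 1) of replicate Cts), experimental strains only,
  non-detections at 40. Strains with fewer than two replicates carry no
  variance information and are excluded (logged). Controls and benchmarks
  are excluded from σ_w; the assay design excludes them from all
  analyses, and the pooled value is intended to describe experimental
  strains.
* **Threshold.** τ = (minimum *detected* benchmark-4 Ct) − σ_w, pooling
  benchmark wells across all blocks (a single global threshold; the
  design reports one). Undetected benchmark wells are ignored — an
  undetected well says nothing about the maximum carry-over. A
  benchmark-5 variant (`benchmark=5`) uses the no-replication benchmark
  instead, giving a deliberately conservative threshold.
* **Call.** A replicate is infected iff Ct < τ *strictly* (equality is
  not infection); a strain is susceptible iff ≥ 1 replicate is infected.
  Imputing non-detections at 40 can never create an infected call for any
  τ ≤ 40, and calls are monotone in τ (both property-tested).

## Transmission scoring

A passage line is an ordered detection sequence over passages 0–5
(passage 0 = primary exposure). Lines that stop early did so because the
virus became undetectable, so they are padded with non-detections; a line
*detected* at its last recorded passage but shorter than six entries is
ambiguous between scores 2 and 3 and rejected as truncated. The rule —
0: not detected at exposure; 1: detected at exposure, not at passage 1;
2: detected at passage 1 but lost by passage 5; 3: detected at passage 5
— partitions all scoreable sequences (verified by exhaustive
enumeration).

## Tree handling

The phylogeny must arrive rooted, with branch lengths on every non-root
edge, and ultrametric; ultrametricization (e.g. strict-clock smoothing)
is treated as preprocessing by external tools and is *not* reimplemented.
Validation is relative: max tip-depth deviation ≤ `tol`·H (default 1e−6),
naming the worst tip on failure.

The relatedness matrix A holds root-to-MRCA depths of species pairs; on
an ultrametric tree diag(A) = H and cophenetic distance satisfies
d(i,j) = 2(H − A[i,j]) (both tested). A is inverted by dense Cholesky
(panels here are ≤ ~100 species), which simultaneously verifies positive
definiteness; a singular A — typically tips joined by a zero-length
split — triggers one retry with an effective minimum branch length of
1e−9·H, then an error advising a minimum branch length. Taxon order is
Newick first-appearance order everywhere. Pruning keeps the root (even
unifurcate) so the height and all retained pairwise distances are
unchanged. Strains map to their species' tip; observations on species
absent from the tree have no defined distance or covariance and are
dropped with a logged warning before model fitting.

## The phylogenetic mixed model

Liability: ℓ = Xβ + Σ_t Z_t u_t + e with u_phylo ~ N(0, σ²_p A),
u_species ~ N(0, σ²_s I), u_strain ~ N(0, σ²_st I), e ~ N(0, σ²_e I).
Binomial response: per-strain counts k ~ Binom(n, logistic(ℓ)) with ℓ
latent (per-strain counts, not per-replicate Bernoulli: replicate
populations of one strain share one exposure and one liability).
Gaussian response: the score is the liability.

Priors follow the conventions of the mixed-model ecosystem this design
comes from: fixed effects N(0, 10⁸); each variance component gets the
parameter-expanded prior (V = 1, ν = 1, α_μ = 0, α_V = 1000), implemented
as the redundant multiplicative scheme u_t = α_t η_t with
η_t ~ N(0, σ²_η,t K_t) and α_t ~ N(0, 1000), whose implied prior on
σ²_t = α_t² σ²_η,t is the scaled-F family; residuals are inverse-Wishart
(V = 1, ν = 0.002).

One Gibbs/Metropolis sweep:

1. *(binomial)* per-site random-walk Metropolis on ℓ given its normal
   prior around the linear predictor and the binomial likelihood;
   per-site step sizes adapt multiplicatively (rate 0.05) towards 0.44
   acceptance during burn-in and are frozen afterwards. Realised
   acceptance is reported and sits in [0.2, 0.7] on the designs tested.
2. Joint multivariate-normal draw of (β, η) from the mixed-model
   equations, assembled from a precomputed Gram matrix rescaled by the
   current α's; Cholesky factorization doubles as the positive-
   definiteness check (failure aborts with the iteration index, as does
   any non-finite draw).
3. Conjugate normal update of all α's jointly.
4. Conjugate inverse-gamma update of each σ²_η,t.
5. Conjugate inverse-gamma update of σ²_e, unless held fixed.

The equivalence of the target distribution, not the update order, is the
contract: the Gaussian fixed-effect-only sampler is tested against the
closed-form conjugate posterior, and with A = I the phylo and species
terms are exchangeable with only their sum identified (tested).

**Residual variance in binomial fits.** σ²_e on the liability scale is
only weakly identified by binomial data; leaving it free inflates the
scale of all liability-scale effects jointly (this is why such analyses
can report very large fixed-effect magnitudes). The default follows the
prior above and reports effects as-is; `fix_residual_variance=1.0` holds
it fixed, which the package's own simulation studies use and which is
recommended when comparing effects across fits.

**Summaries.** Posterior mean, 95 % HPD interval (equal-tailed available
by flag; "central posterior density" interval is read as HPD, the
convention of this model family), and pMCMC = 2·max(1, min(#>0, #<0))/S
capped at 1 — never exactly zero. At least 100 stored draws are required.
Summaries are deterministic functions of the stored draws.

**DIC.** Conditional deviance D(θ) = −2 log p(y | θ) with θ the
liabilities (binomial; binomial coefficient included) or fitted values
plus σ²_e (Gaussian). DIC = mean(D) + pD with pD = mean(D) − D(θ̄) and θ̄
the posterior mean of the liabilities / of (fitted values, σ²_e).
Because the original analyses' exact deviance convention for binomial
DIC is not published, absolute DIC values are not comparable across
implementations; ΔDIC within a suite and the derived weights are the
meaningful quantities.

**Convergence.** One chain per fit. The Heidelberger–Welch stationarity
test applies a Cramér–von Mises statistic to the Brownian-bridge
transform of the cumulative sums, with the long-run variance estimated
as the spectral density at zero from an AIC-selected AR fit to the second
half of the chain; failing chains drop successive 10 % prefixes up to
50 %. A chain that is numerically constant or a deterministic linear
trend has zero long-run variance and fails outright. The statistic is
scale-free, so verdicts are invariant to affine rescaling.

## Model and component comparison

Weights are computed in log space (`logsumexp`) so large ΔDIC cannot
underflow the normalisation; deltas are re-anchored at zero, making
weights invariant to constant shifts of all DICs. Component membership is
decided from the formula descriptor (term sets), never by name-matching
fitted parameters. Report output rounds to 3 decimals.

R² per component and draw: a non-intercept fixed term contributes the
population variance (divisor n) of its fitted contribution over the
observed design rows — deterministic and consistent with
variance-decomposition conventions; random terms contribute their
variance draw, the residual its draw. Shares are normalised per draw, so
they sum to exactly one and combined shares are additive. Draws with zero
total variance are skipped with a warning.

## Synthetic data generator

The generator emulates the *statistical design* of the assay: 44 species
(one to three strains each, ≈ 84 strains), three replicate populations
per strain, eight blocks, controls and benchmarks in triplicate per block
with moments (benchmark 4: 38.4 ± 2.6, benchmark 5: 22.0 ± 0.6, positive
controls 15.7 ± 2.0 and 12.7 ± 2.2), non-detections at Ct 40, and a
binomial liability model on a height-1 pure-birth tree with defaults
β₀ = 0.5, β₁ = −2, σ²_p = 1, σ²_s = 0.5, σ²_e = 1. Those defaults were
chosen to reproduce the design's overall susceptibility rate (the
simulated strain-level susceptible fraction is ≈ 0.27 vs 21/84 = 0.25
observed) and the separation between infected and carry-over Ct regimes
(infected replicates at 20 ± 4, straddled by the positive-control means
and the threshold regime). Passage persistence is
logistic(logit(1 − 0.3) − 0.25·(Ct₀ − 20)) per passage, so transmission
declines with exposure Ct by construction.

Everything is deterministic given (seed, config), and the config is
embedded in the truth record. What the generator does *not* emulate:
within-host kinetics, viral evolution during passage, qPCR curve shape,
block-level batch effects, and real *Caenorhabditis* topology (pure-birth
trees only — topology realism is irrelevant to the contracts tested).
Consequently, passing tests demonstrate correctness of the machinery and
recoverability under the assumed model, not robustness to the ways real
assay data violate it.

## Problem sizes and numerical choices in the test suite

Chains in tests are desk-scale by design: the estimator default is
50 000 iterations / 10 000 burn-in / thin 20; simulation studies in the
suite use 8 000 / 2 000 / thin 6 (1 000 stored draws) per fit, 100
replicate datasets of 40 species × 3 strains for the recovery study, and
20-species panels for pipeline smoke runs. The original chain settings
(10⁸ iterations, burn-in 30 000, thin 5 000) are accepted via
configuration but exercised by no test. Matrix-inverse residuals are
required below 1e−8 up to 100 tips; weight tables normalise to 1 within
1e−12; R² shares to 1 within 1e−10.

## Open design choices made here

* Species without phylogenetic placement are excluded from model fits
  (with logged accounting); a species off the tree has no defined
  covariance. The original analysis is not explicit on this point.
* σ_w pools experimental strains only, and benchmark-4 wells are pooled
  across blocks (one global τ); a per-block option exists.
* Lines with undetected exposure virus (score 0) carry Ct = 40 for the
  transmission model's amplification covariate — declared, configurable.
* Transmission blocks are pooled without a block term, matching the
  model suites, which contain none.
* HPD rather than equal-tailed intervals by default (flag available).

## Known limitations

* The liability-scale residual in binomial fits is weakly identified;
  effect magnitudes are only comparable across fits at a fixed σ²_e.
* Honest posterior power to *sign* the distance-from-focal-host effect
  at the generator's default nuisance variances is limited (the distance
  covariate is strongly confounded with the phylogenetic random effect
  on a pure-birth tree); the recovery study in the acceptance suite
  reports coverage and sign-recovery rates explicitly.
* Single-response models only; no multi-trait fits, no WAIC/LOO, one
  chain per fit.
* Dense linear algebra throughout: fine to a few hundred species, not
  designed for thousands.
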