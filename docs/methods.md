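# Methods

`matechoice` analyses mating-status-dependent mate choice in an
isofemale-strain design: 20 strains of *Drosophila melanogaster* arranged
in 5 randomized blocks of 4, with male mating success scored in four
contexts — virgin (V+) or previously mated (V−) females, with (C+) or
without (C−) male–male competition — plus inbreeding-sensitive fitness and
viability crosses and wing/sex-comb morphometrics. This note records the
models, the generative assumptions of the synthetic-data module, and the
numerical choices, in the package's own terms.

## The estimand and the choice model

Let a_s = (a_{s1}, …, a_{s4}) be the effect of male strain s on mating
success in the four contexts (order V+C+, V−C+, V+C−, V−C−). The target
is the covariance structure

    a_s ~ MVN(0, diag(σ) R diag(σ)),

whose diagonal SDs σ_k index female "choosiness" (how strongly success
discriminates among male genotypes within a context) and whose
correlations R_{jk} measure whether the same genotypes succeed across
contexts. The observation model is Bernoulli-logit on binary
success/failure rows:

    noncompetitive (k = V+C−, V−C−):  logit p = μ_k + a_{m k} + b_{f k}
    competitive    (k = V+C+, V−C+):  logit p = μ_k + γ_color + a_{m k}

with female-strain responsiveness effects b_{fk} ~ N(0, σ_{b,k}²)
independent per noncompetitive context and a dye-color fixed effect in
competitive vials. No male-by-female interaction and no block term are
included (both were negligible in the design this package emulates).
Although the four contexts could be fit separately, cross-context
correlations are only defined in the joint model, so the joint fit is the
primary mode; a per-context fit falls out of the same machinery by
passing a single context's rows (the remaining parameters then sample
their priors, leaving the observed context's marginals intact —
verified against quadrature).

### Making the contexts comparable

Competitive vials identify one winner among four males, so a uniformly
sampled male succeeds with probability 1/4. Noncompetitive trials are
therefore binarized at the 25th percentile of latency within each
block × female-status group: success = mated with latency ≤ the group's
empirical quantile, censored trials counting as slower than any observed
latency. The quantile is linear-interpolation over the full group
(mated + censored at +∞), with an inclusive ≤ rule so threshold ties all
count as successes; a group whose raw mated fraction is already below the
target quantile keeps its raw mated flags. Competitive vials are reduced
to one binary row each by sampling one male per vial; the sampling is
repeated R times (default 100) and the model is refit per resample, the
posteriors pooled with resample provenance retained. Pooling propagates
the sampling uncertainty and is order-invariant.

### Priors, sampler, summaries

Priors: half-Student-t(3, 0, 2.5) on all SDs, Student-t(3, 0, 2.5) on
intercepts, improper flat on the color contrasts, and a uniform
distribution over positive-definite correlation matrices (LKJ shape 1) on
R — the conventional weakly-informative defaults for this model family.

The sampler is adaptive Metropolis-within-Gibbs on a non-centered
parameterization (a = diag(σ) chol(R) z, z ~ N(0, I); likewise for b),
compiled with numba. Non-centering avoids the funnel when the data pull a
SD toward zero, which matters for the null-calibration behaviour.
Blocks: one 4-D random-walk per strain's z row, scalar walks for all
other parameters, log-scale walks for SDs (with the Jacobian), and
entry-wise walks on R with a positive-definiteness check (the uniform
prior contributes only the PD indicator). Step sizes adapt by
Robbins–Monro toward 0.25 (vector blocks) / 0.44 (scalars) during warmup
only. Chains are seeded deterministically from the model seed; the first
half of each chain is warmup and the remainder is thinned (the
4 × 20,000, thin-10 convention retains 4,000 draws). Convergence is
monitored by split-chain potential scale reduction; `summarize()` refuses
when the maximum core-parameter R̂ exceeds 1.05 unless forced.

The sampler was validated against a dense-quadrature oracle on a tiny
instance (σ-posterior quantiles agree to within grid/MC error) and
against a Laplace maximum-likelihood route at large n.

Summaries are the posterior mode with the 95% highest-density credible
interval, because SD posteriors are right-skewed. The interval is the
shortest contiguous window of sorted draws containing ⌈0.95 n⌉ of them
(unimodal HDI; multimodal samples would still get the shortest single
window). The mode is a Gaussian-KDE argmax with Silverman's bandwidth,
computed on a 4096-bin binned kernel estimate with least-squares
parabolic refinement of the peak; SD draws are reflected at zero to avoid
boundary bias. With Silverman's rule the KDE-argmax itself carries a
sampling SD of ≈0.04 at 10⁶ standard-normal draws (1/√(n h³) scaling);
wider peak windows would reduce that jitter only by biasing skewed
posteriors, so the narrow window is kept and tests budget for the jitter.

A correlation is called supported when its 95% HDCI excludes zero, with
a boundary exactly at zero counting as overlap.

### Maximum-likelihood confirmation

Per-context logistic mixed models are fit by maximizing a Laplace
approximation to the marginal likelihood (the adaptive-Gaussian scheme at
one node, which is what crossed male- and female-strain intercepts
admit): an inner Newton solve for the random-effect mode, an outer
L-BFGS-B over fixed effects and SDs with σ ≥ 0 bounds so boundary
estimates are exact zeros. Variance components are tested by 1-df
likelihood-ratio tests with the statistic clamped at zero; a variance on
the boundary reports statistic 0, p 1, with an optional 50:50
χ²₀/χ²₁ mixture correction available (`lrt_boundary_mixture_p`). Note the
statistic is exactly 0 in only about half of null realizations — the
classical boundary mixture — so "always 0 under the null" is not an
attainable calibration target. Covariances of strain means are tested by
a delete-one-strain jackknife (n−1 covariance denominator, SE from
pseudovalues), and plain Pearson correlations of per-strain success
proportions are reported alongside.

## Fitness and viability

Competitive fitness is w = ln((wt + 1)/(be + 1)) for wild-type versus
brown-eyed offspring counts; egg-to-adult viability substitutes adults
for wt and dead eggs (eggs − adults) for be. Zero-egg vials are removed
first (uninformative), then zero-adult vials (possibly unmated females),
with both counts reported.

Each trait is decomposed by a Gaussian linear mixed model: random
male-strain, female-strain and male×female intercepts (crossed variance
components), fixed categorical block and cross (within- vs between-strain)
effects under sum-to-zero coding. REML supplies the variance estimates;
random terms are tested by ML-refit LRTs (1 df, boundary convention as
above); fixed terms by type-II Wald χ² (each term against the model
retaining the other). Estimated marginal means average the fixed-effect
predictions over the other factor's levels with equal weights, random
effects at zero, SEs by the delta method. Residuals further than
2 × IQR from zero (the IQR of the marginal residual distribution; the
"from 0" anchor is the center, and the multiplier is configurable) are
removed in a single pass and the model refit once. Residuals are the
marginal (fixed-effects) residuals of the fitted model. With no random
terms the machinery reduces exactly to OLS with the n − p residual
variance, which is the REML limit.

## Morphometrics

Nine 2-D wing landmarks are superimposed by generalized full Procrustes
analysis: center, scale to unit centroid size, rotate to the current mean
(SVD rotation, no reflection), iterate with the mean re-normalized to
unit size each round (first wing as initial reference) until the mean
changes by < 1e-8. Centroid sizes are kept from before scaling. For PCA,
deviations from the mean shape are projected into the tangent space
orthogonal to the four similarity directions (x/y translation, scaling
along the mean, infinitesimal rotation), so exactly 2·9 − 4 = 14
components carry variance; without the projection the shape-sphere
curvature leaves a spurious ~1e-5-relative 15th eigenvalue. PC signs are
fixed so each component's loading on landmark 2's x-coordinate is
non-negative (first nonzero loading as tie-break). Wing shape is PC1.

Multivariate outliers are flagged on the 14 PCs plus centroid size
(pooled covariance across blocks) when the squared Mahalanobis distance
exceeds the upper-0.001 χ² quantile at 15 df (37.70). Wing length is the
Euclidean landmark 3–9 distance in the raw digitized coordinates times
the per-image mm scale; landmark indexing is 1-based in all I/O. Strain
means of mating success are regressed on strain means of wing length, PC1
and sex-comb tooth count by OLS with intercept; each predictor's marginal
F is t² on (1, n − 4) df.

## The synthetic-data generator

The generator is first-class: it defines the conditions under which every
downstream claim is tested, and it returns the realized true parameters so
recovery is assertable end to end. Design defaults mirror the emulated
study: 5 blocks × 4 strains; 19/15 noncompetitive trials per strain pair
per block for virgin/non-virgin females (1,520/1,200 trials); 21/32
competitive vials per female strain and block (420/640 vials, of which
~390/~340 mate); 120-min censoring.

Latency is a log-normal race: log T = log(baseline) − (a + b) + ε,
ε ~ N(0, 1.5). The same strain effects a drive noncompetitive latency and
the competitive winner (the minimum of four correlated racers), which is
what a cross-context correlation presupposes. Baselines (16/183 min
noncompetitive, 126/580 min per-male competitive) were solved from the
published mating fractions: they reproduce ≈91%/39% noncompetitive and
≈93%/47% competitive mating, and ≈60% of virgin matings within 20 min.
Strain-effect SDs default to (0.27, 0.41, 0.32, 0.38) with the published
correlation pattern (0.80 between the two noncompetitive contexts);
dye-color effects (0.15, −0.06, −0.21, 0.12) reproduce win shares near
28/24/21/27%.

Fitness counts are Poisson with vial-level lognormal rate noise (sd 1.0
on both competitors), block effects, a within-cross deficit of 0.64 on
the log-ratio scale, and male×female effects with SD 0.47; this yields
log-ratio residual variances of order 2 and interaction variances of
order 0.2 — the scale of the published variance decomposition this
design emulates — and within-strain crosses at double replication
because between-strain crosses are reciprocal. Viability is zero-inflated Poisson eggs (44%
zero-egg), a 5% unfertilized-clutch rate (eggs but no adults), and
binomial survival with logit-scale female-strain effects (sd 0.5),
within-cross deficit 0.8 and vial noise sd 1.0. Wings are strain mean
shapes plus isotropic landmark noise, pushed through random rotation,
translation and digitization scale; planted outliers displace one
landmark by a configured multiple (default 15×) of the noise SD.

What the generator does **not** emulate: circadian/temporal structure in
trial scheduling, observer or aspiration effects, dye-feeding physiology,
rearing-vial micro-environments, male harassment dynamics, age effects,
and any genuine genetic architecture beneath the strain effects. Passing
tests therefore demonstrate that the pipeline recovers the stated
statistical structure at the stated scale, not that real data meet these
assumptions.

All generators are pure functions of (config, seed); stage seeds derive
from the master seed by fixed documented offsets; unmated trials record
no latency.

## Problem sizes and numerical conventions in tests and scripts

Bayesian fits in the test-suite and the acceptance script use 2 chains of
1,200–2,000 iterations (half warmup, thin 4–5) — enough, with resample
pooling, for stable mode/HDCI summaries of this model, as chosen for
routine reruns of the whole suite; the 4 × 20,000 convention remains the
default for final analyses. The recovery check runs 10 replicate studies
at full design scale with 10 resamples each; the null-calibration check
runs 50 studies at 2,000 trials per context. The acceptance script runs
one full default-scale study with 10 resamples. Sub-seeds are always
`seed + index`; every simulation, resample and chain is reproducible from
one master seed, and pipeline outputs are byte-identical across reruns
(timestamps live in the run log only).

## Known limitations

- Random-walk MCMC mixes more slowly than gradient-based samplers; short
  chains show R̂ up to ~1.1–1.8 per fit and rely on resample pooling for
  summary stability. The contract (seeded, R̂-checked) is met, and the
  guard refuses to summarize unconverged single fits unless forced.
- The KDE posterior mode has irreducible ~0.03–0.04 jitter under
  Silverman's rule (see above) and is upward-biased for strongly skewed
  posteriors at small draw counts.
- The Laplace approximation can bias variance estimates downward for
  binary data with few observations per strain; it is used as
  confirmation, not as the primary estimator.
- Binarization discards latency information by design (a deliberate
  reduction to a common binary scale, not a survival analysis), and the
  latent-scale SDs recovered on the logit scale are attenuated relative
  to the log-latency scale that generated them; correlations, being
  scale-free, transfer cleanly.
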