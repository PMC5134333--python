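# Methods

## Model

A compound at concentration `x` (μM) blocks a fraction of an ion current
according to the Hill curve with bottom fixed at 0 % and top at 100 %:

```
f(x; pIC50, Hill) = 100 / (1 + (IC50/x)^Hill),   IC50 = 10^(6 − pIC50) μM.
```

All potency arithmetic is done in pIC50 = 6 − log10(IC50[μM]) space;
linear moves in pIC50 translate the curve linearly on the usual
log-concentration axis, which keeps optimisation and sampling well
conditioned. The curve is evaluated as a scaled logistic,
`100·expit(Hill·ln10·(log10 x − (6 − pIC50)))`, which is exact and avoids
overflow for any parameter values; `x = 0` returns the analytic limit 0.

An observation `y` (% block) is modelled as Normal around `f` with SD σ,
truncated to [0, 100] because screening pipelines cap raw values into that
range. The truncation constant `Φ((100−f)/σ) − Φ(−f/σ)` depends on each
point's own mean and is recomputed per point and per parameter proposal.
Since `f ∈ [0, 100]`, the truncated interval always contains the mean, the
retained mass is ≥ Φ(2)−Φ(0) for σ ≤ 50, and a plain `ndtr` difference is
numerically safe down to σ = 10⁻³; everything is evaluated in the log
domain.

**Single-level model** — all K points share one (pIC50, Hill, σ) with
independent uniform priors, defaults pIC50 ∈ (−1, 15), Hill ∈ (0, 10),
σ ∈ (0, 50). The bounds are configuration (`UniformPriorBounds`) so that
screens with different dynamic ranges can widen them; the defaults encode
that sub-(−1) pIC50 values are indistinguishable from "no effect" over any
practical concentration range, that Hill coefficients above 10 are
biologically implausible, and that 50 % noise SD is a generous ceiling.

**Hierarchical model** — experiment i keeps its own pair

```
Hillᵢ  ~ log-logistic(α, β)         pIC50ᵢ ~ logistic(μ, s)
```

with a single shared σ; the free parameter vector is
(α, β, μ, s, σ, pIC50₁…pIC50_Nₑ, Hill₁…Hill_Nₑ), dimension 5 + 2Nₑ.
The log-logistic density is used in scale–shape form with median α,

```
p(h; α, β) = (β/α)(h/α)^(β−1) / (1 + (h/α)^β)²,
```

equivalently log h ~ logistic(log α, 1/β). This makes α directly
interpretable as the typical Hill coefficient and μ as the typical pIC50,
which is exactly how the "underlying effect" prediction mode uses them.

## Hyperpriors

The top-level parameters get gamma priors (shape k, scale θ):

| parameter | prior            | mean | rationale |
|-----------|------------------|------|-----------|
| α         | Γ(2.5, 0.5)      | 1.25 | typical Hill near 1, support ~0.2–4 |
| β         | Γ(2.5, 2.5), β>2 | 6.25 | Hill spread weakly known; hard floor below |
| μ         | Γ(7.5, 1.5) − 4  | 7.25 | broad; shifted so < 5 % mass below −2 |
| s         | Γ(2.0, 0.5)      | 1.0  | potency spread from fractions to ~2 log units |
| σ         | Γ(2.0, 3.5), σ>10⁻³ | 7.0 | noise expected at a few % with generous headroom |

Two hard support constraints are enforced as −∞ log density (i.e. proposal
rejection): β > 2, which makes the log-logistic density and its gradient
vanish at Hill = 0 so zero Hill coefficients cannot be sampled; and
σ > 10⁻³, since observation error never vanishes exactly and σ → 0 is a
numerical singularity. The μ prior's −4 shift admits slightly negative
typical potencies (ineffective compounds) while keeping essentially no
mass where curves are flat over any measurable concentration range. All
five specs are plain `GammaSpec(shape, scale, shift)` fields of
`HierPriorConfig` and can be replaced wholesale. With even one experiment
the likelihood dominates μ and σ; β is the one parameter that typically
stays prior-like, and the prior-versus-posterior contraction test tracks
this explicitly.

## Inference

1. **Starting point (CMA-ES).** A compact (μ/μ_w, λ)-CMA-ES (weighted
   recombination, rank-one + rank-μ covariance update, cumulative
   step-size adaptation) maximises the log posterior. Box constraints are
   handled by clip-repair plus a quadratic penalty. Because small
   populations on 3-parameter problems occasionally converge prematurely
   (measured ~6 % of runs), the optimiser restarts up to twice with
   doubled population from the incumbent best, which brought the measured
   stall rate below 0.3 %. For the hierarchical model, each experiment is
   first fitted separately with the single-level posterior; the top-level
   start is then moment-matched — α and μ from the medians of the
   per-experiment estimates, β and s from their spreads via
   SD(log Hill) = π/(β√3) and SD(pIC50) = sπ/√3, and σ from the pooled
   residual SD of the per-experiment start curves (robust to any single
   stalled experiment fit).

2. **Sampling (adaptive Metropolis).** Random-walk Metropolis with
   multivariate Gaussian proposals centred on the current state. The
   proposal covariance is `λ · (Ĉ + 10⁻¹⁰ I)` where Ĉ is the running
   empirical covariance of the chain (Welford update, Cholesky refreshed
   every 25 iterations) and the global scale λ starts at 2.38²/d and is
   tuned towards 25 % acceptance by a Robbins–Monro recursion with decay
   (t+1)^−0.6. For the first 100·d iterations the covariance is a fixed
   diagonal whose entries come from the inverse diagonal curvature of the
   log posterior at the starting point (central second differences),
   falling back to preset per-parameter scales where curvature is
   unusable; the scalar λ adapts from iteration 0. At a few geometric
   checkpoints inside the first fifth of the run the chain is repositioned
   to its best-seen state if it has fallen more than max(2d, 25) log units
   below it — an equilibrated chain sits only ~d/2 below the mode, so this
   only fires on trapped burn-in excursions, and the checkpoints all lie
   well inside the discarded quarter. Out-of-support proposals are
   rejected via −∞, preserving detailed balance trivially.

3. **Burn-in.** The first quarter of the chain (configurable) is
   discarded; `ceil((1−fraction)·T)` samples are retained, at least one.

All randomness — CMA-ES, proposals, acceptance — flows from one seed via
`numpy.random.SeedSequence` spawning, so a (seed, data, settings) triple
reproduces every sample bit-for-bit. The default production chain length
is 500,000 iterations; the validation studies in this repository use
100,000 (the three-preset recovery studies) down to 30,000 (the
contraction sweep), sizes at which the recovered posteriors agree with
400k–600k reference chains.

## Posterior predictives and block prediction

The predictive for a future experiment's Hill (or pIC50) is the
equal-weight mixture over retained iterations t = 1..T of
log-logistic(α_t, β_t) (or logistic(μ_t, s_t)) densities; the CDF is the
average of component CDFs. Sampling uses inverse transform through a
deterministic 4096-point grid spanning the 10⁻⁶ … 1−10⁻⁶ quantile
envelope of the components (geometric spacing for the positive-support
log-logistic, linear otherwise) with monotone interpolation; the grid
resolution bounds the CDF error well below the 0.01 Kolmogorov–Smirnov
tolerance the tests enforce at 10⁵ draws. Component evaluation is chunked
so arbitrarily long chains stay within memory.

`predict_block` pushes (pIC50, Hill) sample pairs through the Hill curve
at a given concentration. Three sources are supported: single-level chain
columns; hierarchical (μ_t, α_t) columns — the *underlying* effect with
inter-experiment variability discounted; and draws from the posterior
predictive mixtures — a *future experiment* including that variability.
The exported block samples are the hand-off point for downstream
simulation tools; no action-potential modelling is included here.

## Synthetic data generator

`generate_dataset` draws per-experiment (pIC50ᵢ, Hillᵢ) from the same
population families the hierarchical model assumes (or holds either
fixed), evaluates the Hill curve on a shared dose grid, and adds
truncated-normal noise on [0, 100] — the exact observation model of the
likelihood, which makes parameter-recovery studies well-posed. A
`clip_noise` flag instead adds unbounded Normal noise and caps, emulating
how raw screening data are actually censored at source. The default dose
grid is 4 log-equispaced concentrations from IC50/30 to 30·IC50 of the
population-median potency, covering the curve from ~3 % to ~97 % block.

Three presets define the standard studies: `fig9`
(μ=6, s=0.1, α=1, β=5, σ=1, 16 experiments) for noise recovery and
prior-to-posterior contraction; `shamiodarone` (Hill fixed at 1,
pIC50 ~ logistic(6, 0.2), σ=0.5, 5 experiments) and `shamitriptyline`
(pIC50 fixed at 6, Hill ~ log-logistic(1, 2.5), σ=0.5, 5 experiments) for
checking that variability is attributed to the correct parameter.

What the generator does **not** emulate: patch-clamp artefacts (rundown,
series-resistance error, leak), dose-dependent noise, correlated errors
within a sweep, or misspecified population shapes. Passing recovery tests
therefore demonstrates the inference machinery is correct under its own
assumptions, not that real screening data satisfy those assumptions.

## Numerical notes and edge cases

- Stable logistic-family log densities use the −|z| − 2·log1p(e^−|z|)
  form; no overflow for any argument.
- Chain CSVs are written at `%.17g` and read back with correctly-rounded
  float parsing, so write→read is bit-lossless.
- `x = 0` doses are legal (zero-dose controls) and contribute a response
  of exactly 0 through the curve.
- Degenerate generator settings (σ = 0) return exact curve values.
- With a single experiment the hierarchical start cannot estimate spreads
  and falls back to fixed defaults (s = 0.02 floor, β = 10).

## Known limitations

- σ is only weakly identified at 4 points per experiment: with two latent
  parameters per experiment the population layer can absorb or release
  part of the realised noise, so single-dataset posteriors for σ scatter
  around the generating value by roughly ±0.2 at Nₑ = 16 even with a
  perfectly specified model. More doses per experiment sharpen it quickly.
- Random-walk Metropolis mixing degrades as 5 + 2Nₑ grows; beyond a few
  tens of experiments a structured sampler (blocked or gradient-based)
  would be needed.
- The truncated-likelihood treatment of capped data is a pragmatic match
  to how screens report values; a censored-data likelihood would use the
  capped observations more faithfully and is not implemented.
- Priors are calibrated for ion-channel screening; other assay families
  should revisit `HierPriorConfig` and the uniform bounds.
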