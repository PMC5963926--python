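# Methods

## The model

`scobserver` implements a Bayesian observer for a two-step perceptual
task: the observer first judges whether a stimulus orientation θ
(degrees relative to a discrimination boundary; positive = clockwise) is
cw or ccw, then reproduces the orientation.  The generative chain is

    θ  →  m  = θ + ε_s,   ε_s ~ N(0, σ_s²)      (sensory measurement)
    m  →  mm = m + ε_m,   ε_m ~ N(0, σ_m²)      (working-memory recall)

The categorical judgment maximizes the posterior over C ∈ {cw, ccw}:

    ĉ(m) = argmax_C p(m|C) p(C),   p(m|C) = ∫ p(m|θ) p(θ|C) dθ.

Because the likelihood ratio is monotone in m, this is a threshold rule;
the criterion is located once by bisection on the posterior odds and is
exactly 0 for the symmetric default (p(C) = 0.5).  The predicted
psychometric function marginalizes the rule over p(m|θ) and therefore
reduces to Φ((θ − c)/σ_s).

The defining feature of the *self-consistent* observer is that the
estimation stage is conditioned on its own preceding judgment: the
posterior over θ given the recall mm and the choice ĉ is

    p(θ | mm, ĉ) ∝ q(mm | θ, ĉ) · p(θ | ĉ),

where p(θ|ĉ) is the choice-conditioned stimulus prior (zero on the
inconsistent side) and q is the decide-restricted recall density

    q(mm | θ, ĉ) = ∫_{ĉ(m)=ĉ} N(mm; m, σ_m) N(m; θ, σ_s) dm
                 = N(mm; θ, σ_t) · Φ(± (μ(mm) − c)/τ),

with σ_t² = σ_s² + σ_m², μ(mm) = (σ_m²θ + σ_s²mm)/σ_t², and
τ = σ_s σ_m/σ_t (Gaussian product rule).  We use q *unnormalized* in the
posterior; the fully-coherent alternative (dividing by p(ĉ|θ)) would
cancel the choice information entirely and remove the truncation that
produces the model's signature.  Summed over the two choices with their
masses, q reconstructs N(mm; θ, σ_t) exactly — a partition identity the
test suite asserts everywhere.

The estimate is the posterior mean (squared-error loss), a deterministic
monotone mapping θ̂(mm, ĉ).  Predicted estimate distributions push the
(normalized) conditional recall density through this mapping and mix
over choices with weights p(ĉ|θ); the reported estimate adds Gaussian
motor noise σ_0 (measured separately, never fitted).

Model variants share the same parameters:

- **known_category** — the conditioning category is given and correct
  (cued designs): the recall marginalization runs over all m (no
  decide-restriction) and the mixing weights are p(C|θ) ∈ {0, 1}
  (½/½ exactly at the boundary).  Biases are slightly smaller than for
  self-made judgments because incorrect-judgment trials no longer exist.
- **independent** — the control observer that estimates from the
  unconditioned posterior p(θ|mm) ∝ N(mm; θ, σ_t) p(θ).  Its estimate
  distribution is unimodal; conditioning it on the (still-made) choice
  uses the same truncated recall density pushed through the single
  unconditioned mapping, so the two models have identical parameter
  counts and directly comparable likelihoods.
- **boundary_shift** — the boundary moves by a fixed offset before
  estimation while the stimulus stays put; both the implicit judgment
  and the conditioned prior follow the shifted boundary, so the
  predicted density is an exact frame translation.
- **boundary_noise** — the boundary is absent at estimation time and the
  conditioned prior is re-centred on a Gaussian recalled boundary
  (SD σ_b), integrated by 21-node Gauss–Hermite quadrature (extreme
  nodes beyond half the grid span are trimmed and the weights
  renormalized; their Gauss–Hermite mass is negligible).  The decide
  restriction and choice weights stay at the true boundary, where the
  judgment was actually made.  This fills in the estimate-density gap;
  note that at the canonical σ_0 = 4.3° the motor-convolved density has
  a dip-to-peak ratio above 0.5 even at σ_b = 0, so the bimodality-loss
  signature is asserted on the unconvolved gap plus the monotone rise of
  the convolved ratio.

## Parameters

| name | meaning | unit | default |
|------|---------|------|---------|
| σ_s (3) | sensory noise per stimulus-noise level | deg | 3, 5, 8 |
| σ_m | memory recall noise | deg | 2 |
| α | uniform half-range of the conditioned prior | deg | 25 |
| β | cosine fall-off extent of the prior | deg | 12 |
| σ_0 | motor noise (fixed, measured) | deg | 4.3 |
| λ | lapse rate (report flip probability) | – | 0.04 |
| σ_b | boundary-recall noise (boundary-absent variant) | deg | optional |
| p(C) | category prior | – | 0.5 |

The conditioned prior is uniform on (0, α] with the quarter-cycle ramp
cos(π(θ−α)/(2β)) on (α, α+β]; this is the unique standard cosine ramp
whose half-density point sits at the prior width w_p = α + 2β/3.
Normalization is analytic (α + 2β/π).  Support is open at exactly 0: the
boundary itself belongs to neither category, and all grids are offset
half a step from 0 so no sample point ever sits on the discontinuity.

The default synthetic observer (σ_s = 3/5/8 for array SDs 0/6/18°,
σ_m = 2, α = 25, β = 12 → w_p = 33, σ_0 = 4.3, λ = 0.04) reflects the
behavioral regime of practiced observers in such tasks: sensory noise
monotone in stimulus noise, modest memory noise, a subjective prior
wider than the true ±21° stimulus range, and a few-percent lapse rate.

**Lapse convention.**  A lapse flips the reported category with
probability λ while the estimate still follows the internal judgment
(wrong button, not a changed mind); in the cued design a lapse is a
misremembered — hence wrong — cue that the estimate then follows.  The
lapse-augmented psychometric is accordingly λ + (1−2λ)Φ((θ−c)/σ_s):
floor λ, ceiling 1−λ, with λ identified on [0, ½] (λ = ½ is random
responding).  This flip parameterization, rather than the
guess-rate convention with floor λ/2, is used consistently in the
generator, the psychometric fits, and the inconsistency predictions, so
a single λ means the same event everywhere.

## Numerics

- **Grids.**  θ, m, mm and θ̂ share a uniform grid, by default 0.2° over
  ±80° (≥ 4 SD beyond the prior support for plausible noise), midpoint
  integration.  The fitter uses 0.4° over ±60°; both resolutions give
  log-likelihoods equal to ~0.1 nat on 1800 trials.
- **Closed forms.**  The decide-restricted recall density and the choice
  probabilities use the Gaussian-product closed form above rather than
  inner quadrature over m; a quadrature route is retained and
  cross-checked in the tests.  Degenerate noise (σ_s = 0 or σ_m = 0)
  reduces to indicator-truncated Gaussians and grid deltas.
- **Estimate mapping.**  θ̂(mm) is tabulated on the grid from the
  log-posterior (log-space softmax; rows whose posterior underflows —
  recalls far on the inconsistent side, where the conditional recall
  mass is itself negligible — are filled from the nearest valid
  neighbor).  Monotonicity is asserted (tolerance 1e-6) and enforced by
  a running maximum.
- **Pushforward.**  The predicted estimate density is an exact
  mass-preserving CDF transport: the mapping is evaluated at the input
  cell edges and each cell's mass is spread linearly over its image
  interval.  This is the change-of-variables density without Jacobian
  differencing; plateaus (posterior saturated against the prior edge)
  correctly collapse to point masses in a single output cell.
- **Motor convolution** uses a discrete Gaussian filter
  (`scipy.ndimage.gaussian_filter1d`, truncate 8 SD, zero-padded ends);
  double convolution raises.
- **Ties.**  m exactly at the criterion is judged cw (measure-zero on
  continuous m; fixed for reproducibility).  Estimates of exactly 0 are
  classified inconsistent — they lie in neither category's open
  half-line.
- **Orthant probabilities** for the no-conditioning analysis use the
  bivariate normal CDF (`scipy.stats.multivariate_normal`), verified
  against the closed form ½ − arcsin(ρ)/π at the boundary.

## Fitting

The six free parameters (σ_s per level, σ_m, α, β) are fitted by
multi-start Nelder–Mead on log-transformed parameters (positivity by
construction; relative function tolerance via `fatol`, 2000-iteration
cap, adaptive simplex).  Restart initializations are log-uniform over
σ_s ∈ [1, 20], σ_m ∈ [0.5, 30], α ∈ [10, 40], β ∈ [1, 30]; one
additional start takes σ_s from probit slopes of the choice data.
Twenty restarts reproduce the published procedure; the test suite and
the acceptance script use 2–3 starts with 150–500 iterations, which the
recovery experiments show is sufficient at these problem sizes.

Trials whose estimate contradicts the reported category are excluded
before fitting.  The likelihood of a remaining trial is therefore the
*conditional* density of a consistent trial under the full generative
chain: on the reported side,

    f_ĉ(θ̂) = (1−λ)·ψ_ĉ·d_ĉ(θ̂) + λ·ψ_¬ĉ·d_¬ĉ(θ̂),

where ψ is the lapse-free choice probability and d the motor-convolved
conditional estimate density, normalized by the total consistency
probability.  λ is measured from the psychometric functions of the full
data set beforehand and held fixed; the six model parameters are
unaffected.  At λ = 0 this reduces to the familiar product of the choice
probability and the half-line-renormalized estimate density.  We use
this form because the naive product objective is measurably biased on
synthetic data: conditioning on consistency steepens the effective
psychometric, and the rare lapse trials rescued by motor noise fall
where the pure conditional density vanishes, dragging σ_s down and σ_m
up by ~20–40%.  A switch (`renormalize=False`) disables the consistency
normalizer for comparison.  Known-category trials use the unrestricted
recall density, replace ψ by the cue assignment, and contribute no
choice factor.  Predicted densities are floored at a configurable
minimum (default 1e-6 deg⁻¹, with a warning) so single outliers cannot
produce an infinite objective.

Joint fits across experiments pool trials into one table; σ_s is then
shared per noise level automatically because there is a single parameter
vector.  Bootstrap confidence intervals resample trials with replacement
within each (θ, noise level) cell and refit with a reduced budget
(starting from the point estimate); percentile intervals are widened, if
necessary, to contain the point estimate.  The expected √n shrinkage of
interval widths is not asserted by the tests: at reduced refit budgets
the σ_m width is dominated by refit scatter along the σ_s/σ_m trade-off
ridge rather than by the information term, so a reliable check would
require full-budget fits beyond the suite's scale.

## The synthetic generator

`synthetic_data.simulate_trials` draws the exact chain the analysis
assumes — measurement, judgment (or given cue), lapse, recall,
posterior-mean estimate, motor noise — with independent per-stage random
streams derived from one master seed (changing one stage's draw count
never shifts another stage's stream).  Designs mirror the standard
three-experiment task battery: 15 orientations −21…21° in 3° steps,
three stimulus-noise levels, 40 trials per cell (1800 trials), plus the
boundary-shift (±6°) and boundary-absent variants.  The boundary-absent
simulation discretizes the recalled boundary to 1° so estimate mappings
can be cached per offset.

What the generator does *not* emulate: sequential effects between
trials, learning of the prior over sessions, orientation-dependent
(oblique-effect) sensory noise, non-Gaussian motor error, and the
unrelated color task of the cued design (cue-memory errors enter only as
the wrong-cue lapse rate).  Passing tests therefore demonstrate internal
consistency of model, fitter and generator — not that real observers
satisfy these assumptions.

## Problem sizes in tests and the acceptance script

Monte-Carlo oracles use 1–2 × 10⁵ draws (total-variation tolerances 0.02
against ~0.008 sampling noise at 0.2° bins; histogram agreement checks
rebin to 2° so sampling noise stays below the 0.03 tolerance at 10⁴
trials per cell).  Parameter recovery averages five 1800-trial fits with
an informed start plus two random restarts (500 iterations); the model
comparison runs twenty seeds with one informed start per model (150
iterations) — the self-consistent vs independent log-likelihood gap
(~20–40 nats) dwarfs optimization slop at that budget.

## Known limitations

- The no-conditioning dominance argument (without conditioning, memory
  noise would produce far more inconsistent trials than observed) is
  quantitatively decisive only when σ_m is comparable to σ_s; at the
  default σ_m = 2 < σ_s the design-averaged no-conditioning fraction is
  similar in size to the lapse+motor prediction.  The package tests the
  dominance at σ_m ≥ σ_s and the monotone structure elsewhere.
- Only squared-error loss (posterior mean) is implemented; MAP or L1
  estimators would need a new mapping function.
- Orientations are treated as unwrapped angles; the implementation is
  valid while stimuli stay well within ±90° of the boundary, as in the
  ±21° designs.
- The mapping from physical stimulus noise (array SD) to σ_s is left
  free per level; no psychophysical linking model is assumed.
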