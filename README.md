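# scobserver

A self-consistent Bayesian observer model for discrimination–estimation
task sequences in psychophysics.

## The problem

In many perceptual experiments an observer first makes a categorical
judgment about a stimulus — *was the orientation clockwise (cw) or
counter-clockwise (ccw) of a reference boundary?* — and then estimates
the same stimulus feature.  Human estimates in such sequences are
systematically **repelled from the boundary**, toward the side of the
preceding judgment, forming bimodal estimate distributions near the
boundary.  A Bayesian observer that treats the two tasks independently
predicts none of this.

`scobserver` implements the observer model that does: after the
categorical judgment ĉ, the estimation posterior is *conditioned on the
observer's own choice*,

    p(θ | mm, ĉ) ∝ p(mm | θ, ĉ) · p(θ | ĉ),

where θ is the orientation relative to the boundary, mm a noisy working
memory recall of the sensory measurement m ~ N(θ, σ_s²) (recall noise
σ_m), p(θ|ĉ) a choice-conditioned stimulus prior (uniform over α with a
cosine fall-off over β; zero on the inconsistent side), and the
likelihood marginalizes only over measurements that led to the choice.
The posterior-mean estimate (L2 loss) is then biased away from the
boundary — the self-consistency signature.  Gaussian motor noise σ_0
(measured separately) corrupts the report, and lapses flip the reported
category at rate λ.

The package is aimed at computational-psychophysics work: it provides
the generative model and its predicted psychometric functions, estimate
densities and bias curves; an "independent observer" control model with
identical parameters; joint maximum-likelihood fitting of trial data;
predictions for inconsistent trials (lapse + motor decomposition) and
for the consistency cost of *not* conditioning; and a synthetic-trial
generator for the standard experiment designs (including known-category
cueing and boundary shift/removal variants).

## Worked example

Simulate the standard 1800-trial experiment (15 orientations from −21°
to 21°, three stimulus-noise levels, 40 trials per cell) from the
canonical synthetic observer and refit the model from scratch:

```python
import scobserver as so

truth = so.default_params()          # sigma_s=(3,5,8), sigma_m=2, alpha=25,
                                     # beta=12, sigma_0=4.3, lapse 4%
design = so.make_design(1)
table = so.simulate_trials(design, truth, seed=0)

consistent, inconsistent = so.classify_consistency(table)
print(f"inconsistent trials: {len(inconsistent)/len(table):.1%}")
print(f"extracted lapse rate: {so.extract_lapse_rate(table):.3f}")

fit = so.ObserverMLE(n_restarts=2, max_iter=500, random_state=0).fit(table)
p = fit.params_
print(f"fitted sigma_s: {tuple(round(s, 2) for s in p.sigma_s)}")
print(f"fitted prior width wp: {p.prior_width:.1f} deg (truth {truth.prior_width:.0f})")

th, bias = so.bias_curve(truth, 2, "self_consistent")
print(f"repulsive bias at 3 deg, high noise: {dict(zip(th, bias.round(2)))[3.0]} deg")
```

Output:

```
inconsistent trials: 6.8%
extracted lapse rate: 0.044
fitted sigma_s: (2.35, 4.43, 8.49)
fitted prior width wp: 32.1 deg (truth 33)
repulsive bias at 3 deg, high noise: 7.67 deg
```

The inconsistent fraction is the lapse + motor-noise prediction in
action (λ plus boundary crossings of the motor-corrupted estimate); the
fitted sensory noise tracks the generating values per level and the
prior width w_p = α + 2β/3 is recovered to a couple of degrees; the
bias at 3° grows with stimulus noise (4.4 → 6.6 → 9.9° across the three
levels for the generating parameters).

A command-line interface wraps the same pipeline:

```bash
scobserver simulate --experiment 1 --seed 0 --out runs/sim
scobserver fit runs/sim/trials.csv --restarts 5 --seed 0 --out runs/fit
scobserver predict runs/fit/fit_result.json --variant self_consistent --out runs/pred
```

Every run writes a resolved-config JSON sidecar next to its outputs.

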