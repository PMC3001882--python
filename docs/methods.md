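# Methods

`bayesrt` models trial-by-trial reaction times in a probabilistic
cue–outcome association task as the behaviour of an ideal Bayesian
observer coupled to a speed–accuracy trade-off, and inverts that model
from observed reaction times. This note records the model, its
assumptions, the numerical choices, and what the synthetic validation
does and does not establish.

## The observer's generative (perceptual) model

On trial *k* the observer receives a scalar sensory sample
*u<sub>k</sub>* caused by a binary category *x<sub>k</sub>* (0 = face,
1 = house):

    u_k | x_k ~ N(eta_house, sigma_u^2)^{x_k} N(eta_face, sigma_u^2)^{1-x_k}
    x_k | a_k ~ Bernoulli(s(a_k)),        s = logistic sigmoid

where *a<sub>k</sub>* is the hidden cue–outcome association on the logit
scale. Two models differ only in the prior over *a*:

* **static** — a single constant drawn from N(0, 1/λ); λ is the prior
  precision of the association and, operationally, an initial condition
  for the belief dynamics;
* **dynamic** — a Gaussian random walk,
  a<sub>k</sub> = a<sub>k−1</sub> + ε, ε ~ N(0, 1/λ); λ is the transition
  precision, so 1/λ is the assumed volatility of the world and sets the
  observer's effective learning (forgetting) rate.

The sensory constants are treated as known to the observer and to the
experimenter. Defaults: η = ±1 and σ<sub>u</sub> = 0.5, i.e. a
discrimination ratio |Δη|/σ<sub>u</sub> = 4, comparable to natural
face/house images after projection to one dimension; it is a
configuration knob. The logistic slope is fixed at 1 — any rescaling is
absorbed by λ.

## Recognition (variational inversion of the perceptual model)

The joint posterior over (x<sub>k</sub>, a<sub>k</sub>) is factorised as
Bernoulli(μ<sub>x</sub>) × N(μ<sub>a</sub>, σ²<sub>a</sub>) and the
sufficient statistics maximise a per-trial free energy — a lower bound on
the log-evidence of that trial's sample. The intractable
E[softplus(a)] term is expanded to second order around μ<sub>a</sub>,
which makes the bound computable and yields the stationarity conditions

    mu_x   = s(llr(u) + mu_a)
    0      = s(llr + mu_a) - s(mu_a)
             - (sigma2_a/2) s'(mu_a)(1 - 2 s(mu_a)) - (mu_a - m)/v
    sigma2_a = 1 / (s'(mu_a) + 1/v)

with (m, v) the trial's prior over *a* (for the dynamic model
v = σ²<sub>prev</sub> + 1/λ) and `llr` the sensory log-likelihood ratio.
The third term of the μ<sub>a</sub> equation is a skew correction that
follows from the same expansion used in the free-energy value; without
it the Gaussian mean sits at the Laplace mode, which is biased by up to
~0.1 towards zero relative to the exact posterior mean at prior
variances around 2. With it, the scheme matches dense-grid exact Bayes
to better than 0.05 on the mean and 20% on the variance over randomised
decisive-stimulus instances (this is verified by the test suite, not
assumed).

The pre-stimulus prediction of the outcome,
ξ = s(m / √(1 + πv/8)), uses MacKay's moment approximation for a
Gaussian pushed through a logistic.

Numerical choices. The μ<sub>a</sub> equation is a scalar root problem
whose solution is unique whenever v < 3.5 (safeguarded Newton); for
larger prior variances the per-trial free energy can be multimodal, so
all roots are located by a bracketed sign-change scan (the root is
confined to |a − m| ≤ 1.5v + 2) refined by Brent's method, and the root
with the highest free energy is kept. Tolerance 1e−8 on the stationarity
residual; σ²<sub>a</sub> is floored at 1e−8. Exactly ambiguous stimuli
with a symmetric prior resolve to μ<sub>x</sub> = ξ. Trial-1 belief for
the dynamic model defaults to (0, 1); the static model's trial-1 prior is
N(0, 1/λ) by definition, which makes the dynamic model's zero-volatility
limit coincide with a static observer of unit prior precision.

Known limitation: on genuinely ambiguous stimuli (|llr| ≲ 1) the
mean-field factorisation treats the inferred soft category as real
Bernoulli information and shrinks the association variance more than
exact Bayes does. The task this package models operates in the
strong-evidence regime, where the effect is negligible; the grid-oracle
tests therefore draw decisive stimuli.

## Response model: deciding when to decide

Deliberating longer buys accuracy at a price. The loss of announcing
choice *c* at peristimulus time *t* is

    L(c, x, t) = 1{c != x} + beta_err * t

so β<sub>err</sub> (in errors per second) is the number of errors the
subject would trade against one second of delay. Within a trial the
category belief relaxes exponentially from the pre-stimulus prediction ξ
towards the converged posterior μ<sub>x</sub> at rate β<sub>sens</sub>
(1/s). Writing ε for the post-hoc prediction error μ<sub>x</sub> − ξ
signed towards the chosen category, the posterior risk is

    R(t) = const + eps * exp(-beta_sens t) + beta_err * t

which for ε > 0 is convex with the closed-form minimiser

    t* = max(0, ln(beta_sens * eps / beta_err) / beta_sens).

Consequences: categorisation errors (ε ≤ 0) are emitted instantly;
well-predicted outcomes (small ε) yield fast responses — the
learning-induced facilitation the task exhibits; t* is affine in ln ε
over its positive range (a Hick's-law-like form in the amount of
incoming information). Observed reaction times add i.i.d. Gaussian noise
of precision φ; error trials enter the likelihood with a tiny weight
(default 1e−8), which removes them from the fit without disturbing the
learning trajectory. An optional constant non-decision offset (default
0, excluded from inversion) is provided for fitting real data.

## Inversion of the response model

Unknowns: θ = (ln λ, ln β<sub>err</sub>, ln β<sub>sens</sub>) with
Gaussian priors (log-normal on the natural scale) and φ with a Gamma
prior. Defaults: prior means (0, −2, 2) for the dynamic model and
(2, −2, 2) for the static one, variance 10² each; φ ~ Gamma with mean
10⁴ and unit coefficient of variation (shape 1, rate 10⁻⁴). The response
prior means are package defaults chosen so that typical draws produce
0.1–0.6 s optimal reaction times. The φ prior is deliberately a
*weakly* informative one: a Gamma with the same mean but variance 10⁶
(shape 100) acts as ~200 pseudo-observations of the noise precision and
provably biases the posterior precision upward by a factor
(a₀ + n/2)/(n/2) whenever the realised noise exceeds the prior mean,
which produced overconfident credible intervals (joint 99%-CI coverage
0.82 instead of ≥ 0.9 in calibration runs). The sharper variant remains
available through `PriorSpec.from_phi_moments`.

The scheme is a mean-field q(θ)q(φ) with a Laplace (Gaussian) factor for
θ, algorithmically the inversion of a nonlinear state-space model:

1. **E-step** — regularised Gauss–Newton (Levenberg-damped) ascent on the
   fixed-precision MAP objective; each objective evaluation re-runs the
   nested recognition at the candidate λ. Covariance
   Σ = (E[φ] JᵀWJ + P₀)⁻¹ at the mode.
2. **M-step** — conjugate Gamma update of φ from the weighted residuals
   plus the linearised posterior-uncertainty correction.
3. Free energy assembled from the linearised accuracy term and the two
   KL divergences; the outer loop stops when |ΔF| < 10⁻⁴ (max 64
   iterations), and a step that lowers F is rejected (best state kept),
   so the recorded F sequence is non-decreasing.

Derivatives: the response-parameter columns of the Jacobian are
analytic; the perceptual column is a central secant whose step adapts to
the current posterior sd of ln λ (floor 0.03, cap 0.5). The wide secant
is deliberate: sequential mode-tracking recognition is only piecewise
smooth in λ (belief trajectories can bifurcate), and machine-scale
differences across those micro-discontinuities masquerade as enormous
curvature. The diagnostic `response_objective` (φ marginalised
analytically against its Gamma prior) retains exact small-step central
differences and a Gauss–Newton curvature.

Multi-start: the free-energy surface can be multimodal in ln λ, so the
first starts place ln λ at the prior mean and at offsets −2, +2, −4
(covering the sampling range of the validation study); any further
starts are jittered with sd 1. After the winner converges, the MAP
objective is probed on a local ln λ grid around it and the loop restarts
from any probe that clearly wins — this catches Gauss–Newton stalls on
the stair-stepped λ direction. The best free energy wins; ties break
towards the prior mean. Log-parameters are clipped to ±16 during
optimisation. Candidate parameter vectors whose recognition fails are
treated as rejected steps.

Because distinct local modes can carry comparable evidence, the reported
posterior over the log-parameters is a Gaussian mixture over the
distinct modes found within 10 nats of the best (weights proportional to
exp of their free energies): `theta_mean`/`theta_cov` are the mixture
moments and credible intervals come from the mixture's marginal
quantiles, while `theta_mode` is the best single mode. The model
evidence remains the best single-mode bound — any one variational
density gives a valid lower bound on the log evidence, whereas a sum of
basin bounds does not. Calibration of the 99% intervals at 0 dB is ~0.9
joint coverage over 50-replicate runs; the residual overconfidence stems
from micro-modes of the piecewise-smooth recognition surface that mode
enumeration cannot exhaust.

Belief trajectories are reconstructed at the posterior mode of λ with
per-trial variances propagated from Var(ln λ) by first-order
sensitivity; the delta-method variances agree with Monte-Carlo
propagation within a factor of two on test sessions.

## Model comparison

Free energies are lower bounds on log model evidences; their difference
is an approximate log Bayes factor (|ΔF| ≥ 3 flagged as strong
evidence). Group-level comparison uses the random-effects variational
scheme: each subject's model is drawn from an unknown multinomial with a
Dirichlet prior (α₀ = 1 per model); iterated updates give the Dirichlet
posterior over model frequencies, expected frequencies, and exceedance
probabilities (closed Beta form for two models, seeded Dirichlet
sampling otherwise, 10⁶ draws by default). Per-subject evidences from
multiple cue streams are summed before group comparison, with the
option of treating cues as pseudo-subjects for robustness checks. Only
within-subject evidence differences matter.

## Synthetic validation (what the Monte-Carlo study emulates)

Two series of simulations validate the whole pipeline with known ground
truth. Series A draws observers that use the static model, series B
observers that use the dynamic one; in each simulation the stimuli are
sampled from the observer's own generative model (a constant-association
world for A, a random-walk world for B), the observer's recognition and
optimal reaction times are computed, noise is added at a controlled SNR,
and the response model is inverted under both perceptual models.

Conditions (package choices, fixed once):

* 100 trials per session; discrimination ratio 4.
* No categorisation errors: the sensory sample of a trial is redrawn
  (sequential rejection, hence still causal) if a misleading draw would
  leave the converged belief on the wrong side of chance.
* SNR in dB of the ratio of deterministic RT signal *power* (mean
  square) to noise variance, levels {40, 20, 0}; with second-scale
  reaction times, 0 dB corresponds to roughly unit noise variance, the
  level realistic for empirical reaction-time data. Sessions whose
  deterministic RT modulation has sd below 20 ms (an order of magnitude
  under motor-noise scales, hence uninformative about learning) are
  redrawn.
* True log-parameters sampled uniformly: response pair from
  [−4, 0] × [0, 4]; ln λ from [−2, 2] for dynamic observers and from
  [−1, 1] for static ones. The static box brackets unit prior
  precision — the dynamic model's zero-volatility limit, which is where
  "static nested in dynamic" genuinely holds in this parameterisation
  and where the static prior (worth about one trial of evidence) leaves
  almost no footprint in behaviour, making it weakly identifiable, as a
  static initial condition should be.
* Reduced-replicate mode (12–20 simulations per cell) for routine runs;
  `MCConfig(n_sims=50)` for full runs.

Under these conditions the dynamic-true series is identified in 100% of
high-SNR simulations with mean evidence margins of order 10²,
the static-true series by margins of order 10¹ at high SNR shrinking to
near zero at 0 dB, dynamic margins exceed static ones by at least an
order of magnitude at matched SNR, and both evidence margins and
log-space parameter SSE improve monotonically with SNR. At 20 and 0 dB
the static-series margin is a coin toss within ±2 nats — the two models
are then genuinely near-equivalent on static data and the ~1-nat
asymmetry of the linearised free-energy approximation can favour either
model.

What passing does **not** show about real data: the generator assumes
exactly Gaussian, i.i.d. RT noise, a known and fixed sensory mapping,
no lapses, no non-decision time, no slow drifts in preferences, and
error-free sessions; empirical reaction times violate all of these to
some degree. The validation establishes internal consistency
(recognition ≈ exact Bayes, optimal times ≈ risk minimisation, inversion
recovers what the generator produced, evidence bounds hold), not
external validity of the behavioural model.

## Degenerate inputs and edge cases

Zero-length sessions are rejected; inversion requires ≥ 10 usable
trials. Weights lie in (0, 1]; non-positive precisions, variances, or
weights are rejected at construction. Saturated sigmoid arguments are
evaluated stably; reaction times are never predicted negative; the
prediction-error denominator in the learning-rate diagnostic is guarded
(NaN on zero-error trials). Time is in seconds everywhere; trial files
may be in ms with an explicit flag; trials are 1-based in files and
0-based in memory.
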