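# Methods

## The model

`diffdcm` implements a graph-diffusive generalisation of the linear
neuronal state equation used in dynamic causal modelling (DCM).  For `N`
regions coupled by a binary structural adjacency matrix `K` (with degrees
`d_i` and graph Laplacian `L = D − K`), the latent states obey

    dx_i/dt = Σ_j p_ij x_j + σ Σ_j k_ij (x_i − x_j) + Σ_j q_ji v_j + ω_i(t)

The second term equals `σ (L x)_i` — the algebraic identity
`Σ_j k_ij (x_i − x_j) = Σ_j l_ij x_j` is verified both ways in the test
suite — so the flow's drift matrix (and Jacobian) is `J = P + σL`.

Two conventions deserve emphasis:

* **Sign of the diffusion term.**  The term enters as `+σL x`.  Since `L`
  is positive semidefinite, this is *anti*-smoothing: a larger diffusion
  coefficient pushes eigenvalues toward instability.  That is intentional —
  it is precisely what makes a *reduction* in diffusivity (the `α < 1`
  result below) the stabilising direction, and what gives the
  gradient-minimising stimulation protocol its purchase.  We implement the
  equation exactly as the model defines it and do not "correct" it to the
  conventional `−σL` heat-equation operator.
* **σ is a rate constant**, units 1/s, and nonnegative in every generative
  context.  (During inference it is a free parameter whose posterior may
  straddle zero; see below.)

Observations are the latent states through the identity map plus i.i.d.
Gaussian noise — no haemodynamic convolution.  The fluctuations `ω` are
smooth ("non-Markovian") noise: white Gaussian draws convolved with a
Gaussian kernel of width `smoothness` (seconds), rescaled to a marginal
standard deviation `amplitude`.

## Structural preprocessing

Weighted connectomes are symmetrised by `(W + Wᵀ)/2`, the diagonal is
zeroed (the degree/Laplacian algebra presumes no self-loops), and weights
are normalised by the maximum entry.  Thresholds are fractions of that
maximum with an *inclusive* rule `k_ij = 1 ⇔ w_ij ≥ t`; the standard sweep
covers 10–95 % in 5 % steps (18 matrices).  Percentile-based thresholding
would also be defensible; fraction-of-max was chosen because normalisation
to the maximum immediately precedes thresholding in the pipeline.

## Integration

Because the model is linear, the default integrator is the *exact* one-step
discretisation: `x_{t+1} = A x_t + G u_t` with `A = expm(J·dt)` and
`G = ∫₀^dt expm(Js) ds`, computed jointly from one augmented matrix
exponential (robust when `J` is singular).  Inputs and fluctuations are
held constant across each step.  Euler–Maruyama is available
(`method="euler"`) for cross-checks; the exact scheme removes step-size
artefacts from every stability claim.  Trajectories whose amplitude exceeds
`1e9` are truncated and flagged `diverged` rather than raising — unstable
systems are a studied behaviour here, not an error.

Default sampling interval is `dt = 2.16 s` (a typical fMRI repetition
time); all generators and the inversion accept any positive `dt`.

## Stability and the critical diffusion scaling

The Jacobian is input-independent (`J = P + σL`; LTI systems' stability
does not depend on driving inputs), with `J_ii = p_ii + σ d_i` and
`J_ij = p_ij − σ k_ij`.  Scaling `σ → ασ` gives the affine trace identity

    tr J′(α) = tr P + α σ Σ_i d_i

Since the trace is the sum of eigenvalues, `tr J > 0` guarantees an
unstable eigenvalue.  The trace-critical scaling

    α_trace = −tr P / (σ Σ d_i) = 1 − tr J / (σ Σ d_i)

is strictly `< 1` whenever `tr J > 0`: a trace-positive system can only be
rendered trace-negative by *reducing* diffusivity.  Note `α_trace` is
derived from the affine identity and can exceed 1 (even be negative) for
trace-negative inputs; the flag `trace_positive_input` records which regime
applies.  Trace negativity is necessary, not sufficient, for stability, so
a *spectral* critical scaling — the root of `max Re eig J′(α)` on a
bracketing interval, found by Brent's method to `1e-8` — is reported
alongside (`None` when no sign change is bracketed).  A zero leading real
part is classified as not stable (strict inequality).

## Variational inversion

The discretised model is linear-Gaussian, so inference uses that class's
exact machinery rather than generalised-coordinate filtering:

1. **Marginal likelihood.**  For a parameter vector θ (free entries of `P`,
   σ, free entries of `Q`, and two noise log-precisions `λ_x`, `λ_y`), the
   latent states are integrated out exactly by a Kalman filter.  The
   process-noise covariance is `exp(−λ_x)·G Gᵀ`: fluctuations enter the
   discrete states through the one-step input integral `G`, so their
   covariance is spatially structured, not isotropic.  (An isotropic noise
   model demonstrably biases the σ estimate.)
2. **Optimisation.**  The log-joint (likelihood + Gaussian priors) is
   maximised by L-BFGS with monotone line search; the iteration trace is
   recorded and convergence declared at ΔF < 1e-4 or 128 iterations.  The
   noise log-precisions start from data-driven guesses (observation noise
   at a fifth of the data scale); a jittered restart is triggered only if a
   fit never leaves the overflow-penalty plateau.
3. **Posterior.**  Laplace: the covariance is the inverse finite-difference
   Hessian at the optimum (symmetrised, eigenvalue floor `1e-8`).  Latent
   states come from Rauch–Tung–Striebel smoothing at the posterior mean.
4. **Free energy.**  `F = ⟨log p(d|θ)⟩_q − KL[q, p]` with the accuracy term
   evaluated to second order around the posterior mean; this decomposition
   coincides exactly with the Laplace log-evidence.  With all prior
   variances zero the posterior equals the prior, KL = 0, and F reduces to
   the accuracy term.

**Functional-connectivity priors.**  The free-parameter budget is kept
near a tenth of the number of time points.  All `N` self-couplings are free
(prior `N(−0.5, 1)` per second — weakly informative at the scale of one
over the repetition time); off-diagonal couplings are freed in symmetric
pairs ranked by the absolute Pearson correlation of the observed rows;
σ is free with prior `N(0.1, 1)`; `q` entries are freed only for designated
input-receiving regions; the log-precisions carry `N(3, 16)` hyperpriors.
All values are configurable; none are estimates of any published prior.

**σ parameterisation.**  Default is the natural scale.  A log-scale option
exists (posterior reported on the natural scale by the delta method), but
the natural scale is the default because Bayesian model reduction must pin
σ at exactly zero — a point outside the log-scale parameter space.
Positivity is then a property of the posterior when the data support
diffusion, not a hard constraint; on non-diffusive data the posterior mean
straddles zero as it should.

**Group averaging** is fixed-effects: precisions add, means are
precision-weighted, group free energy is the sum of member free energies.
It requires identical parameter sets, so multi-subject studies should use
a shared prior layout (e.g. diagonal-only budgets); correlation-ranked
pair selections differ between subjects.

## Bayesian model reduction

The evidence of a model differing from the fitted one only in its Gaussian
prior follows analytically from the full posterior.  The non-diffusive
model pins σ at 0 via a point-mass prior (variance `1e-12`); the routine
returns both free energies, the log Bayes factor `F(σ=0) − F(σ≠0)`, and
the reduced posterior over σ.  The reduction formula is verified in the
tests against a fully conjugate linear-Gaussian example where the evidence
is available in closed form (agreement to `1e-6`).

Because the Kalman likelihood is not exactly quadratic in θ, the analytic
reduction agrees with an actual refit (σ fixed at 0) only where the
Laplace quadratic is adequate — within half a nat on weak-diffusion
fixtures, but tens of nats when the posterior sits many standard
deviations from σ = 0.  This is a property of Laplace-based reduction in
general, not of this implementation; model selection (which model wins) is
unaffected in every tested configuration.

Model probabilities use the softmax of free energies, the standard
transform of log evidences and invariant to their arbitrary additive
constant.  A naive ratio `F₁/(F₁+F₂)` is available behind
`mode="ratio"` for comparison only; it is not shift-invariant and should
not be used for inference.

## Intervention protocol

The pre-ictal envelope (resampled to the simulation grid and min-max
normalised to [0, 1]) drives the seizure-prone target regions through `q`.
Mirrored stimulation supplies every non-target region with `β` times the
same envelope, `β` swept linearly over [0, 1] across (by default) 1000
forward models.  Stimulation never enters the Jacobian — eigenvalues are
bitwise identical across the sweep — so what it buys is "pseudo-stability":
with identical inputs everywhere, inter-regional gradients shrink and the
anti-smoothing diffusion term loses its lever.

The suppression metric is `max |x(t) − baseline|` over a configurable
window (terminal deviation as an option); "suppressed" means the metric
falls below `baseline_tolerance` (default 5 %) of its unstimulated value.
Sweeps default to noise-free forward models (`ω = 0`) for exact
reproducibility; with noise off, responses are exactly affine in β by LTI
superposition.

**Single-node ranking.**  The reference level is the suppression achieved
by full mirroring of all non-target nodes at gain 1; a candidate node
suppresses when its metric is within 5 % of that level.  Because the model
is linear and noise-free, the response at any gain `g` is
`r₀ + g·(r₁ − r₀)` from two simulations, so the minimum effective gain per
candidate is located exactly (fine grid plus bisection where the metric
decreases monotonically into the crossing; the grid value stands
otherwise).  Strengths are reported relative to the smallest (assigned 1,
ties broken by node order); candidates that never suppress within the gain
cap are N/A and sorted last.  "Stimulation strength" means the scalar gain
on the mirrored envelope; relative reporting makes the choice scale-free.

## Synthetic data

No subject recordings ship with the package, so the generators emulate the
study conditions:

* **Seizure network**: 8 nodes — bilateral frontal mid, frontal mid
  orbital, precuneus, thalamus.
* **Connectomes**: a connected Bernoulli topology (density 0.5 by
  default) whose edges carry log-normal weights mapped monotonically into
  [0.5, 1]; the matrix is symmetric, zero-diagonal, max 1.  Mapping the
  weights above the working threshold guarantees that the default 50 %
  binarization recovers exactly the drawn (connected) topology, so every
  synthetic subject has a usable diffusion channel.
* **Parameters**: negative self-couplings deepened until
  `max Re eig(P + σL) < −0.05` (stable regime), or with the designated
  nodes' self-coupling inflated until the leading real part sits in
  (0.01, 0.1) and loads chiefly on those nodes (`unstable_subset`).
* **Cohorts**: 15 + 15 subjects by default, `T = 296` samples at
  `dt = 2.16 s` (300 volumes minus 4 discarded), patients at
  `σ = 0.4`, controls at `σ = 0.1`, SNR 10 (std(latent)/std(noise) per
  region, geometric mean), fluctuation amplitude 0.05 with smoothness
  0.75 s — fast relative to the sampling interval, consistent with the
  adiabatic treatment of the fluctuations and keeping the white-noise
  filter model a good approximation.
* **Pre-ictal envelope**: low noisy baseline with a smoothly ramping
  amplitude-modulated ~3 Hz burst in the final third, min-max normalised.
  A surrogate for a frontal EEG envelope: only its role as a bounded,
  normalised, ramping driving signal matters downstream.

What the generators deliberately do not emulate: haemodynamic convolution,
physiological/scanner artefacts, anatomically faithful tractography
weights, or genuinely non-Markovian seizure dynamics.  Passing tests
demonstrate internal consistency of the method under its own assumptions —
parameter recovery, model selection, stabilisation — not performance on
real recordings.

The shipped intervention fixtures are *constructed*, not fitted:
`demo_unstable_fixture` places homogeneous self-coupling `−0.2/s` on a
complete 8-node graph with `σ = 0.0265` so that every non-uniform Laplacian
mode grows at ~0.012/s while the uniform mode is stable — the geometry in
which target-only input excites the instability and perfect mirroring
(uniform input) cannot; `star_fixture` couples exactly one candidate to
the driven target so the ranking's N/A behaviour is exercised.

## Problem sizes and numerical choices

Experiments in the tests and the acceptance script use: recovery at
`N = 4, T = 600, dt = 2.16, SNR 10` (20 replicates); model reduction on
20 + 20 subjects at the same conditions with σ ∈ {0, 0.4}; group
comparisons on 10 cohort seeds with 3 subjects per group at
`N = 8, T = 296`; suppression sweeps at `N = 8, T = 300` with 1000 forward
models.  The cohort runs use 3 subjects per group (the generator's default
is 15) — a deliberately compact design that still separates the groups
decisively.

Tolerances: Laplacian identity `1e-12`; trace zeroing `1e-9`; spectral
root `1e-8`; LTI superposition `1e-8`; Hessian steps `1e-3` (relative);
posterior eigenvalue floor `1e-8`; point-mass prior variance `1e-12`.
Ties at zero leading real part count as unstable; N/A ranking rows sort
last; equal minimum gains are ordered by node index.

## Known limitations

* The observation model is the identity; applying the method to real BOLD
  would require either accepting the haemodynamic response as part of the
  effective dynamics or adding a convolution model (out of scope).
* Laplace posteriors can misrepresent strongly skewed likelihoods; the
  BMR-vs-refit gap above is the visible symptom.
* The observation-noise log-precision is weakly identified when
  observation noise is much smaller than state noise (SNR 10 here); its
  posterior variance is honest but unstable across problem sizes.
* Group analysis is fixed-effects only; no random-effects or hierarchical
  (PEB-style) reduction.
* Single-node ranking exploits linearity; a nonlinear extension would need
  the per-candidate grid search to run full simulations.
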