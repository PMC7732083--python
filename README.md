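# diffdcm

Graph-diffusive dynamic causal modelling: a toolkit for simulating,
inverting and perturbing linear neuronal dynamics coupled through the
graph Laplacian of a structural connectome.

## The problem

Epileptic seizure activity spreads along structural brain connections.
Classic dynamic causal modelling (DCM) describes regional dynamics as
`dx/dt = f(x, v, θ)` but is blind to *how* activity disperses across the
network.  `diffdcm` implements a generalised neuronal state equation in
which states change both in time and along the edges of a structural graph:

    dx_i/dt = Σ_j p_ij x_j  +  σ Σ_j k_ij (x_i − x_j)  +  Σ_j q_ji v_j  +  ω_i

Here `P` is the intrinsic coupling matrix, `K` the binarized structural
adjacency matrix, `v` external driving inputs with extrinsic coupling `Q`,
and `ω` smooth stochastic fluctuations.  The structural term equals
`σ (L x)_i` with `L = D − K` the graph Laplacian, so the model is a
discretised drift–diffusion (Fokker–Planck-type) equation with diffusion
coefficient σ — and the Jacobian of the flow is simply `J = P + σL`.

Two consequences drive everything in this package:

1. **Stability lives in the Jacobian.**  Because the trace of
   `J′ = P + ασL` is affine in the diffusion scaling α, a trace-positive
   (unstable) system can only be made trace-negative by α < 1 — *reducing*
   diffusivity stabilises.
2. **Diffusivity can be lowered without touching the system.**  σ and `K`
   are intrinsic, but the activity gradients `x_i − x_j` are not: driving a
   seizure-prone region's neighbours with a copy of its own (pre-ictal)
   activity profile shrinks the gradients, starves the diffusion term, and
   suppresses the pathological response — while leaving the Jacobian's
   eigenvalues bit-for-bit unchanged ("pseudo-stability").

The toolkit is for computational neuroscientists who want to fit this model
to regional time series (variational Bayes with functional-connectivity
priors), compare diffusive against non-diffusive accounts by free energy
(Bayesian model reduction), analyse stability and critical diffusivity,
and prototype pre-emptive mirrored-stimulation protocols in silico.

## Worked example

```python
import numpy as np
from diffdcm import (binarize, build_fc_priors, critical_alpha, invert,
                     jacobian, reduce_sigma, simulate)
from diffdcm.dynamics import DrivingInput, FluctuationSpec
from diffdcm.synth import gen_connectome, gen_observations, gen_parameters

# a connected 4-region connectome, binarized at the 50% working threshold
graph = binarize(gen_connectome(4, edge_density=0.8, seed=1), 0.5)

# ground truth: stable dynamics with diffusion coefficient 0.3 /s
params = gen_parameters(graph, "stable", sigma_true=0.3, seed=101)

# ten minutes of BOLD-like data at TR = 2.16 s, SNR 10
fluct = FluctuationSpec(amplitude=0.05, smoothness=0.75, seed=201)
traj = simulate(params, graph, DrivingInput.zeros(1, 600, 2.16),
                np.zeros(4), fluct)
obs, _ = gen_observations(traj, snr=10.0, seed=301)

# invert: functional-connectivity priors, Kalman likelihood, Laplace posterior
priors = build_fc_priors(obs, graph, max_free=8)
post = invert(obs, None, graph, priors)
print(f"sigma posterior mean {post.sigma_posterior[0]:.3f} "
      f"(sd {post.sigma_posterior[1]**0.5:.3f}), F = {post.free_energy:.1f}")

# is the diffusion term worth its complexity?
red = reduce_sigma(post)
print(f"log BF (sigma=0 vs sigma!=0) = {red.log_bayes_factor:.1f}, "
      f"p(full) = {red.prob_full:.3f}")

# stability analysis of the fitted system
summ = jacobian(params, graph)
alpha = critical_alpha(params, graph)
print(f"max Re(lambda) = {summ.max_real:.3f}, trace = {summ.trace:.3f}, "
      f"alpha_trace = {alpha.alpha_trace:.3f}")
```

prints

```
sigma posterior mean 0.283 (sd 0.027), F = 3433.0
log BF (sigma=0 vs sigma!=0) = -53.2, p(full) = 1.000
max Re(lambda) = -0.237, trace = -2.870, alpha_trace = 2.595
```

The posterior mean recovers the generating σ = 0.3 within one posterior
standard deviation; the strongly negative log Bayes factor says the data
decisively favour the diffusive model; and since this system is stable
(trace < 0), the trace-critical scaling sits above 1 — diffusivity could
more than double before the trace turns positive.

A scikit-learn-style front end wraps the same machinery:

```python
from diffdcm import DiffusionDCM
est = DiffusionDCM(graph=graph, dt=2.16, max_free=8).fit(obs.y.T)
est.sigma_, est.free_energy_   # fitted attributes
```

For the stimulation protocol, `diffdcm.synth.demo_unstable_fixture()`
builds an unstable 8-node seizure network; `mirror_sweep` runs 1000 forward
models from zero stimulation (β = 0) to perfect mirroring (β = 1) and
`rank_single_node` ranks individual regions by the minimum gain that
suppresses the target response.  The command line mirrors the library:

```bash
diffdcm graph sweep --in W.tsv --out-dir sweeps/      # 18 thresholds, 10–95%
diffdcm synth cohort --config cohort.yaml --out-dir data/
diffdcm invert --series data/patient_00_bold.tsv --graph K.tsv --out post.json
diffdcm reduce --posterior post.json --out bmr.json
diffdcm intervene sweep --params params.json --graph K.tsv \
    --preictal eeg.tsv --targets 0,1 --n-models 1000 --out sweep.tsv
```

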