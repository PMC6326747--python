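# Methods

## Model

Each cortical region carries one state variable, the population-average
synaptic gating fraction `S_i ∈ [0, 1]`, evolving under the reduced
(Wong–Wang) mean-field dynamics

    dS_i = [ −S_i/τ_s + r (1 − S_i) H(x_i) ] dt + σ dW_i
    x_i  = w_i J S_i + G J Σ_j C_ij S_j + I_i
    H(x) = (a x − b) / (1 − exp(−d (a x − b)))

with fixed biophysical constants `J = 0.2609 nA`, `a = 270 n/C`,
`b = 108 Hz`, `d = 0.154 s`, `r = 0.641`, `τ_s = 0.1 s`. The model is
"relaxed" in that the recurrent strength `w_i` (dimensionless
self-excitation gain) and the subcortical input `I_i` (nA, constant
external drive) are free per region, while the global coupling `G` and the
noise amplitude `σ` are shared scalars. `C` is the structural connectome,
nonnegative, symmetric, zero diagonal, rescaled so its maximum entry is
0.2.

Neural activity drives a Balloon–Windkessel hemodynamic cascade per region
(vasodilatory signal `z`, inflow `f`, venous volume `v`, deoxyhemoglobin
`q`; constants κ = 0.65 s⁻¹, γ = 0.41 s⁻¹, τ = 0.98 s, α = 0.32, ρ = 0.34)
and the static BOLD observation

    BOLD = V0 [ k1 (1 − q) + k2 (1 − q/v) + k3 (1 − v) ]

with `V0 = 0.02`, `k1 = 4.3·(28.265·B0)·ρ·TE`, `k2 = ε·r0·ρ·TE`,
`k3 = 1 − ε` at 3 T defaults (`TE = 33.1 ms`, `r0 = 110 Hz`, `ε = 0.47`).
Renderings of this model differ in where the transit-time factor 1/τ
appears; we follow the canonical form (`df/dt = z`, with 1/τ on the
volume and deoxyhemoglobin equations only), under which
the baseline `(0, 1, 1, 1)` is an exact fixed point — an invariant the
tests enforce.

Both systems are Euler(-Maruyama) integrated at `dt = 10 ms`; the noise
term is discretized as `σ √dt N(0,1)` per region per step, and `S` is
clipped to `[0, 1]` after each step (the gating variable is a fraction;
noise can push it out). The default scan protocol is 16.4 min, first
2 min discarded, BOLD point-sampled (no anti-alias filter) at TR = 0.72 s,
giving 1200 frames. The firing-rate function is evaluated limit-safely:
for `|d·u| < 1e-8` the series value `(1/d)(1 + d·u/2)` is used, and for
`d·u < −500` the expression is rearranged as `u·e^{du}/(e^{du} − 1)` to
avoid overflow.

## Estimation

The `2n + 2` free parameters `θ = [w_1..w_n, I_1..I_n, G, σ]` are
estimated by maximizing the Pearson correlation between the vectorized
upper triangles of simulated and empirical FC. Parameters are
log-reparameterized, `φ = ln(θ/θ0)` with `θ0 = [0.5, 0.3, 1, 0.001]`,
which enforces positivity; `φ` carries a Gaussian prior `N(0, 0.25 I)`
(θ0 is thereby the prior *median* of θ, not its mean; we document rather
than "correct" this). Each outer iteration:

1. simulate FC at the current `φ` and form the residual
   `R = y_emp − y_sim` (length `n(n−1)/2`);
2. forward-difference Jacobian of the simulator in φ-space
   (default step 0.1) under common random numbers — the same simulation
   seed for the base point and all perturbed evaluations, without which
   realization noise swamps the differences;
3. M-step: Fisher-scoring update of the log error variance λ in
   `C_e = e^λ I` (initialized at −3, tolerance 1e-3, ≤ 64 inner
   iterations, |λ| capped at 50). With J = 0 the fixed point is
   `ln(RᵀR/m)`, which the tests verify against the iteration;
4. E-step: regularized Gauss–Newton step
   `Δφ = (Jᵀ C_e⁻¹ J + C_θ⁻¹)⁻¹ (Jᵀ C_e⁻¹ R − C_θ⁻¹ φ)` (shrinkage form
   pulling toward the prior mean; a "printed" variant with the opposite
   prior sign is selectable, as both conventions circulate for this
   update). The step direction is kept but its largest component is
   clipped to `max_step = 0.1` in log space: the linearization of a
   stochastic nonlinear simulator is only locally valid, and unclipped
   steps can exceed an e-fold in the parameters and make the outer loop
   bounce instead of converge. The clipping also acts as implicit
   averaging over successive noisy residuals.

Each iteration draws a fresh simulation seed (`base_seed + k`); λ is
re-initialized each iteration by default (configurable). The estimate is
selected by best simulated-vs-empirical correlation, but that correlation
is *re-measured* before selecting: each run keeps its top 10 iterates by
in-loop fit, and the pooled candidates from all restarts (restart 0
starts at the prior mean; others draw `φ_init ~ N(0, 0.25 I)`) are
re-scored against the empirical FC at a long evaluation protocol
(62 min, averaged over 6 seeds). Independent restarts typically converge
to distinct optima — and iterates within a run scatter around one
optimum — whose in-loop fit differences are smaller than a single scan's
FC sampling noise, so selecting on the raw in-loop fit is close to a
coin flip between genuinely different solutions; the re-scored
comparison is reliable at the cost of a few hundred extra simulations.

Optimization-time simulations default to the full-length standard
protocol. A shortened protocol is a supported configuration
(`fit_config`) and cuts cost roughly linearly, but it raises the
per-iteration objective noise and makes it more likely that a run
settles into a wrong-permutation optimum; the reported fit of the
selected estimate is in any case recomputed at the full-length
protocol.

## Synthetic data

`make_synthetic_sc` draws a modular random connectome: contiguous
modules, higher within-module connection probability, log-normal weights
(σ_ln = 1) with a 1.5× within-module boost, symmetrized, zero diagonal,
rescaled to maximum 0.2. Defaults (n = 10, 2 modules, density 0.75) are
deliberately dense and heavy-tailed: a consensus-averaged connectome over
a coarse parcellation is dense, and streamline-weight distributions are
log-normal. Identifiability of the recovery experiment depends on this:
on sparse, weakly heterogeneous connectomes the simulated FC tracks the
SC so closely that no estimator can beat the SC–FC baseline by a useful
margin.

`make_ground_truth_params` draws `w_i` and `I_i` as monotone gradients
across ROI index with 5% multiplicative jitter, with defaults
`w ∈ [0.2, 0.8]` and `I ∈ [0.25, 0.35]` (both centered on the prior
values), `G = 1`, `σ = 0.001`. The w-range is wide because the FC
carries usable information about `w_i` only where the recurrent loop
gain is non-negligible: the sensitivity of FC to `ln w` is far weaker
than its sensitivity to `ln I` in weakly recurrent regions and grows
steeply as `w` rises toward the strongly recurrent regime. A gradient
confined to a narrow band around 0.5 makes rank recovery of `w`
ill-posed for any method.

`make_synthetic_dataset` composes connectome, ground truth and the
forward model into a self-contained problem. The "empirical" FC is a
single forward simulation at the ground truth, by default at a long
(62 min) scan: empirical FC in real studies is averaged over runs and
subjects, so its sampling noise is far below that of one short scan. The
dataset records its three seeds and is bit-reproducible. The committed
regression fixture is the 10-region dataset with seeds (1, 2, 3).

What the generator does **not** emulate: head motion, physiological
noise, scanner drift, regional hemodynamic variability, subject
heterogeneity, and parcellation mismatch. Passing recovery tests
therefore show that the estimator inverts the model it assumes — not
that the model is correct for real fMRI.

## Parameter identifiability

`w_i` and `I_i` act on the FC largely through a single per-region
excitability combination: at synthetic ground truths, the w-columns of
the simulator Jacobian lie almost entirely inside the span of the I/G/σ
columns. The prior resolves this near-degeneracy: along the flat direction the
estimate stays at the minimum-prior-norm point, which allocates the
identified combination between `w_i` and `I_i` in proportion to their
local sensitivities. Since the w-sensitivity grows with `w`, the
allocation preserves the rank order of a broad ground-truth w gradient.
This is why the recovery experiment scores *rank* (Spearman) rather than
absolute error for `w`, and why absolute w-magnitudes below ~0.5 are
reported shrunk toward the prior.

## Numerical and design choices

- Upper-triangle vectorization is row-major `(i < j, sorted by (i, j))`,
  fixed so vectors are comparable across runs.
- Consensus SC averaging keeps an entry when the fraction of subjects
  with nonzero streamline counts is *at least* the threshold (strictly
  fewer → zero), and averages over the nonzero subjects only.
- FC matrices from multiple runs are averaged plainly (no Fisher-z);
  flagged here because conventions differ.
- Equal-area zoning solves the contiguous partition minimizing the sum of
  squared deviations of zone areas from the equal share, by dynamic
  programming (exact); ties in map values are broken by ROI label.
- Singular E-step systems get 1e-10 jitter with a warning; a failed
  simulation inside the inversion skips the iteration with a warning
  rather than aborting the run.
- `evaluate_params` with `n_sim = 1` reports SD = 0 by convention.

## Problem sizes

The committed recovery experiment uses the 10-region dataset with seeds
(1, 2, 3), 3 random restarts plus the prior-mean start, 64 outer
iterations, shrinkage mode, optimization at the full 16.4 min protocol —
about 6000 forward simulations, on the order of fifteen minutes on one
CPU with the numba integrators (a 10-region full-protocol simulation
takes ~0.15 s). σ is reported at its prior value: FC is a correlation
and is first-order invariant to a global rescaling of the noise
amplitude, so σ is essentially unidentifiable from FC and the prior
keeps it in place — a known property of this model family, not a bug.
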