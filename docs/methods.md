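# Methods

## Reservoir model

Neurons are analog leaky integrators with firing rate `r = tanh(x)`:

```
τ dx/dt = −α_l x + W_res r + W_inᵀ u + ξ
```

* `τ` — membrane time constant, ms. Default **40 ms**. (A literal reading
  of the source configuration would give 0.04 ms, which is stiff beyond
  usefulness at the 1 ms step; we interpret the value as 0.04 s, which
  yields the slow echo dynamics the model needs. Configurable.)
* `α_l` — leak coefficient, dimensionless, default **0.8**; it multiplies
  only the state-decay term, exactly as written above.
* `dt` — integration step, default **1 ms**; integration is Heun's
  predictor–corrector (globally second order; the suite verifies the 4×
  error drop when `dt` halves against the scalar closed form). Input and
  noise are held constant within a step.
* `ξ` — i.i.d. Gaussian current with standard deviation `noise_amp`
  (default 0: fully deterministic). The noise is an input current, not a
  Wiener increment, so its effect scales with `dt`; at the fixed default
  step this distinction is immaterial.
* Sign convention: the dynamics are the standard stable leaky-integrator
  form; an anti-leak (unstable) sign variant sometimes seen in print is
  not implemented.

Weights: `W_in` and `W_res` are standard normal; `W_res` is rescaled so
its spectral radius equals `r_s` (default **1.5**, the edge-of-chaos
regime; an alternative printed value of 1.4 is selectable via
configuration). Connectivity is 100% dense — since all connections are
trained, sparsity serves no purpose here. There are no output→reservoir
feedback connections. Readouts are linear, `y = W_outᵀ r`, one
`(n_res × 2)` block per simultaneous output pattern.

Phases: sensory (input applied, default 300 ms) then motor (input
detached — held at exactly zero — default 300 ms). The phase boundary is
carried explicitly on the signal container, never inferred.

## Separation and approximation metrics

A trajectory is compared after flattening the `n_res × T` rate matrix
neuron-major into one vector.

* Pairwise separation: time-averaged Euclidean distance between two state
  trajectories.
* SP = tr(S_b), with `S_b = Σ_i P(ω_i)(μ_i−μ_g)(μ_i−μ_g)ᵀ`; computed as
  `Σ_i P(ω_i)‖μ_i−μ_g‖²` without materializing the D×D matrix.
* tr(S_w) uses the unbiased per-class sample covariance; single-member
  classes contribute zero (keeps DR finite on tiny fixtures).
* DR = tr(S_b)/max(tr(S_w), ε), ε = 1e−12 — sweeps must stay numeric.
* Linear separation rank: count of singular values above
  `tol × σ_max`, default `tol = max(N, m)·eps`; `D = (R_S−R_G)/R_S`.
* Rank sampling time `t_0` is a parameter (default: final motor step).
* **SP window**: the attractor SP reported by the separation step is
  measured over the *full trial* (sensory + motor) by default, because
  that is the window over which the training errors are taken and the
  quantity the update drives; the chaotic motor phase alone gives a far
  noisier epoch-to-epoch readout. `window="motor"` restricts it.

## Training procedure

All three steps use the Sherman–Morrison running-inverse update
`P ← P − (Pv)(Pv)ᵀ/(1+vᵀPv)`, `P(0) = I/α` (`1/α` is the learning rate).

**Step 1 — separation.** Inverse learning rate `alpha_sep = 500`, with
`P` the running inverse correlation of the input vector (`n_in × n_in`;
`P` persists across epochs). Per epoch, classes are visited in sorted
order; the class template is played online and at every `delta_steps`-th
sensory step the update `W_in += γ·(P x_in) ⊗ clip(1 ⊘ e_ij)` is applied
sequentially for each other class `j` in sorted order, against attractors
frozen at the last epoch boundary (re-captured once per epoch). The
element-wise inverse error is unbounded as `e → 0`, so each component is
clipped at `inv_error_clip` (default **1e3**) — unavoidable for numerical
survival. Updates act only while the input is live (during the motor
phase `x_in = 0` and the update vanishes identically).

**Step 2 — innate/approximation.** Inverse learning rate
`alpha_approx = 100`, `P` is `n_res × n_res`. Training window is the
full trial by default (instances must reach the attractor that spans the
motor phase); a motor-only window is a config option.
`delta_steps` defaults to 1 (every integration step). The per-epoch
distance history uses the online dynamics of that epoch; the first entry
is a frozen-weights pre-training evaluation, so `history[-1] <
history[0]` measures net convergence.

**Step 3 — readout.** Same RLS form per output block
(`alpha_readout = 100` by default; parameter-recovery tests use 1.0 so
the ridge bias does not mask exact recovery). The blocks update
independently from shared reservoir rates; since `W_in`/`W_res` are
frozen here, instance rates are simulated once and cached across epochs.

Variable-length instances are aligned to the fixed sensory length by
linear time-rescaling (zero-padding is the config alternative). Epoch
defaults: 10 (separation), 20 (innate), 10 (readout).

Open choices resolved: the per-`j` updates of step 1 are applied
sequentially (not summed); the `α` constant of step 1 is `alpha_sep`;
step-1 `P` uses `v = x_in`.

## Synthetic data

The generator emulates the *shape* of cochleagram data, not audio: per
class, each of 39 channels is a sum of 3 random-phase sinusoids (0.5–3
cycles per 300-step pattern) under a bell-shaped channel envelope, peak
normalized to 0.8. Classes factor as word × attribute; the attribute
group applies a ±0.4 linear spectral tilt plus a small additive
signature, so the dual-readout task (draw the word shape and the
attribute mark) is exercisable. `class_similarity ∈ [0, 1)` blends every
word base toward one shared pattern (hard datasets differ only subtly —
the regime where separation training matters). Within-class variability:
scalar amplitude jitter (SD 0.1), smooth monotone time warp with fixed
endpoints (SD 0.05, mimicking utterance-duration variability), additive
white noise (SD 0.02). Every class/instance draws from its own seeded RNG
substream, so datasets are bit-reproducible.

What the generator does **not** emulate: cochlear filter dynamics,
onset/offset asymmetries, speaker identity structure beyond the binary
attribute, or non-stationary noise. Passing tests therefore demonstrate
the training algorithm's properties on smooth class-structured inputs,
not speech-recognition performance.

Targets are single-stroke shapes in the unit square, resampled uniformly
in arc length (closed curves drop the duplicate endpoint; open curves
keep both ends), to exactly one point per motor step.

## Evaluation

`d` is the mean over examples of the per-example *sum* over points of
squared coordinate error — no normalization by point count, so values
scale with the 300-point drawings and unit-square coordinates.
Recognizability is scored by nearest-template distance (the same `d` on
one example); ties break to the lowest label and are flagged. The 28×28
rasterizer (2-pixel margin, aspect-preserving normalization, Bresenham
line joins) is retained so an external image classifier can be plugged
in. The γ sweep retrains from scratch per γ with a shared seed and
records SP, DR and held-out `d`; the argmax-DR γ is the predictor of the
argmin-`d` γ.

## Desk-scale benchmark

The standard fixture uses 2 words × 2 attributes (4 classes), 39
channels, 300 ms + 300 ms phases at 1 ms, a 100-neuron reservoir, 6
training + 3 held-out instances per class, and γ = 0.02 with epochs
10/10/5 — sizes chosen so the full property suite (including 5-seed
paired comparisons and the 5-point γ sweep) runs on a single CPU in
minutes. `hard=True` sets `class_similarity = 0.85`. The γ grid
{0.001, 0.005, 0.02, 0.1, 0.5} spans under- to over-separation; at 0.5
the attractors become so oscillatory that approximation fails and the
error rises an order of magnitude — the expected non-monotonicity.

## Known limitations

* Separation SP is not monotone epoch-to-epoch (the chaotic reservoir
  reshuffles attractors as `W_in` moves); only the start-to-end trend is
  a contract, and one benchmark seed shows a slightly worse paired
  with/without-separation error.
* RLS keeps a dense `P`; memory is O(n_res²) and step 2 dominates run
  time, so large reservoirs (the default 2000 neurons) are feasible but
  slow on one core.
* The attribute factor is binary; richer attribute sets would need
  additional readout blocks and target sets.
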