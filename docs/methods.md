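# Methods

## The model

`subsetnet` simulates a recurrent network of `N` leaky integrate-and-fire
(LIF) neurons, half excitatory (E) and half inhibitory (I), in the *strongly
coupled balanced regime*, and trains the synaptic inputs of a selected
subset of neurons so that each follows a prescribed target time course.
The scientific question the machinery addresses: when only a subset of
neurons is trained, how does the trained activity spread to the untrained
neurons through the pre-existing, task-independent random connectivity?

### Membrane and synapses

Each neuron obeys forward-Euler LIF dynamics at `dt = 0.1 ms`,

    τ_m dv/dt = −v + u_bal + u_plas + X_bal + X_plas + X_stim ,

with `τ_m = 10 ms`, threshold `v_thr = 1`, reset `v_reset = 0`, no
refractory period.  Synaptic inputs are exponentially filtered spike
trains: static inputs with `τ_bal = 3 ms`, plastic inputs with
`τ_plas = 150 ms`.  Filters use the unit-integral jump convention (a spike
increments its filtered trace by `1/τ`), so a trace's time average equals
the presynaptic rate in spikes/ms; all internal rates are spikes/ms and
are converted to Hz only at reporting boundaries.

### Static connectivity and the balanced regime

Any ordered pair of neurons is connected by a static synapse independently
with probability `K_αβ/N_β` (`α, β ∈ {E, I}`, `K = pN`, default
`p = 0.2`).  The weight of every static synapse from population β to α is
`±g·J̄_αβ/√K_αβ` (excitatory positive, inhibitory negative; Dale's law
holds for static synapses).  The default weight magnitudes follow the
standard parametrization `J̄ = [[γ_E·J_E, γ_I·J_I], [J_E, J_I]]` with
`J_E = J_I = 2.0`, `γ_E = 0.15`, `γ_I = 0.75`, and constant external
drives `X_α = X̄_α·√K_I·g` with `X̄ = (0.12, 0.08)`.

Because single weights scale as `1/√K` while in-degrees scale as `K`, the
aggregate E and I inputs are each of order `√K` — far above threshold —
and cancel dynamically.  The population rates then solve the linear
*balanced equations*

    J̄_EE r_E − J̄_EI r_I + X̄_E ≈ 0
    J̄_IE r_E − J̄_II r_I + X̄_I ≈ 0 ,

which for the default table give `(r_E, r_I) = (0.05, 0.09)` spikes/ms
(50 and 90 Hz); `meanfield.solve_balance` computes this exactly.

### The efficacy normalization `g`

The factor `g` (`NetworkSpec.input_gain`) is the voltage integral a spike
contributes per unit of tabulated weight.  It is the one unit the model
definition leaves open: reading the synaptic drive in the membrane
equation as a current rather than a voltage rescales every input by up to
`τ_m/ms = 10`, and the balanced-equation rates are invariant to the
choice.  The dynamical regime is not: at `g = 1` the network is
mean-driven and fires almost clockwork-regularly, around `g ≈ 8` it is
fluctuation-driven with Poisson-like irregularity, and beyond that it
develops strong slow chaotic rate switching.  The irregularity of the
*trained* network additionally interacts with the online learning loop,
which destabilizes when the chaotic fluctuations are too strong.

Each shipped configuration fixes `g` once, using untrained- or
training-side anchors (never the reported outcome statistics): the
network should spike irregularly (ISI CV of order 1) and subset training
at desk scale should remain dynamically stable.  At the default
drives (sine-task configuration, rates 50/90 Hz) these pull in opposite
directions, and the configuration uses `g = 4.0` — the largest value at
which the full-network sine task trains stably at `N = 2000` — giving
untrained CV ≈ 0.3–0.5.  The cortical-rate configuration (4/11 Hz
operating point) satisfies both anchors simultaneously at `g = 8.0`
(untrained CV ≈ 0.8, stable training).  The consequences of the
sine-side compromise are discussed under *Limitations*.

### Plastic synapses

Each trained neuron receives `L` excitatory plus `L` inhibitory recurrent
plastic synapses (`L = c√K_E`; sine task `c = 2`, cortical-PSTH task
`c = 4` with an additional `3.65√K_E` feedforward synapses from external
Poisson units firing at OU-modulated rates around 5 Hz).  Same-population
presynaptic partners are drawn from the other *trained* neurons of that
population, opposite-population partners from the entire opposite
population; untrained neurons receive no plastic synapses.  The plastic
support is disjoint from the static support and fixed; only the values
change.  Initial plastic weights are fixed multiples of the realized
static weights (sine: `W_EE = W_IE = 2J_E`, `W_EI = W_II = J_I`;
cortical: `1·J_E` and `0.5·J_I`), excitatory entries positive and
inhibitory negative, placing the initial plastic input near the spike
threshold.  Trained plastic weights may change sign.

## Training

Each trained neuron `i` minimizes a private cost

    C_i = ½ Σ_t (f_i(t) − u_i(t) − X_i(t))²
        + ½ λ‖w_i‖² + ½ μ Σ_{α} (w_i·1_α)² ,

with ridge penalty `λ = 0.05` and ROWSUM penalty `μ = 8.0` on the
aggregate E and I plastic weights of the row.  The online solution is the
recursive-least-squares recursion with per-neuron inverse-correlation
matrix `P` initialized to `(λI + μΣ1_α1_αᵀ)⁻¹` (closed form via the
Woodbury identity).  At each update,

    e = f − u_bal − X_bal − w·r ,   w ← w + e·P r/(1 + rᵀP r) ,
    P ← P − P r rᵀ P/(1 + rᵀP r) ,

where `r` is the vector of filtered presynaptic spike trains (recurrent
then feedforward).  Updates fire every `learn_every` ms during the target
window (default 10 ms for the sine task, 20 ms for the 2 s cortical task);
`P` carries over across training iterations.  Iterations alternate trial
types when two stimulus conditions are trained.  Correctness is anchored
by a batch oracle: on fixed toy sequences the online weights reproduce the
direct regularized least-squares solution to 1e-8 relative error.

Error signals use the instantaneous filtered quantities; with `w₀ ≠ 0`
(the initialization above) the recursion carries a transient that decays
along visited regressor directions — the batch-equivalence oracle
initializes at zero where the equivalence is exact.

## Targets

*Sine task*: `f_i(t) = a·sin(2πft + φ_i) + b_i` with random phases,
`a = 0.5` in tabulated input units (internally `a·g`), and `b_i` the
neuron's measured mean input in the untrained network; 1 Hz on a 1 s
window for the main demonstration, 2 Hz for the spread-mechanism analysis.

*Cortical (ALM-like) task*: firing-rate PSTHs are converted to input
targets by inverting the LIF transfer function (Ricciardi)

    φ(m, σ) = τ_m⁻¹ [√π ∫_{(v_r−m)/σ}^{(v_θ−m)/σ} erfcx(−w) dw]⁻¹ ,

evaluated with adaptive quadrature on the scaled complementary error
function (no overflow; deep-subthreshold inputs return 0) and inverted via
a dense monotone interpolant with a 0.1 Hz rate floor.

The fluctuation entering the inversion is *self-calibrated*: the raw SD
of the filtered static input overstates the noise the threshold mechanism
sees (the membrane filters the 3 ms-correlated input once more, a
`√(2τ_bal/(τ_bal+τ_m))` ≈ 0.68 correction), and at desk-scale in-degrees
the diffusion approximation carries an additional shot-noise bias.  The
package therefore fits `φ(m − δ, σ)` to the untrained network's own
per-neuron (mean input, rate) scatter (`targets.fit_transfer_to_rates`)
and uses `(σ, δ)` for the inversion; with this calibration the realized
trained rates land within ≈ 15% of the requested rates at `N = 800`,
versus an order of magnitude low with the raw SD.

### The synthetic PSTH generator

Real recordings (trial-averaged ALM PSTHs) are emulated by a parametric
generator: baseline rates are log-normal (mean 4.2 Hz for the
pyramidal-like spec, 11.0 Hz for the fast-spiking-like spec, log-SD 1.0 —
the data's means; the shape is a package default), and each neuron's
centered PSTH is a Gaussian-loading combination of `D = 9` orthonormal
temporal modes over the 2 s delay window (20 ms bins): a normalized ramp
followed by QR-orthogonalized cosines.  Per-mode variance shares are
`[0.41, 0.105, 0.085, 0.075, 0.070, 0.065, 0.065, 0.063, 0.062]`, i.e.
a dominant ramp and a slow monotone tail with the first six modes
carrying ≈ 81% of the centered variance, matching the low-dimensionality
of delay-period cortical activity.  Loading scale is proportional to the
baseline rate (coupling exponent 1), with total modulation SD `0.5·rate`
at multiplier 1; the fast-spiking spec uses uniformly 1.5× stronger
loadings, reflecting the stronger rate modulation of fast-spiking
neurons.  Lick-right/lick-left pairs are generated independently, sorted
by mean rate and paired rank-wise; zero-mean Gaussian noise with SD equal
to the pair's mean-rate difference is added to the lick-left member,
injecting choice selectivity whose preferred side is symmetric across
realizations.

What the generator does *not* emulate: empirical loading distributions
(ours are Gaussian by construction), non-stationarities across the delay,
correlations between modes conditioned on rate beyond the single coupling
exponent, and any sampling structure of real recordings.  Tests passing
on synthetic targets therefore validate the machinery and the model's
internal predictions, not agreement with any particular data set.

Targets are assigned to model neurons by rate: targets in descending-rate
order each take the unassigned model neuron of the trained pool with the
closest untrained-network firing rate.

## Analyses

* PSTHs: 20 ms bins, trial averaged, boxcar-smoothed over 300 ms
  (truncated at edges); mode/projection analyses use 1 ms bins with a
  200 ms boxcar, following the two conventions used for data PSTHs and
  for coding-mode trajectories respectively.
* PCA: per-neuron time-mean removed; components are temporal profiles
  (eigenvectors of R·Rᵀ); variance fractions λ_k²/Σλ_i² with λ the
  singular values; component signs fixed so the largest-magnitude bin is
  positive.
* Transferred activity: fraction of centered variance of the untrained
  subnetwork's PSTHs captured by its first six PCs (optionally by fixed
  reference PCs); PC fidelity: per-mode |correlation| between trained and
  untrained PC profiles.
* Shared variance: SVD of the per-pair correlation matrix between two
  populations' PSTHs; shared components are the centered matrices
  projected on the singular vectors, with per-side variance fractions.
* Choice selectivity: `(r_R − r_L)/mean rate` per neuron; scalar =
  time-average; zero-rate neurons excluded.
* Choice mode: normalized R−L difference of trial-averaged rates in the
  last 1 s of the delay, `‖C‖ = 1/√N`; homogeneous mode: population mean.
  Trials with fewer than 10 recorded neurons are excluded.
* Perturbation recovery: per-bin two-sided t-tests between perturbed and
  unperturbed projections (no multiple-comparison correction); a session
  enters the analysis if ≥ 10% of the bins inside the perturbation
  window differ significantly.  The recovery time is the last bin of the
  contiguous significant run carrying the perturbation response — a
  per-bin α-level test produces isolated false positives late in the
  window, and the contiguous-run rule is this package's operational
  version of the (ambiguously specified) derivative criterion for
  ignoring them.  An exponential decay rate is fitted to the
  |Δprojection| curve.  The model perturbation re-injects the opposite
  trial type's stimulus during a 400 ms window mid-delay; on the delay
  axis t ∈ [−2, 0] s this is [−1.6, −1.2] s with the recovery search on
  [−1.2, 0] s.
* Spiking statistics: Fano factor = var/mean of per-trial counts in the
  counting window (default: the full target window), averaged over
  neurons with mean count ≥ 1; ISI CV per neuron; normality diagnostics
  of log rates.
* Gaussian loading test: Lilliefors-corrected KS test of standardized
  PC loadings.

## Mean-field spread predictions

Writing the centered trained rates (spikes/ms) as `δφ = U√λVᵀ`, the
aggregate static input from the trained population to an untrained neuron
has per-mode loadings that are Gaussian with mean zero and variance
`g²J̄²λ_n/N_pre` (the normalization by the presynaptic pool size is
carried explicitly; it is absorbed into the singular-vector convention in
the usual statement of this result).  The across-neuron variance of the
time-mean input is the quenched disorder `q = (gJ̄)²·[⟨φ⟩²]`.
Predictions tested in simulation: (1) Gaussianity of the loadings;
(2) vanishing transfer under `1/K` (weak) coupling; (3) transfer fidelity
increasing with the mode's singular value; (4) choice-selectivity spread
with variance set by the R−L differences of the quenched disorder and the
ramp-mode loadings (`A`, `B` of `selectivity_spread_prediction`).

The weak-coupling control keeps the adjacency and rescales weights to
`gJ̄/K`; each neuron receives the centered mean input it had in the strong
untrained network as a constant (preserving the heterogeneous operating
points), a uniform drive `X_weak = 0.35` with population factors
(1.5, 0.8), and injected white noise whose amplitude
`σ_α·√(2τ_bal/((τ_bal+τ_m)τ_m))` matches the membrane-potential variance
the strong network's measured input fluctuations would produce.

## Problem sizes

Package defaults are desk-sized and were chosen once as the standard
study conditions: sine task `N = 2000`, `K = 400`, all neurons trained,
100 iterations, 30 evaluation trials; cortical task `N = 800`, `K = 160`,
40 training iterations, 40–100 evaluation trials; sweeps over trained
fractions {0.4, 0.7, 1.0} with 3 seeds.  The construction is identical at
full scale (`N = 30000`, `K = 6000`); only memory and time grow.

## Known limitations

* The efficacy normalization cannot simultaneously reproduce
  Poisson-level irregularity in the untrained network and stable subset
  training at desk scale; the default favors trainability.  Untrained-
  network ISI CV at the default is ≈ 0.3–0.5, below the ≈ 1 of the
  asymptotic balanced regime, and trained-network trial-to-trial count
  variability (Fano ≈ 0.9–1) sits at the low end of the super-Poisson
  range expected at full scale.
* At desk-scale in-degrees the diffusion approximation behind the
  transfer function is biased; the two-parameter empirical calibration
  absorbs most but not all of it (realized trained rates ≈ 15% low).
* The trained activity's fast temporal modes are compressed: with a
  150 ms plastic filter and desk-scale plastic in-degrees, the
  regression's per-mode gain falls below one for modes faster than a few
  hundred ms, so the realized trained PSTHs are more ramp-dominated (and
  lower-dimensional) than their targets.  Spread metrics are
  correspondingly closer to their ceiling than at full scale.
* Trial-to-trial variability arises only from initial membrane potentials
  and stochastic external-unit spikes; stimulus traces are frozen across
  trials of a type.
* The ROWSUM penalty keeps the aggregate plastic weights far closer to
  their initial values than an unpenalized fit, but at the default
  normalization the inhibitory aggregate still drifts by ~25% over 100
  iterations of the sine task (the excitatory one by ~5%); exact
  conservation would require a stiffer penalty than the default μ.
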