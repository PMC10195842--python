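# subsetnet

Subset training of balanced excitatory–inhibitory spiking networks, and
analysis of how trained activity spreads to untrained neurons through
task-independent strong synapses.

## The scientific problem

During learned behaviors, task-related activity appears across far more
cortical neurons than plausibly undergo synaptic reorganization.
`subsetnet` implements a circuit-level explanation: in a strongly coupled
spiking network operating in the *balanced regime* — random E/I
connectivity with mean in-degree K and synaptic weights scaling as
J̄/√K — training the synaptic inputs of only a *subset* of neurons is
enough for the trained activity patterns to spread to the untrained rest
of the network, because every untrained neuron receives a random O(1)
projection of the trained population's activity through the pre-existing
strong synapses.

The package provides, as a library plus a `subsetnet` command-line tool:

* a leaky integrate-and-fire network simulator (forward Euler, 0.1 ms
  steps) with static balanced connectivity, sparse *plastic* synapses
  whose support is disjoint from the static one, frozen
  Ornstein–Uhlenbeck trigger stimuli, and external Poisson units;
* FORCE-style online training: each trained neuron's plastic weight
  vector w follows the recursive-least-squares recursion for the private
  cost ½Σ(f − u − X)² + ½λ‖w‖² + ½μΣ_α(w·1_α)², where the μ (ROWSUM)
  term keeps the aggregate E and I plastic weights of each row fixed so
  training cannot push the network out of the balanced regime;
* target generation: random-phase sinusoids, and cortical-like
  (ALM-inspired) synthetic PSTHs — log-normal rates, a dominant ramping
  mode plus eight weaker orthogonal modes, paired lick-right/lick-left
  conditions — converted to synaptic input targets by inverting the LIF
  transfer function φ(m, σ) (Ricciardi), with the effective σ
  self-calibrated on the untrained network;
* population analyses: PSTHs, PCA, transferred activity (six-PC variance
  of the untrained subnetwork), PC fidelity, shared variance, choice
  selectivity, choice/homogeneous-mode projections, perturbation
  recovery times, Fano factor and ISI CV;
* mean-field theory: the balanced equations, quenched disorder, the
  Gaussian random-projection prediction for the per-mode input loadings
  of untrained neurons, and the matched weak-coupling (1/K) control
  network.

See `docs/methods.md` for the model, parameter choices, and limitations.

## Worked example

Train every neuron of a desk-scale balanced network (N = 2000, K = 400)
to follow random-phase 1 Hz sine input targets, then measure how well the
total synaptic inputs track the targets and how variable the spiking is
across trials:

```python
from subsetnet.experiments import sine_experiment

r = sine_experiment(n=2000, n_iter=100, n_trials=30, seed=1)
print(f"median input/target correlation: {r['median_corr']:.3f}")
print(f"population Fano factor:          {r['stats'].fano:.2f}")
print(f"2-PC variance of trained PSTHs:  {100*r['pca'].cumulative_variance(2):.1f}%")
```

prints (seed 1, ~3 minutes on one core):

```
median input/target correlation: 0.985
population Fano factor:          0.93
2-PC variance of trained PSTHs:  97.4%
```

The correlation says the trained inputs follow their sine targets almost
perfectly; the Fano factor near one says the spiking remains strongly
variable across trials rather than clockwork-repeatable; and the two
dominant PCs are the sine/cosine Fourier pair, confirming the trained
activity occupies the intended two-dimensional subspace.

The same pipelines run from the shell:

```bash
subsetnet run sine_demo --seed 1 --out artifacts/
subsetnet run ei_transfer_sweep --seed 1 --set n=600 --set n_iter=20
```

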