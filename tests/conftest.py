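import numpy as np
import pytest

from subsetnet.params import (NeuronParams, PopulationLayout, SynapseParams,
                              NetworkSpec)


@pytest.fixture(scope="session")
def tiny_spec():
    """40-neuron network with K = 8 per block, used by connectivity tests."""
    layout = PopulationLayout(20, 20)
    syn = SynapseParams(tau_bal=3.0, tau_plas=150.0,
                        jbar=np.array([[0.3, 1.5], [2.0, 2.0]]),
                        kbar=np.full((2, 2), 8.0))
    return NetworkSpec(neuron=NeuronParams(), layout=layout, syn=syn,
                       xbar=np.array([0.12, 0.08]), input_gain=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sine_run_full():
    """The standard desk-scale sine-training run (N = 2000, K = 400,
    100 iterations, 30 evaluation trials), shared by the end-to-end
    tests.  Takes a few minutes; built once per session."""
    from subsetnet.experiments import sine_experiment
    from subsetnet.network import subseed

    return sine_experiment(n=2000, n_iter=100, freq_hz=1.0,
                           t_target_ms=1000.0, n_trials=30,
                           seed=subseed(20260927, 31))
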