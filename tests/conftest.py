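import numpy as np
import pytest

from loopshift import (LoopSystemSpec, make_reference_states,
                       simulate_loop_ensemble)


@pytest.fixture(scope="session")
def quick_spec():
    return LoopSystemSpec(n_replicas=3, n_frames=400, seed=11)


@pytest.fixture(scope="session")
def quick_system(quick_spec):
    """A small simulated system shared across tests: (spec, refs, top,
    ensemble, true_labels)."""
    refs, top = make_reference_states(quick_spec)
    ens, truth = simulate_loop_ensemble(quick_spec, refs, top)
    return quick_spec, refs, top, ens, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
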