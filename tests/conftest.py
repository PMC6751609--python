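import dataclasses

import numpy as np
import pytest

import myonet as mn


@pytest.fixture(scope="session")
def hc_recording():
    """One shortened healthy-control subject (20 gait cycles)."""
    cfg = dataclasses.replace(mn.preset("HC"), n_cycles=20, seed=11)
    return mn.generate_emg(cfg)


@pytest.fixture(scope="session")
def hc_envelopes(hc_recording):
    return mn.make_envelopes(hc_recording)


@pytest.fixture(scope="session")
def dm1_recording():
    cfg = dataclasses.replace(mn.preset("DM1"), n_cycles=16, seed=12)
    return mn.generate_emg(cfg)


@pytest.fixture(scope="session")
def dm1_envelopes(dm1_recording):
    return mn.make_envelopes(dm1_recording)


def random_muscle_graph(rng: np.random.Generator, directed: bool,
                        density: float = 0.8) -> mn.MuscleGraph:
    """Random weighted 8-node graph for oracle comparisons."""
    n = 8
    a = rng.uniform(0.1, 1.0, size=(n, n))
    mask = rng.random((n, n)) < density
    a = np.where(mask, a, 0.0)
    np.fill_diagonal(a, 0.0)
    if not directed:
        a = np.triu(a, 1)
        a = a + a.T
    return mn.MuscleGraph(node_labels=mn.MUSCLES, adjacency=a,
                          directed=directed)
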