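import pytest

from bgsim.network import NetworkSpec, build_graph


@pytest.fixture(scope="session")
def graph():
    """Full-scale (S = 300) circuit graph shared across the session."""
    return build_graph(NetworkSpec(), seed=1)


@pytest.fixture(scope="session")
def tonic_record(graph):
    """One 3-s tonic-mode run at baseline dopamine."""
    from bgsim.engine import experiment_tonic
    return experiment_tonic(graph, seed=5, duration=3000.0)


@pytest.fixture(scope="session")
def phasic_record(graph):
    """One 3-s run with channel 0 phasically driven at 10 spikes/s."""
    from bgsim.engine import experiment_phasic
    return experiment_phasic(graph, seed=20, duration=3000.0)
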