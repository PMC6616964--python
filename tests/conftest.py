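import pytest

from tractchange.synthetic import SyntheticSpec, default_regimes, generate_region


@pytest.fixture(scope="session")
def demo():
    """Frozen 200-tract demo region: zero-noise panel with planted truth.

    Session-scoped so classifier, comparison and CLI tests share one
    deterministic panel (seed 7) without regenerating it.
    """
    panel, truth = generate_region(SyntheticSpec(n_tracts=200, seed=7), default_regimes(0.0))
    return panel, truth


@pytest.fixture(scope="session")
def demo_panel(demo):
    return demo[0]


@pytest.fixture(scope="session")
def demo_truth(demo):
    return demo[1]
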