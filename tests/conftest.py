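import numpy as np
import pytest

from cosel import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """A reproducible 15-expert panel over three outcomes of graded importance."""
    spec = synth.PanelSpec(
        outcome_mu={"treatment_failure": 8.4, "cat_score": 6.8, "wbcc": 5.1},
        outcome_sigma=1.2,
        seed=7,
    )
    return synth.gen_panel(spec)


@pytest.fixture
def small_md_network():
    """A connected 3-treatment continuous network with known effects."""
    spec = synth.NetworkSpec(
        d={"CI": 0.0, "A": 1.0, "B": 2.0},
        comparisons=(("A", "CI"), ("B", "CI"), ("A", "B")),
        tau=0.2,
        trials_per_comparison=3,
        n_per_arm=100,
        seed=42,
    )
    return synth.gen_network(spec)
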