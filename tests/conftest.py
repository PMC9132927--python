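import numpy as np
import pytest

from mixtoxpred import FittedDRC, MixtureComponent, MixtureSpec


@pytest.fixture
def logit_pair():
    """Two full-agonist Logit components with distinct potencies (uM)."""
    a = MixtureComponent("A", 0.4, cas="1-11-1", mw=100.0,
                         drc=FittedDRC("Logit", (0.5, 2.0), "uM"))
    b = MixtureComponent("B", 0.6, cas="2-22-2", mw=250.0,
                         drc=FittedDRC("Hill", (3.0, 1.5), "uM"))
    return MixtureSpec((a, b), output_unit="uM")


@pytest.fixture
def partial_trio():
    """Three slope-1 Hill partial agonists (the GCA-relevant family)."""
    comps = tuple(
        MixtureComponent(f"P{i}", 1 / 3, cas=f"{i}-00-{i}", mw=300.0 + 50 * i,
                         drc=FittedDRC("Hill_three", (k, 1.0, g), "uM"))
        for i, (k, g) in enumerate([(5.0, 0.55), (12.0, 0.7), (25.0, 0.8)], start=1)
    )
    return MixtureSpec(comps, output_unit="uM")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
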