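import numpy as np
import pytest

from mbfd import (
    EffectParameters,
    VarianceComponents,
    build_standard_design,
    randomize,
    simulate_trial,
)

ADDITIVE = EffectParameters(beta_a=0.8, beta_b=0.8, beta_c=1.6)
INTERACTION = EffectParameters(beta_a=0.8, beta_b=0.8, beta_c=2.0)


@pytest.fixture(scope="session")
def standard_design():
    return build_standard_design()


def make_trial(seed, n=30, icc=0.10, effects=ADDITIVE, design=None, **kw):
    """One simulated standard-design trial with a deterministic seed."""
    design = design or build_standard_design()
    alloc = randomize(design, n, seed)
    return simulate_trial(
        design, alloc, effects, VarianceComponents.from_icc(icc), seed + 1, **kw
    )


@pytest.fixture(scope="session")
def small_trial(standard_design):
    """One N=30 additive-effects dataset reused across fit tests."""
    return make_trial(42, n=30, icc=0.10)


@pytest.fixture(scope="session")
def trial_batch(standard_design):
    """Twenty deterministic small datasets with varied ICC and effects."""
    out = []
    for k in range(20):
        icc = (0.0, 0.05, 0.10, 0.30)[k % 4]
        eff = (ADDITIVE, INTERACTION, EffectParameters())[k % 3]
        out.append(make_trial(1000 + k, n=30, icc=icc, effects=eff))
    return out
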