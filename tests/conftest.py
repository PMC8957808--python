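"""Shared fixtures: shipped circuits and (expensive) protocol runs.

The default-protocol runs are session-scoped — the simulator is
deterministic, so every test sees the identical result object.
"""

import numpy as np
import pytest
from hypothesis import settings

import socialfear as sf

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basic_spec():
    return sf.build_basic_model()


@pytest.fixture(scope="session")
def alt_spec():
    return sf.build_alternative_model()


@pytest.fixture(scope="session")
def basic_result(basic_spec):
    return sf.run_protocol(basic_spec)


@pytest.fixture(scope="session")
def alt_result(alt_spec):
    return sf.run_protocol(alt_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)


def random_valid_spec(rng, n_units=6, plastic_fraction=0.5):
    """A small random network satisfying all structural invariants.

    Used by the parameter-free property tests; the simulator itself is
    seedless — randomness lives only in the test harness.
    """
    names = [f"u{i}" for i in range(n_units)]
    signs = ["+" if rng.random() < 0.7 else "-" for _ in names]
    units = [
        sf.UnitSpec(name=n, area="rnd", sign=s) for n, s in zip(names, signs)
    ]
    conns = []
    for i, pre in enumerate(names):
        for j, post in enumerate(names):
            if i == j or rng.random() < 0.5:
                continue
            mag = rng.uniform(0.1, 1.5)
            w = mag if signs[i] == "+" else -mag
            plastic = signs[i] == "+" and rng.random() < plastic_fraction
            bounds = None
            if plastic:
                lo = rng.uniform(0.0, mag)
                hi = mag + rng.uniform(0.0, 1.0)
                bounds = (lo, hi)
            conns.append(
                sf.ConnectionSpec(
                    pre=pre, post=post, weight=w, plastic=plastic, bounds=bounds
                )
            )
    channels = {"drive": {names[0]: 1.0, names[1]: rng.uniform(0.2, 1.0)}}
    spec = sf.NetworkSpec(
        units=units,
        connections=conns,
        input_channels=channels,
        plasticity=sf.PlasticityParams(alpha=0.003, theta=0.5),
        name="random",
    )
    assert sf.validate_spec(spec) == []
    return spec
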