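import pytest

from dualcycle.network import NetworkOptions, build_dual_cycle_network
from dualcycle.synth import (
    TraceSpec,
    generate_landscape,
    generate_trace,
    two_channel_spec,
)


@pytest.fixture
def two_channel_network():
    """Minimal Curtin-Hammett benchmark network (ddG = 1.447 kcal/mol)."""
    landscape = generate_landscape(two_channel_spec(1.447))
    return build_dual_cycle_network(landscape, NetworkOptions())


@pytest.fixture
def noiseless_trace():
    """Exact exponential 3-signal trace, k = 1e-3 s^-1."""
    return generate_trace(TraceSpec(k_true=1e-3, noise_sd=0.0, seed=0))
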