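import dataclasses

import pytest

import hvprime as hv


@pytest.fixture
def sym_solution():
    """Symmetric pH 6.0 at 22 degC (the standard recording condition)."""
    return hv.SolutionPair(pH_i=6.0, pH_o=6.0)


@pytest.fixture
def quiet_params():
    """Noiseless, leak-free, fully available spruce-like channel."""
    return dataclasses.replace(
        hv.preset("PsHv1_like"),
        noise_sd_pA=0.0,
        g_leak_nS=0.0,
        silent_availability=1.0,
    )


@pytest.fixture
def tail_recording(quiet_params, sym_solution):
    """Noiseless tail-current step family for round-trip G-V tests."""
    proto = hv.make_protocol("tail_family")
    return hv.simulate_recording(quiet_params, proto, sym_solution)
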