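import numpy as np
import pytest

import oncocea as oc


@pytest.fixture(scope="session")
def base_pipeline():
    """One full base-case run on the synthetic preset, shared across tests."""
    return oc.run_pipeline(seed=1)


@pytest.fixture(scope="session")
def consistent_funcs():
    """A survival-function set whose three curves are mutually consistent
    with the four-state chain: PFS empties quickly, second progressions
    clearly precede deaths, so state occupancies track the curves."""

    def P(t):
        return np.exp(-((np.asarray(t, float) / 2.0) ** 1.5))

    def P2(t):
        return np.exp(-((np.asarray(t, float) / 24.0) ** 1.8))

    def S(t):
        return np.exp(-((np.asarray(t, float) / 40.0) ** 1.8))

    return oc.SurvivalFunctionSet(P=P, P2=P2, S=S, arm="consistent")
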