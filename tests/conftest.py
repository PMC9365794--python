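import numpy as np
import pytest

import synaptoprobe as sp


@pytest.fixture(scope="session")
def epsc_recording():
    """One 60 s EPSC recording at the study conditions, with ground truth."""
    return sp.gen_epsc_trace(rate=1.0, amp_mean=20.0, amp_cv=0.3, tau=2.3,
                             noise_sd=2.0, duration=60.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_cc():
    """Noiseless 35-step current-clamp family."""
    return sp.gen_current_clamp(seed=0)


@pytest.fixture()
def single_event_trace():
    """Noiseless trace with one 20 pA, τ = 2 ms EPSC at 200 ms."""
    from synaptoprobe.synth import epsc_kernel
    dt = 0.05
    x = np.zeros(20000)
    k = epsc_kernel(2.0, dt)
    x[4000:4000 + k.size] += 20.0 * k
    return sp.Trace(x, dt, "current")
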