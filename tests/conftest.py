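import numpy as np
import pytest

from gqfret.analysis import FretrTrace, NormalizedTrace


def biexp_trace(tau1, tau2, frac1=0.5, hz=10.0, baseline_s=10.0,
                response_s=15.0, washout_s=0.0, direction="decrease"):
    """Additive biexponential test trace on the analysis' normalized scale.

    Starts at 1, relaxes toward 0 (decrease) or 2 (increase) with two
    exponential components of fractional amplitudes (frac1, 1 - frac1).
    """
    duration = baseline_s + response_s + washout_s
    t = np.arange(int(round(duration * hz)) + 1) / hz
    rel = np.clip(t - baseline_s, 0.0, None)
    decay = frac1 * np.exp(-rel / tau1) + (1 - frac1) * np.exp(-rel / tau2)
    on = t >= baseline_s
    value = np.ones_like(t)
    sign = -1.0 if direction == "decrease" else 1.0
    value[on] = 1.0 + sign * (1.0 - decay[on])
    return NormalizedTrace(t=t, value=value, direction=direction,
                           t_on=baseline_s, t_off=baseline_s + response_s)


@pytest.fixture
def wt_biexp():
    return biexp_trace(0.2, 2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
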