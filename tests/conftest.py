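import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_dfa(x, scales, order=2):
    """Brute-force DFA reference: explicit loop over windows with plain
    polynomial least squares; windows from both ends of the profile."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    out = []
    for s in scales:
        m = len(y) // s
        msq = []
        for block in (y[: m * s].reshape(m, s),
                      y[len(y) - m * s:].reshape(m, s)):
            for seg in block:
                t = np.arange(s, dtype=float)
                coef = np.polyfit(t, seg, order)
                resid = seg - np.polyval(coef, t)
                msq.append(np.mean(resid**2))
        out.append(np.sqrt(np.mean(msq)))
    return np.array(out)


@pytest.fixture
def naive_dfa_fn():
    return naive_dfa
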