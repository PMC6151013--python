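import numpy as np
import pytest

from diauxie import SolverSettings, Trajectory, make_batch, make_variant, simulate


@pytest.fixture
def fast_settings():
    """Moderate-accuracy settings for tests that only need qualitative output."""
    return SolverSettings(rtol=1e-7, atol=1e-9, n_out=801)


@pytest.fixture(scope="session")
def base_trajectory():
    return simulate(make_variant("base"), make_batch(t_end=50.0))


def synthetic_trajectory(t, r1, r2, b, s1_0=1.0, s2_0=1.0, w1=1.0, w2=1.0):
    """Hand-built trajectory carrying only what the index needs."""
    s1 = s1_0 - np.concatenate([[0.0], np.cumsum(np.diff(t) * 0.5 *
                                                 (r1[1:] + r1[:-1]) *
                                                 0.5 * (b[1:] + b[:-1]))])
    s2 = s2_0 - np.concatenate([[0.0], np.cumsum(np.diff(t) * 0.5 *
                                                 (r2[1:] + r2[:-1]) *
                                                 0.5 * (b[1:] + b[:-1]))])
    states = {"s1": np.maximum(s1, 0.0), "s2": np.maximum(s2, 0.0), "b": b}
    rates = {"r_s1": r1, "r_s2": r2}
    return Trajectory(t=t, states=states, rates=rates,
                      meta={"initial": {"s1": s1_0, "s2": s2_0},
                            "core": {"w1": w1, "w2": w2}})
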