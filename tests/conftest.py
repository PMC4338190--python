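import numpy as np
import pytest

import critslow as cs
from critslow.markers import MarkerSample, MarkerSeries


@pytest.fixture(scope="session")
def sn_trajectory():
    """Default saddle-node study run (y0=1.6, eps=0.001, pulses 0.1 per 60)."""
    return cs.simulate_saddle_node(cs.SDEConfig.saddle_node(seed=0))


@pytest.fixture(scope="session")
def sn_markers(sn_trajectory):
    return cs.compute_markers(sn_trajectory)


@pytest.fixture(scope="session")
def hopf_trajectory():
    return cs.simulate_hopf(cs.SDEConfig.hopf(seed=0))


@pytest.fixture(scope="session")
def hopf_markers(hopf_trajectory):
    return cs.compute_markers(hopf_trajectory)


@pytest.fixture(scope="session")
def recording():
    """One emulated patch recording under the default protocol."""
    return cs.emulate_patch_recording(cs.PatchProtocolConfig(), cs.SDEConfig.saddle_node(seed=3))


@pytest.fixture(scope="session")
def control_recording():
    return cs.emulate_patch_recording(
        cs.PatchProtocolConfig(), cs.SDEConfig.saddle_node(seed=3), control=True
    )


@pytest.fixture(scope="session")
def recording_markers(recording):
    return cs.compute_markers(recording)


def make_series(delta_I, lam=None, variance=None, acf=None, mean_voltage=None,
                v_cm=None, kind="recording"):
    """Hand-built MarkerSeries for synthetic scaling/prediction tests."""
    delta_I = np.asarray(delta_I, dtype=float)
    n = len(delta_I)

    def col(x, fill):
        return np.full(n, fill) if x is None else np.asarray(x, dtype=float)

    samples = [
        MarkerSample(
            delta_I=d,
            lam=l,
            variance=v,
            acf=a,
            mean_voltage=mv,
            pulse_time=float(t),
        )
        for t, (d, l, v, a, mv) in enumerate(
            zip(delta_I, col(lam, np.nan), col(variance, np.nan),
                col(acf, np.nan), col(mean_voltage, np.nan))
        )
    ]
    return MarkerSeries(samples=samples, I_c=None, V_cm=v_cm, onset_time=None,
                        acf_lag=1, acf_lag_time=1.0, kind=kind)
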