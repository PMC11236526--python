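import numpy as np
import pytest

import cvrflow as cf


@pytest.fixture(scope="session")
def protocol():
    return cf.build_default_protocol()


@pytest.fixture(scope="session")
def gas_traces(protocol):
    """Default CO2/O2 traces with the default 10-s gas transitions."""
    return cf.render_traces(protocol)


@pytest.fixture(scope="session")
def co2_volumes(protocol, gas_traces):
    co2, _ = gas_traces
    return cf.resample_trace(co2, protocol.tr, protocol.n_volumes)


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic subject at the default study conditions."""
    return cf.simulate_dataset()


@pytest.fixture(scope="session")
def subject_report(dataset):
    return cf.analyze_subject(
        dataset.bold,
        dataset.masks,
        dataset.co2,
        dataset.o2,
        protocol=dataset.protocol,
    )


def brute_force_best_lag(x, y, max_lag):
    """Independent exhaustive-shift Pearson-correlation oracle.

    Evaluates the correlation at every integer shift with overlap-only
    samples and returns the argmax, ties toward the smallest |lag| and the
    positive lag at equal magnitude.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    best = None
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
        if xs.size < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        key = (-r, abs(lag), -np.sign(lag))
        if best is None or key < best[0]:
            best = (key, lag, r)
    assert best is not None
    return best[1], best[2]
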