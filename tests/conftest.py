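import numpy as np
import pytest

from sonophys import DetectorConfig
from sonophys.core import BiexpKernel


@pytest.fixture(scope="session")
def kernel() -> BiexpKernel:
    return BiexpKernel(tau_rise=0.001, tau_decay=0.015)


@pytest.fixture(scope="session")
def psc_detector(kernel) -> DetectorConfig:
    return DetectorConfig(template=kernel)


def match_events(truth_times: np.ndarray, detected_times: np.ndarray, tol: float):
    """Greedy one-to-one matching of truth to detected times within ``tol``."""
    used = np.zeros(detected_times.size, dtype=bool)
    pairs = []
    for t in truth_times:
        if detected_times.size == 0:
            break
        err = np.abs(detected_times - t)
        err[used] = np.inf
        i = int(np.argmin(err))
        if err[i] < tol:
            used[i] = True
            pairs.append((t, detected_times[i]))
    return pairs
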