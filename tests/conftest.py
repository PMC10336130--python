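import numpy as np
import pytest

import mztrail as mt


def gaussian_track(n_scans, center, sigma, height, baseline=0.0):
    """Analytic single-Gaussian intensity vector on unit scan spacing."""
    t = np.arange(n_scans, dtype=float)
    return baseline + height * np.exp(-((t - center) ** 2) / (2.0 * sigma**2))


@pytest.fixture(scope="session")
def drift_experiment():
    """100 compounds, 5 samples, 1 ppm jitter, +-5 s smooth drift."""
    truth = mt.make_ground_truth(seed=1)
    exp = mt.generate_experiment(truth)
    return exp


@pytest.fixture(scope="session")
def drift_result(drift_experiment):
    return mt.run_pipeline(drift_experiment.runs)


@pytest.fixture()
def simple_run():
    """Tiny 10-scan run with two well-separated ion series."""
    times = np.arange(1.0, 11.0)
    scans = []
    for k in range(10):
        scans.append((np.array([200.0, 500.0]), np.array([1e4 * (k + 1), 2e5])))
    return mt.SampleRun("tiny", times, scans)
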