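import numpy as np
import pytest

import taarip as T


@pytest.fixture
def make_sinusoid():
    """Factory for clean analytic two-band sinusoid recordings."""

    def _make(lag_deg=0.0, amp_rc=1.0, amp_abd=1.0, rate_bpm=15.0,
              duration_s=60.0, fs=50.0, noise_sd=0.0, seed=0):
        p = T.BreathingParams(
            rate_bpm=rate_bpm, amp_rc=amp_rc, amp_abd=amp_abd,
            phase_lag_deg=lag_deg, noise_sd=noise_sd, duration_s=duration_s,
            fs=fs, seed=seed,
        )
        return T.generate_breathing(p)

    return _make


@pytest.fixture(scope="session")
def small_cohort_features():
    """Features and labels from a small default cohort (shared across tests)."""
    spec = T.CohortSpec(n_normal=6, n_abnormal=6, seed=11)
    X, y, curves = [], [], []
    for rec, label in T.generate_cohort(spec):
        series = T.compute_indices(rec)
        curve = T.compute_icp(series.phase_deg)
        curves.append(curve)
        X.append(T.icp_features(curve))
        y.append(label)
    return np.asarray(X), y, curves
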