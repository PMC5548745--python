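import numpy as np
import pytest

import dimerscope as ds


@pytest.fixture(scope="session")
def geom():
    """Calibration geometry: 222/272 nm radii, 125 nm focus displacement."""
    return ds.DetectionGeometry(omega_g=0.222, omega_r=0.272, r0=0.125)


@pytest.fixture(scope="session")
def geom_overlap():
    """Perfectly overlapping foci (r0 = 0)."""
    return ds.DetectionGeometry(omega_g=0.222, omega_r=0.272, r0=0.0)


def direct_correlation(a, b, lag_bins):
    """Brute-force O(n²) correlation estimate with symmetric normalization.

    Independent oracle for the multiple-tau estimator: plain Python loops,
    one lag at a time, ⟨a(t)b(t+j)⟩ over the overlap divided by the product
    of the overlap-window means, minus 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = []
    for j in lag_bins:
        n = len(a) - j
        total = 0.0
        for t in range(n):
            total += a[t] * b[t + j]
        num = total / n
        mean_left = a[:n].mean()
        mean_right = b[j:].mean()
        out.append(num / (mean_left * mean_right) - 1.0)
    return np.array(out)


def bin_by_two(x):
    n = len(x) // 2
    return np.asarray(x, dtype=float)[: 2 * n].reshape(n, 2).mean(axis=1)


def multiple_tau_level(lag_bins, m=16):
    """Coarsening level a lag belongs to on the multiple-tau grid."""
    level = 0
    while lag_bins // 2**level > m:
        level += 1
    return level
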