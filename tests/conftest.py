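import numpy as np
import pytest

from rsnflow.synthetic_data import (CohortSpec, CouplingSpec,
                                    default_network_specs, make_mask)


@pytest.fixture(scope="session")
def small_mask():
    return make_mask((20, 20, 20), 8.0)


@pytest.fixture(scope="session")
def network_specs(small_mask):
    return default_network_specs(small_mask, K=8)


@pytest.fixture(scope="session")
def matched_couplings():
    """Planted couplings forming a matching (no shared networks), so the
    planted edge set equals the full set of true pairwise correlations."""
    return [CouplingSpec((0, 1), 0.5, 1.0), CouplingSpec((2, 3), 0.5, -2.0),
            CouplingSpec((4, 5), 0.5, 0.0), CouplingSpec((6, 7), 0.5, 2.0)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_bh(p, alpha):
    """Exhaustive BH oracle: try every p-value as the threshold and keep the
    largest one satisfying the step-up inequality."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = 0.0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= alpha * rank / m:
            thresh = p[idx]
    return p <= thresh if thresh > 0 else np.zeros(m, dtype=bool)


def brute_force_lag_scan(x, y, dt_s, max_lag_s):
    """Independent exhaustive lag scan with numpy corrcoef; mirrors the
    tie-break rule (smallest |lag| first, negative before positive)."""
    L = int(max_lag_s / dt_s)
    best_r, best_lag = None, None
    lags = sorted(range(-L, L + 1), key=lambda s: (abs(s), s))
    for step in lags:
        r = np.corrcoef(x, np.roll(y, -step))[0, 1]
        if best_r is None or abs(r) > abs(best_r) + 1e-15:
            best_r, best_lag = r, step * dt_s
    return best_r, best_lag
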