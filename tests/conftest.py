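import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_valid_breakpoints(rng, T):
    """Sample a strictly feasible breakpoint vector of length T.

    Exact-pattern feasibility only exists for T <= 5 (see the methods
    note); the sampler walks the feasibility polytope constructively
    (p_2 = 1, p_1 = c, then each p_{t+1} drawn inside its admissible
    interval) and verifies with validate_breakpoints.
    """
    from spikequant.atif import validate_breakpoints

    if T == 1:
        return np.array([float(rng.uniform(0.2, 2.0))])
    if T > 5:
        raise ValueError("exact-pattern-valid vectors exist only for T <= 5")
    while True:
        c = float(rng.uniform(max(T / (T - 1), 1.1), 3.0))
        p = np.empty(T)
        p[0], p[1] = c, 1.0
        ok = True
        for t in range(2, T):  # choose p_{t+1} inside its interval
            V_prev = [T * (p[s - 1] - p[s]) for s in range(2, t)]  # V_2..V_{t-1}
            U = min(
                [T * p[t - 1] / (T + t)]
                + [v / s for v, s in zip(V_prev, range(2, t))]
            )
            L = max((T - t) / T, 1.0 - (t - 1) * c / T)
            if U <= L * 1.001:
                ok = False
                break
            p[t] = L + rng.uniform(0.05, 0.95) * (U - L)
        if not ok:
            continue
        p *= float(rng.uniform(0.05, 2.0))
        if validate_breakpoints(p, T).all_ok:
            return p
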