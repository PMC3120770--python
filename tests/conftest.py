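import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from schizocea import CEAModel, gen_parameter_set

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ps():
    """Default synthetic parameter set (seed 1)."""
    return gen_parameter_set(1)


@pytest.fixture(scope="session")
def results(ps):
    """Deterministic run of every default strategy."""
    return CEAModel(ps).run()


def microsimulate(matrices, n_persons, seed, record_cycles):
    """Independent per-person state-sampling oracle for the cohort model.

    Samples each person's state path from the same age-indexed matrices and
    returns {cycle: occupancy fraction array} at the requested cycles.
    """
    rng = np.random.default_rng(seed)
    state = np.zeros(n_persons, dtype=np.int64)  # everyone starts in S
    out = {}
    if 0 in record_cycles:
        out[0] = np.bincount(state, minlength=3) / n_persons
    for t in range(matrices.shape[0]):
        rows = matrices[t][state]
        u = rng.random(n_persons)
        state = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
        if t + 1 in record_cycles:
            out[t + 1] = np.bincount(state, minlength=3) / n_persons
    return out


def frontier_oracle(points):
    """Brute-force efficient-frontier construction by greedy minimum slope.

    ``points`` are (name, cost, effect) including the null ("", 0, 0).
    Starting from the cheapest point (tie: highest effect, then name), always
    step to the strictly-more-effective point with the smallest incremental
    cost-effectiveness ratio (tie: larger effect).  This is the convex-hull
    construction, independent of dominance-elimination order.
    """
    pts = sorted(points, key=lambda p: (p[1], -p[2], p[0]))
    chain = [pts[0]]
    while True:
        cur = chain[-1]
        candidates = [p for p in pts if p[2] > cur[2]]
        if not candidates:
            break
        best = min(
            candidates, key=lambda p: ((p[1] - cur[1]) / (p[2] - cur[2]), -p[2], p[0])
        )
        chain.append(best)
    return chain
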