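import numpy as np
import pandas as pd
import pytest

import epiburden as eb
from epiburden.matrix import M_SCALE, MethylationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


@pytest.fixture
def m_matrix(rng):
    """Small random M-scale matrix (12 probes x 9 samples)."""
    vals = pd.DataFrame(
        rng.normal(0, 2, size=(12, 9)),
        index=[f"cg{i:08d}" for i in range(12)],
        columns=[f"S{i:04d}" for i in range(9)],
    )
    return MethylationMatrix(vals, scale=M_SCALE)


@pytest.fixture(scope="session")
def signal_bundle():
    """One simulated cohort with ten planted signal genes (seed 7)."""
    cfg = eb.with_signal(n_signal=10, seed=7)
    return eb.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def signal_calls(signal_bundle):
    mvals = eb.beta_to_m(signal_bundle["matrix"])
    calls, limits, boundaries = eb.call_and_rank(mvals)
    return calls


def brute_force_calls(values: np.ndarray, probes, samples) -> set:
    """Independent epimutation caller: explicit sort-based quartiles and a
    plain loop over cells.  Returns {(sample, probe, direction, delta)}."""
    out = set()
    for i, probe in enumerate(probes):
        row = sorted(values[i])
        n = len(row)

        def q(p):
            pos = p * (n - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, n - 1)
            return row[lo] + (pos - lo) * (row[hi] - row[lo])

        q1, q3 = q(0.25), q(0.75)
        iqr = q3 - q1
        lmin, lmax = q1 - 3 * iqr, q3 + 3 * iqr
        for j, sample in enumerate(samples):
            v = values[i, j]
            if v > lmax:
                out.add((sample, probe, "hyper", round(v - lmax, 9)))
            elif v < lmin:
                out.add((sample, probe, "hypo", round(lmin - v, 9)))
    return out


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """Direct evaluation of q_i = min_{j: p_(j) >= p_(i)} p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running = min(running, p[idx] * m / (rank_from_top + 1))
        q[idx] = min(running, 1.0)
    return q
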