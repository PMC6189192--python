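import itertools
import math

import numpy as np
import pytest

from prtf.pipeline import make_demo
from prtf.synthetic import SyntheticConfig, generate_cohort


def null_config(seed: int = 11) -> SyntheticConfig:
    """A cohort with no planted structure: labels carry no signal at all."""
    return SyntheticConfig(
        effect_size=0.0, activity_sd=0.0, hazard_ratio_Rpos=1.0, seed=seed
    )


@pytest.fixture(scope="session")
def planted_cohort():
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(null_config())


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """One full pipeline run on the default planted cohort, shared by tests."""
    out = tmp_path_factory.mktemp("demo")
    summary = make_demo(7, out)
    return out, summary


# ---------------------------------------------------------------- oracles


def brute_force_extrema(member_ranks, n, m):
    """Running-score extrema by direct prefix summation (independent oracle)."""
    h = np.full(n, -1.0 / (n - m))
    for r in member_ranks:
        h[r - 1] = 1.0 / m
    cs = np.cumsum(h)
    return min(cs.min(), 0.0), max(cs.max(), 0.0)


def brute_force_null(n, m):
    """All C(n, m) membership placements, scored by the naive prefix oracle."""
    minus, plus = [], []
    for ranks in itertools.combinations(range(1, n + 1), m):
        e_minus, e_plus = brute_force_extrema(ranks, n, m)
        minus.append(e_minus)
        plus.append(e_plus)
    return np.array(minus), np.array(plus)


def hypergeom_upper_tail(k, N, K, n):
    """P(overlap >= k) for fixed margins, by direct enumeration."""
    total = math.comb(N, n)
    hi = min(K, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, hi + 1)) / total


def cox_score_statistic(times, events, x):
    """Score test of a single covariate Cox model at beta = 0.

    For tie-free data this equals the log-rank chi-square. Direct risk-set
    summation: U = sum over events of (x_i - mean_x(risk set)),
    I = sum of var_x(risk set).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    U = 0.0
    I = 0.0
    n = len(times)
    for i in range(n):
        if events[i] != 1:
            continue
        risk = x[i:]
        mu = risk.mean()
        U += x[i] - mu
        I += ((risk - mu) ** 2).mean()
    return U * U / I


def random_full_rank_ternary(rng, n_genes, n_tfs):
    """A random {-1,0,+1} design with nonzero rows/cols and full column rank."""
    while True:
        X = rng.choice([-1, 0, 1], size=(n_genes, n_tfs), p=[0.2, 0.5, 0.3])
        if (X != 0).sum(axis=0).min() == 0 or (X != 0).sum(axis=1).min() == 0:
            continue
        if np.linalg.matrix_rank(X) == n_tfs:
            return X
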