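import numpy as np
import pytest

from keetools.enhancer_classifier import call_enhancers, classify_buckets
from keetools.synthetic_data import (
    SimConfig,
    simulate_enhancers_and_peaks,
    simulate_genome_and_genes,
)


@pytest.fixture(scope="session")
def default_sim():
    """Noise-free default synthetic genome (seed 7): peaks + ground truth."""
    config = SimConfig(seed=7)
    sizes, genes = simulate_genome_and_genes(config)
    peaks, truths = simulate_enhancers_and_peaks(config, sizes, genes)
    return config, sizes, genes, peaks, truths


@pytest.fixture(scope="session")
def default_calls(default_sim):
    """Enhancer calls from the default synthetic peaks (H3K79me2 slot)."""
    _, sizes, _, peaks, _ = default_sim
    states = classify_buckets(
        sizes,
        {
            "H3K4me1": peaks["H3K4me1"],
            "H3K27ac": peaks["H3K27ac"],
            "H3K79": peaks["H3K79me2"],
        },
    )
    return call_enhancers(states)


def signed_rank_oracle(diffs):
    """Brute-force signed-rank two-sided p by enumerating all sign patterns.

    Independent of the package implementation: explicit loop over the 2^n
    sign assignments of the (zero-dropped, midranked) absolute differences.
    """
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for mask in range(2 ** n):
        w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        ws.append(w)
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum_oracle(x, y):
    """Exact rank-sum two-sided p by enumerating all group assignments."""
    from itertools import combinations

    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    n1, n = len(x), len(combined)
    w_obs = ranks[:n1].sum()
    ws = np.array(
        [sum(ranks[list(idx)]) for idx in combinations(range(n), n1)]
    )
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))
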