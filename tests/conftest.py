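import itertools

import numpy as np
import pytest

from feediv import Community, SpeciesPool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def line_pool():
    """Four species on a 1-D line at 0, 0.3, 0.6, 0.9."""
    return SpeciesPool.from_normalized(
        ["a", "b", "c", "d"], np.array([[0.0], [0.3], [0.6], [0.9]])
    )


@pytest.fixture
def line_community(line_pool):
    return Community(line_pool, ("a", "b", "c", "d"))


def prufer_to_edges(seq, n):
    """Decode a Prüfer sequence into the labeled tree's edge list."""
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    seq = list(seq)
    for x in seq:
        for j in range(n):
            if degree[j] == 1:
                edges.append((j, x))
                degree[j] -= 1
                degree[x] -= 1
                break
    u, v = [j for j in range(n) if degree[j] == 1]
    edges.append((u, v))
    return edges


def brute_force_mst(D):
    """Exhaustive minimum over all labeled spanning trees (Cayley/Prüfer).

    Returns (total_length, sorted branch lengths) of the optimum.
    Feasible for n <= 6 (at most 6^4 = 1296 trees).
    """
    n = D.shape[0]
    if n == 2:
        return float(D[0, 1]), np.array([D[0, 1]])
    best_total, best_lengths = np.inf, None
    for seq in itertools.product(range(n), repeat=n - 2):
        edges = prufer_to_edges(seq, n)
        lengths = np.array([D[i, j] for i, j in edges])
        total = lengths.sum()
        if total < best_total:
            best_total, best_lengths = total, np.sort(lengths)
    return float(best_total), best_lengths
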