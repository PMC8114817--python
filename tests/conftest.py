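import random

import pytest

# 15-element vectors of the traced worked example (distinct values, so
# layer membership is deterministic).
WORKED_X = [31, 5, 11, 7, 33, 6, 39, 42, 20, 0, 9, 1, 41, 26, 8]
WORKED_Y = [12, 26, 40, 9, 14, 49, 8, 2, 20, 1, 46, 43, 4, 5, 7]


@pytest.fixture
def worked_x():
    return list(WORKED_X)


@pytest.fixture
def worked_y():
    return list(WORKED_Y)


@pytest.fixture
def rng():
    return random.Random(20240501)


def brute_force_topk(X, Y, k):
    """Sort oracle: the k smallest pairwise sums, ascending."""
    return sorted(x + y for x in X for y in Y)[:k]


def corner_scan_oracle(loh_x, loh_y, k):
    """Independent phase-1/2 oracle: enumerate all corner tuples of the
    layer products in sorted order and accumulate committed area.

    Uses only the LOH layer contents (plain tuples, no heap, none of the
    sweep code) so it can vouch for the sweep's trace.
    Returns (tau, s, s_prime, phase1_pairs, phase2_pairs).
    """
    corners = []
    for u in range(loh_x.num_layers):
        for v in range(loh_y.num_layers):
            corners.append((min(loh_x.layers[u]) + min(loh_y.layers[v]), (u, v), 0))
            corners.append((max(loh_x.layers[u]) + max(loh_y.layers[v]), (u, v), 1))
    corners.sort()
    s = 0
    tau = None
    phase1 = []
    min_visited = []
    for value, (u, v), flag in corners:
        if flag == 0:
            min_visited.append((u, v))
        else:
            phase1.append((u, v))
            s += len(loh_x.layers[u]) * len(loh_y.layers[v])
            if s >= k:
                tau = value
                break
    committed = set(phase1)
    phase2 = [p for p in min_visited if p not in committed]
    s_prime = sum(len(loh_x.layers[u]) * len(loh_y.layers[v]) for u, v in phase2)
    return tau, s, s_prime, phase1, phase2
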