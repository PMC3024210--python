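import math

import numpy as np
import pytest

from intensitybounds import AreaMap, CaseVector


@pytest.fixture
def tiny_map():
    """Three areas on a line with populations 10, 20, 30."""
    amap = AreaMap(
        ids=("A", "B", "C"),
        centroids=np.array([[0.0, 0.0], [1.0, 0.0], [2.5, 0.0]]),
        populations=np.array([10, 20, 30]),
    )
    return amap, CaseVector(np.array([1, 0, 2]))


@pytest.fixture
def hex_flower():
    """A center cell with its six ring neighbours, equal populations."""
    angles = [k * math.pi / 3 for k in range(6)]
    cent = np.vstack([[0.0, 0.0]] + [[math.cos(a), math.sin(a)] for a in angles])
    ids = tuple(f"h{i}" for i in range(7))
    adjacency = {ids[0]: frozenset(ids[1:])}
    for k in range(1, 7):
        nbrs = {ids[0], ids[1 + (k % 6)], ids[1 + ((k - 2) % 6)]}
        adjacency[ids[k]] = frozenset(nbrs - {ids[k]})
    return AreaMap(ids, cent, np.full(7, 100), adjacency)


def random_small_map(rng, max_areas=12):
    """A random planar map with integer populations and cases, for oracles."""
    K = int(rng.integers(2, max_areas + 1))
    cent = rng.uniform(0, 10, size=(K, 2))
    pop = rng.integers(1, 200, size=K)
    cases = rng.integers(0, 12, size=K)
    if cases.sum() == 0:
        cases[int(rng.integers(K))] = 1
    ids = tuple(f"a{i}" for i in range(K))
    return AreaMap(ids, cent, pop), CaseVector(cases)


def brute_force_mlc(amap, cases, max_pop_fraction=1.0):
    """Independent maximization over all center x radius circular windows.

    Walks every center's nested window sequence explicitly, computes the
    LLR from the scalar formula, and applies the documented tie-break
    (smaller population, then fewer members, then lowest center index).
    Returns (member frozenset or None, llr).
    """
    counts = cases.counts
    pop = amap.populations
    C = int(counts.sum())
    N = int(pop.sum())
    cap = max_pop_fraction * N
    best = (0.0, None)  # (llr, key); key = (n_z, size, center)
    best_members = None
    for center in range(amap.n_areas):
        d = np.hypot(
            amap.centroids[:, 0] - amap.centroids[center, 0],
            amap.centroids[:, 1] - amap.centroids[center, 1],
        )
        order = sorted(range(amap.n_areas), key=lambda i: (d[i], i))
        members, c_z, n_z = [], 0, 0
        for i in order:
            members.append(i)
            c_z += int(counts[i])
            n_z += int(pop[i])
            if n_z > cap + 1e-9:
                break
            mu = C * n_z / N
            if c_z > mu:
                rem = C - c_z
                llr = c_z * math.log(c_z / mu)
                if rem > 0:
                    llr += rem * math.log(rem / (C - mu))
            else:
                llr = 0.0
            if llr <= 0.0:
                continue
            key = (n_z, len(members), center)
            if llr > best[0] or (llr == best[0] and (best[1] is None or key < best[1])):
                best = (llr, key)
                best_members = frozenset(members)
    return best_members, best[0]
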