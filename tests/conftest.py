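import numpy as np
import pytest

from fecalpop import synthetic_data as syn


@pytest.fixture(scope="session")
def clean_dataset():
    """Small error-free simulated dataset: consensus must equal truth."""
    cfg = syn.SimulationConfig(
        seed=11,
        deme_sizes={"AM": 8, "MM": 8, "CCA": 12, "SE": 8, "TA": 8},
        dropout_rate=0.0,
        false_allele_rate=0.0,
    )
    truth, table, meta, seqs, truth_map = syn.simulate_dataset(cfg)
    return cfg, truth, table, meta, seqs, truth_map


@pytest.fixture(scope="session")
def noisy_dataset():
    """Two-deme dataset with realistic dropout and false-allele rates."""
    cfg = syn.SimulationConfig(
        seed=7,
        demes=("A", "B"),
        deme_sizes={"A": 60, "B": 60},
        barrier_assignment={"A": "east", "B": "west"},
        focal_deme=None,
        recapture_mean_by_deme={},
        recapture_mean=1.3,
        dropout_rate=0.2,
        false_allele_rate=0.05,
    )
    truth, table, meta, seqs, truth_map = syn.simulate_dataset(cfg)
    return cfg, truth, table, meta, seqs, truth_map


def random_additive_tree(n: int, rng: np.random.Generator):
    """Random unrooted binary tree; returns (labels, leaf distance matrix).

    Independent of the package's tree code: builds an adjacency list by
    random sequential joining and extracts path lengths by graph search.
    """
    ids = list(range(n))
    next_id = n
    adj: dict[int, list[tuple[int, float]]] = {}
    avail = ids[:]
    while len(avail) > 2:
        i, j = sorted(rng.permutation(len(avail))[:2])
        a, b = avail[i], avail[j]
        new = next_id
        next_id += 1
        for x in (a, b):
            w = float(rng.uniform(0.1, 1.0))
            adj.setdefault(new, []).append((x, w))
            adj.setdefault(x, []).append((new, w))
        avail = [x for x in avail if x not in (a, b)] + [new]
    a, b = avail
    w = float(rng.uniform(0.1, 1.0))
    adj.setdefault(a, []).append((b, w))
    adj.setdefault(b, []).append((a, w))
    dmat = np.zeros((n, n))
    for s in range(n):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, wt in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + wt
                    stack.append(v)
        for t in range(n):
            dmat[s, t] = dist[t]
    return [f"T{i}" for i in range(n)], dmat
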