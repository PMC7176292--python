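import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def dbscan_bruteforce(D: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Independent O(n²) DBSCAN: core points have >= min_pts neighbors
    within eps (counting themselves); clusters grow by BFS through core
    points; border points join the first cluster that reaches them."""
    n = D.shape[0]
    neighbors = [np.nonzero(D[i] <= eps)[0] for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
        cid += 1
    return labels


def labels_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """Cluster labelings equal up to a permutation of cluster ids
    (noise label -1 must match exactly)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    used: set[int] = set()
    for x, y in zip(a, b):
        if x == -1:
            continue
        if x in mapping:
            if mapping[x] != y:
                return False
        else:
            if y in used:
                return False
            mapping[x] = y
            used.add(y)
    return True
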