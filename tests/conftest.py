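import numpy as np
import pytest

from netpolarity import DirectedNetwork


def count_walks_dfs(adjacency: np.ndarray, source: int, target: int,
                    length: int) -> int:
    """Independent oracle: count walks (nodes may repeat) of an exact
    length between two nodes by depth-limited exhaustive search."""
    A = np.asarray(adjacency)
    n = A.shape[0]

    def rec(v: int, remaining: int) -> int:
        if remaining == 0:
            return 1 if v == target else 0
        return sum(rec(w, remaining - 1) for w in range(n) if A[v, w])

    return rec(source, length)


def walk_nodes_dfs(adjacency: np.ndarray, source: int, target: int,
                   length: int) -> set[int]:
    """Oracle: the set of intermediate nodes appearing on ANY walk of
    the exact length from source to target."""
    A = np.asarray(adjacency)
    n = A.shape[0]
    found: set[int] = set()

    def rec(v: int, remaining: int, inner: tuple[int, ...]) -> None:
        if remaining == 0:
            if v == target:
                found.update(inner)
            return
        for w in range(n):
            if A[v, w]:
                rec(w, remaining - 1, inner + ((w,) if remaining > 1 else ()))

    rec(source, length, ())
    return found


def random_digraph(n: int, p: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A


@pytest.fixture
def chain3():
    """input 0 -> 1 -> output 2."""
    A = np.zeros((3, 3), dtype=int)
    A[0, 1] = A[1, 2] = 1
    return DirectedNetwork(A, roles=np.array(
        ["input", "inter", "output"], dtype=object))


@pytest.fixture
def recurrent_toy():
    """i=0 -> v=1 -> j=2, with a 2-cycle v=1 <-> w=3.

    Walk inventory i->j: length 2 (i,v,j), length 4 (i,v,w,v,j);
    no walks of length 1 or 3.
    """
    A = np.zeros((4, 4), dtype=int)
    A[0, 1] = 1  # i -> v
    A[1, 2] = 1  # v -> j
    A[1, 3] = 1  # v -> w
    A[3, 1] = 1  # w -> v
    return DirectedNetwork(A, roles=np.array(
        ["input", "inter", "output", "inter"], dtype=object))


@pytest.fixture
def two_cliques():
    """Two fully bidirectional 5-cliques joined by a single edge."""
    A = np.zeros((10, 10), dtype=int)
    for base in (0, 5):
        for i in range(5):
            for j in range(5):
                if i != j:
                    A[base + i, base + j] = 1
    A[0, 5] = 1
    return DirectedNetwork(A)
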