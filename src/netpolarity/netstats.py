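"""Directed network statistics: characteristic path length, Fagiolo
clustering, small-worldness, directed modularity, participation
coefficient, and hub classification.

These are the calibration and hub-analysis statistics used around the
propagation measures.  All operate on the binary directed adjacency;
conventions follow the directed generalisations standard in the brain
connectivity literature:

* path length — mean shortest directed path over reachable ordered
  pairs (unreachable pairs excluded, with the excluded fraction
  surfaced);
* clustering — Fagiolo's directed coefficient
  ``C_i = [(A + A^T)^3]_ii / (2 [d_i (d_i - 1) - 2 d_i^<->])``
  with ``d_i`` the total (in+out) degree and ``d_i^<->`` the number of
  reciprocal partners;
* small-worldness ``S = (C / L) / (C_ER / L_ER)`` against a seeded
  Erdős–Rényi ensemble matched on size and density;
* modularity — Leicht–Newman directed
  ``Q = (1/m) sum_ij [A_ij - k_i^out k_j^in / m] delta(c_i, c_j)``,
  maximised by seeded Leiden restarts on the directed graph;
* participation coefficient — ``P_i = 1 - sum_s (k_{i,s}/k_i)^2``
  counting both in- and out-links per module, with an optional
  small-module-count normalisation ``N_m / (N_m - 1)`` that makes a
  uniformly spread hub score exactly 1.

Hubs (top total-degree nodes) classify as provincial (P <= 0.30),
connector (0.30 < P <= 0.75) or kinless (P > 0.75).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import igraph
import leidenalg
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import DirectedNetwork, NetworkValidationError

logger = logging.getLogger("netpolarity")

__all__ = [
    "ModulePartition",
    "HubReport",
    "HubRow",
    "PathLengthResult",
    "characteristic_path_length",
    "clustering_coefficient",
    "small_worldness",
    "directed_modularity",
    "find_modules",
    "participation_coefficient",
    "classify_hubs",
    "HUB_PROVINCIAL_MAX_P",
    "HUB_CONNECTOR_MAX_P",
]

HUB_PROVINCIAL_MAX_P = 0.30
HUB_CONNECTOR_MAX_P = 0.75


class PathLengthResult(NamedTuple):
    """Characteristic path length with the excluded-pair fraction."""

    length: float
    unreachable_fraction: float


def characteristic_path_length(
    net: DirectedNetwork, full: bool = False
) -> float | PathLengthResult:
    """Mean shortest directed path length over reachable ordered pairs.

    Unreachable ordered pairs are excluded from the mean; pass
    ``full=True`` to also get the excluded fraction (so discrepancies
    against other conventions are diagnosable).
    """
    n = net.n_nodes
    if n < 2:
        raise NetworkValidationError("path length needs >= 2 nodes")
    D = shortest_path(
        csr_matrix(net.adjacency), method="D", unweighted=True, directed=True
    )
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_pairs = n * (n - 1)
    if not finite.any():
        raise NetworkValidationError("no reachable ordered pair of nodes")
    L = float(D[finite].mean())
    frac = 1.0 - finite.sum() / n_pairs
    if frac > 0:
        logger.debug("path length: %.1f%% of pairs unreachable", 100 * frac)
    return PathLengthResult(L, float(frac)) if full else L


def clustering_coefficient(net: DirectedNetwork) -> float:
    """Mean directed clustering coefficient (Fagiolo).

    Nodes whose denominator vanishes (degree < 2, or all neighbours
    reciprocal-only) contribute 0.
    """
    if net.n_nodes < 3:
        raise NetworkValidationError("clustering needs >= 3 nodes")
    A = net.adjacency.astype(np.int64)
    S = A + A.T
    tri = np.diagonal(S @ S @ S).astype(np.float64)  # 2x directed triangles
    d_tot = A.sum(axis=0) + A.sum(axis=1)
    d_bi = np.diagonal(A @ A)  # reciprocal partners
    denom = 2.0 * (d_tot * (d_tot - 1) - 2 * d_bi)
    C = np.zeros(net.n_nodes)
    ok = denom > 0
    C[ok] = tri[ok] / denom[ok]
    return float(C.mean())


def small_worldness(
    net: DirectedNetwork,
    n_reference: int = 100,
    seed: int | None = None,
    reference: tuple[float, float] | None = None,
) -> float:
    """Small-worldness ``S = (C/L) / (C_ER/L_ER)``.

    ``C_ER`` and ``L_ER`` are averaged over ``n_reference`` seeded
    Erdős–Rényi draws matched on node count and connection density,
    unless a precomputed ``(C_ER, L_ER)`` pair is supplied (useful when
    scoring a whole ensemble against one reference).
    """
    from .generators import ERConfig, make_er

    C = clustering_coefficient(net)
    L = characteristic_path_length(net)
    if reference is None:
        n = net.n_nodes
        p = net.n_edges / (n * (n - 1))
        rng = np.random.default_rng(seed)
        cs, ls = [], []
        for _ in range(n_reference):
            er = make_er(ERConfig(n, p, int(rng.integers(2**31))))
            cs.append(clustering_coefficient(er))
            ls.append(characteristic_path_length(er))
        c_er, l_er = float(np.mean(cs)), float(np.mean(ls))
    else:
        c_er, l_er = reference
    if c_er <= 0:
        raise NetworkValidationError(
            "degenerate ER reference: zero clustering"
        )
    return (C / L) / (c_er / l_er)


@dataclass
class ModulePartition:
    """Node -> module assignment with its directed modularity score."""

    module_of: np.ndarray
    modularity_q: float

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.module_of))

    def module_nodes(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.module_of == m)

    def save_csv(self, path, names: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("# node\tmodule\n")
            for i, m in enumerate(self.module_of):
                label = names[i] if names else str(i)
                fh.write(f"{label}\t{int(m)}\n")


def directed_modularity(
    net: DirectedNetwork, module_of: np.ndarray
) -> float:
    """Leicht–Newman directed modularity of a given partition."""
    A = net.adjacency.astype(np.float64)
    m = A.sum()
    if m == 0:
        return 0.0
    k_out = A.sum(axis=1)
    k_in = A.sum(axis=0)
    module_of = np.asarray(module_of)
    q = 0.0
    for c in np.unique(module_of):
        idx = module_of == c
        q += A[np.ix_(idx, idx)].sum() / m
        q -= k_out[idx].sum() * k_in[idx].sum() / m**2
    return float(q)


def find_modules(
    net: DirectedNetwork, seed: int | None = None, n_restarts: int = 20
) -> ModulePartition:
    """Partition the network into modules maximising directed modularity.

    Runs seeded Leiden optimisation of the Leicht–Newman directed
    modularity ``n_restarts`` times and keeps the best-scoring
    partition (scored independently by :func:`directed_modularity`).
    Module ids are relabelled 0..N_m-1 in order of first appearance.
    """
    edges = list(zip(*np.nonzero(net.adjacency)))
    if not edges:
        logger.warning("find_modules on an empty network: one module")
        return ModulePartition(np.zeros(net.n_nodes, dtype=int), 0.0)
    g = igraph.Graph(
        n=net.n_nodes,
        edges=[(int(u), int(v)) for u, v in edges],
        directed=True,
    )
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    best_q = -np.inf
    for _ in range(max(1, n_restarts)):
        part = leidenalg.find_partition(
            g,
            leidenalg.ModularityVertexPartition,
            seed=int(rng.integers(2**31)),
        )
        membership = np.asarray(part.membership)
        q = directed_modularity(net, membership)
        if q > best_q:
            best_q, best = q, membership
    # stable relabel by first appearance
    _, relabeled = np.unique(best, return_inverse=True)
    order = {}
    out = np.empty_like(relabeled)
    for i, m in enumerate(relabeled):
        if m not in order:
            order[m] = len(order)
        out[i] = order[m]
    return ModulePartition(out, best_q)


def participation_coefficient(
    net: DirectedNetwork,
    partition: ModulePartition,
    node: int | str,
    modified: bool = True,
) -> float | None:
    """Participation coefficient of one node over a module partition.

    Counts both in- and out-links of the node per module.  The
    unmodified form is ``P = 1 - sum_s (k_s / k)^2``; the modified form
    multiplies by ``N_m / (N_m - 1)`` (and is defined as 0 for a
    single-module partition) so that links spread uniformly over the
    modules score exactly 1 even when few modules exist.  Returns None
    for an isolated node (k = 0).
    """
    i = net.index_of(node)
    module_of = np.asarray(partition.module_of)
    if module_of.shape != (net.n_nodes,):
        raise NetworkValidationError("partition does not cover the network")
    links = net.adjacency[i, :].astype(np.int64) + net.adjacency[:, i]
    k = int(links.sum())
    if k == 0:
        return None
    n_m = partition.n_modules
    if modified and n_m == 1:
        return 0.0
    p = 1.0
    for s in np.unique(module_of):
        k_s = int(links[module_of == s].sum())
        p -= (k_s / k) ** 2
    if modified:
        p *= n_m / (n_m - 1)
    return float(p)


class HubRow(NamedTuple):
    node: int
    name: str
    in_degree: int
    out_degree: int
    total_degree: int
    participation: float | None
    hub_class: str


@dataclass
class HubReport:
    """Top-degree nodes with participation coefficients and classes,
    sorted by total degree descending (ties by node index)."""

    rows: list[HubRow]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def save_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "node,name,in_degree,out_degree,total_degree,"
                "participation,hub_class\n"
            )
            for r in self.rows:
                p = "" if r.participation is None else f"{r.participation:.6f}"
                fh.write(
                    f"{r.node},{r.name},{r.in_degree},{r.out_degree},"
                    f"{r.total_degree},{p},{r.hub_class}\n"
                )


def _classify(p: float | None) -> str:
    if p is None:
        return "isolated"
    if p <= HUB_PROVINCIAL_MAX_P:
        return "provincial"
    if p <= HUB_CONNECTOR_MAX_P:
        return "connector"
    return "kinless"


def classify_hubs(
    net: DirectedNetwork,
    partition: ModulePartition,
    n_hubs: int = 15,
    modified: bool = True,
) -> HubReport:
    """Rank nodes by total (in+out) degree and classify the top ones.

    Classes by (modified) participation coefficient: provincial
    ``P <= 0.30``, connector ``0.30 < P <= 0.75``, kinless
    ``P > 0.75``.
    """
    if n_hubs > net.n_nodes:
        raise NetworkValidationError("n_hubs exceeds node count")
    in_deg = net.adjacency.sum(axis=0).astype(int)
    out_deg = net.adjacency.sum(axis=1).astype(int)
    total = in_deg + out_deg
    order = np.lexsort((np.arange(net.n_nodes), -total))[:n_hubs]
    rows = []
    for i in order:
        i = int(i)
        p = participation_coefficient(net, partition, i, modified)
        rows.append(
            HubRow(
                node=i,
                name=net._label(i),
                in_degree=int(in_deg[i]),
                out_degree=int(out_deg[i]),
                total_degree=int(total[i]),
                participation=p,
                hub_class=_classify(p),
            )
        )
    return HubReport(rows)
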