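"""Directed network data model, polarity roles, and file I/O.

The central object is :class:`DirectedNetwork`: a binary (0/1) adjacency
matrix ``A`` where ``A[i, j] == 1`` means a one-way connection from node
``i`` to node ``j``, together with optional node names and optional
per-node polarity roles.  Roles partition the nodes into ``input``
(entry points for signals, e.g. sensory neurons), ``inter``
(intermediate nodes), and ``output`` (leaving points, e.g. motor
neurons); the role assignment defines the *polarity* of the network.

Self-loops are forbidden everywhere: the propagation semantics count
intermediate nodes along walks, which assumes a node never connects to
itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("netpolarity")

ROLES = ("input", "inter", "output")

__all__ = [
    "DirectedNetwork",
    "RoleCounts",
    "NetworkValidationError",
    "load_edge_list",
    "save_edge_list",
    "load_adjacency_csv",
    "save_adjacency_csv",
    "load_graphml",
    "save_graphml",
    "load_role_table",
    "save_role_table",
    "assign_roles",
    "subnetwork_without",
]


class NetworkValidationError(ValueError):
    """Raised when an input file or constructed network violates the model."""


class RoleCounts(NamedTuple):
    """Sizes of the three polarity classes of a network."""

    n_input: int
    n_inter: int
    n_output: int


@dataclass
class DirectedNetwork:
    """A directed, unweighted network with optional names and polarity roles.

    Parameters
    ----------
    adjacency
        ``(n, n)`` array-like of 0/1; entry ``(i, j)`` is a one-way
        connection ``i -> j``.  Diagonal must be zero.
    node_names
        Optional sequence of unique text labels, one per node.
    roles
        Optional sequence of role tokens in ``{"input", "inter",
        "output"}``, one per node.
    """

    adjacency: np.ndarray
    node_names: list[str] | None = None
    roles: np.ndarray | None = None
    _name_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise NetworkValidationError(
                f"adjacency must be square, got shape {A.shape}"
            )
        if not np.isin(A, (0, 1)).all():
            bad = A[~np.isin(A, (0, 1))].flat[0]
            raise NetworkValidationError(
                f"adjacency entries must be 0 or 1, found {bad!r}"
            )
        if np.diagonal(A).any():
            i = int(np.flatnonzero(np.diagonal(A))[0])
            raise NetworkValidationError(
                f"self-loops are forbidden (node {self._label(i)})"
            )
        self.adjacency = A.astype(np.int8)
        n = A.shape[0]
        if self.node_names is not None:
            self.node_names = [str(x) for x in self.node_names]
            if len(self.node_names) != n:
                raise NetworkValidationError(
                    f"{len(self.node_names)} names for {n} nodes"
                )
            if len(set(self.node_names)) != n:
                raise NetworkValidationError("node names must be unique")
            self._name_index = {nm: i for i, nm in enumerate(self.node_names)}
        if self.roles is not None:
            roles = np.asarray(self.roles, dtype=object)
            if roles.shape != (n,):
                raise NetworkValidationError(
                    f"{roles.size} roles for {n} nodes"
                )
            unknown = set(roles) - set(ROLES)
            if unknown:
                raise NetworkValidationError(
                    f"unknown role token(s): {sorted(unknown)}"
                )
            self.roles = roles

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def input_nodes(self) -> np.ndarray:
        """Indices of input nodes (requires roles)."""
        return np.flatnonzero(self._roles_required() == "input")

    @property
    def inter_nodes(self) -> np.ndarray:
        return np.flatnonzero(self._roles_required() == "inter")

    @property
    def output_nodes(self) -> np.ndarray:
        return np.flatnonzero(self._roles_required() == "output")

    def role_counts(self) -> RoleCounts:
        r = self._roles_required()
        return RoleCounts(
            int((r == "input").sum()),
            int((r == "inter").sum()),
            int((r == "output").sum()),
        )

    def _roles_required(self) -> np.ndarray:
        if self.roles is None:
            raise NetworkValidationError(
                "network has no polarity roles assigned"
            )
        return self.roles

    def _label(self, i: int) -> str:
        if self.node_names is not None:
            return self.node_names[i]
        return str(i)

    def index_of(self, node: int | str) -> int:
        """Resolve a node given as integer index or name."""
        if isinstance(node, str) and not node.lstrip("-").isdigit():
            try:
                return self._name_index[node]
            except KeyError:
                raise NetworkValidationError(f"unknown node name {node!r}")
        i = int(node)
        if not 0 <= i < self.n_nodes:
            raise NetworkValidationError(f"node index {i} out of range")
        return i

    def copy(self) -> "DirectedNetwork":
        return DirectedNetwork(
            self.adjacency.copy(),
            list(self.node_names) if self.node_names is not None else None,
            self.roles.copy() if self.roles is not None else None,
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for i in range(self.n_nodes):
            attrs = {}
            if self.roles is not None:
                attrs["role"] = str(self.roles[i])
            g.add_node(self._label(i), **attrs)
        for i, j in zip(*np.nonzero(self.adjacency)):
            g.add_edge(self._label(int(i)), self._label(int(j)))
        return g


# -- loaders / writers ----------------------------------------------------


def _finish_edges(
    edges: list[tuple[int, int]],
    n: int,
    names: list[str] | None,
    origin: str,
) -> DirectedNetwork:
    A = np.zeros((n, n), dtype=np.int8)
    dup = 0
    for i, j in edges:
        if A[i, j]:
            dup += 1
        A[i, j] = 1
    if dup:
        logger.warning("%s: collapsed %d duplicate edge(s) to binary", origin, dup)
    return DirectedNetwork(A, names)


def load_edge_list(
    path,
    n_nodes: int | None = None,
    name_map: bool = False,
) -> DirectedNetwork:
    """Read a directed network from a two-column edge list.

    Columns are whitespace- or tab-separated ``source target`` pairs;
    lines starting with ``#`` are comments.  Node ids may be 0-based
    integers, or arbitrary names if ``name_map`` is true (names are
    indexed in order of first appearance).  Duplicate edges collapse to
    a single connection with a logged warning; self-loops are rejected.
    """
    names: list[str] | None = [] if name_map else None
    index: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    max_id = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise NetworkValidationError(
                    f"{path}:{lineno}: expected >=2 columns, got {line!r}"
                )
            s_tok, t_tok = parts[0], parts[1]
            if name_map:
                for tok in (s_tok, t_tok):
                    if tok not in index:
                        index[tok] = len(index)
                        names.append(tok)  # type: ignore[union-attr]
                i, j = index[s_tok], index[t_tok]
            else:
                try:
                    i, j = int(s_tok), int(t_tok)
                except ValueError:
                    raise NetworkValidationError(
                        f"{path}:{lineno}: non-integer node id in {line!r} "
                        "(pass name_map=True for named nodes)"
                    )
                if i < 0 or j < 0:
                    raise NetworkValidationError(
                        f"{path}:{lineno}: negative node id"
                    )
            if i == j:
                raise NetworkValidationError(
                    f"{path}:{lineno}: self-loop on node "
                    f"{names[i] if names else i}"
                )
            edges.append((i, j))
            max_id = max(max_id, i, j)
    n = len(index) if name_map else max_id + 1
    if n_nodes is not None:
        if n_nodes < n:
            raise NetworkValidationError(
                f"n_nodes={n_nodes} but file references {n} nodes"
            )
        n = n_nodes
    return _finish_edges(edges, n, names, str(path))


def save_edge_list(net: DirectedNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# source\ttarget\n")
        for i, j in zip(*np.nonzero(net.adjacency)):
            fh.write(f"{net._label(int(i))}\t{net._label(int(j))}\n")


def load_adjacency_csv(path) -> DirectedNetwork:
    """Read a dense 0/1 adjacency matrix from CSV.

    A header row / index column of node names is detected automatically
    (non-numeric first cell); otherwise the file is a bare numeric
    matrix.
    """
    with open(path) as fh:
        first = fh.readline()
    head_tok = first.split(",")[0].strip()
    try:
        float(head_tok or "x")
        has_header = False
    except ValueError:
        has_header = True
    if has_header:
        df = pd.read_csv(path, index_col=0)
        names = [str(c) for c in df.columns]
        A = df.to_numpy()
    else:
        df = pd.read_csv(path, header=None)
        names = None
        A = df.to_numpy()
    if A.shape[0] != A.shape[1]:
        raise NetworkValidationError(
            f"{path}: adjacency must be square, got {A.shape}"
        )
    if not np.isin(A, (0, 1)).all():
        raise NetworkValidationError(f"{path}: entries must be 0 or 1")
    return DirectedNetwork(A, names)


def save_adjacency_csv(net: DirectedNetwork, path) -> None:
    if net.node_names is not None:
        pd.DataFrame(
            net.adjacency, index=net.node_names, columns=net.node_names
        ).to_csv(path)
    else:
        pd.DataFrame(net.adjacency).to_csv(path, header=False, index=False)


def load_graphml(path) -> DirectedNetwork:
    """Read a directed GraphML file (nodes, edges, optional "role" attr)."""
    g = nx.read_graphml(path)
    if not g.is_directed():
        raise NetworkValidationError(f"{path}: GraphML graph must be directed")
    names = list(g.nodes)
    index = {nm: i for i, nm in enumerate(names)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    for u, v in edges:
        if u == v:
            raise NetworkValidationError(
                f"{path}: self-loop on node {names[u]}"
            )
    net = _finish_edges(edges, len(names), [str(n) for n in names], str(path))
    role_attrs = nx.get_node_attributes(g, "role")
    if role_attrs:
        roles = [role_attrs.get(nm, "inter") for nm in g.nodes]
        net = assign_roles(net, roles)
    return net


def save_graphml(net: DirectedNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def load_role_table(path) -> list[tuple[str, str]]:
    """Read a two-column ``node role`` table; returns (node, role) pairs."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise NetworkValidationError(
                    f"{path}:{lineno}: expected two columns, got {line!r}"
                )
            rows.append((parts[0], parts[1]))
    return rows


def save_role_table(net: DirectedNetwork, path) -> None:
    r = net._roles_required()
    with open(path, "w") as fh:
        fh.write("# node\trole\n")
        for i in range(net.n_nodes):
            fh.write(f"{net._label(i)}\t{r[i]}\n")


# -- role assignment and node removal -------------------------------------


def assign_roles(
    net: DirectedNetwork,
    roles: Sequence[str] | Iterable[tuple[str, str]] | str,
) -> DirectedNetwork:
    """Return a copy of *net* with polarity roles set.

    ``roles`` may be a per-node sequence of role tokens (positional), a
    path to a two-column role table, or an iterable of ``(node, role)``
    pairs keyed by node name or index.  Exactly one role per node is
    required; the adjacency is untouched.
    """
    if isinstance(roles, str):
        roles = load_role_table(roles)
    roles = list(roles)
    per_node: np.ndarray = np.empty(net.n_nodes, dtype=object)
    if roles and isinstance(roles[0], tuple):
        seen = np.zeros(net.n_nodes, dtype=bool)
        for node, role in roles:  # type: ignore[misc]
            i = net.index_of(node)
            per_node[i] = role
            seen[i] = True
        if not seen.all():
            missing = net._label(int(np.flatnonzero(~seen)[0]))
            raise NetworkValidationError(f"no role given for node {missing}")
    else:
        if len(roles) != net.n_nodes:
            raise NetworkValidationError(
                f"{len(roles)} roles for {net.n_nodes} nodes"
            )
        per_node[:] = roles
    return DirectedNetwork(
        net.adjacency.copy(),
        list(net.node_names) if net.node_names is not None else None,
        per_node,
    )


def subnetwork_without(
    net: DirectedNetwork, nodes: Iterable[int | str]
) -> DirectedNetwork:
    """Remove a set of nodes and all their incident edges.

    Names and roles of the remaining nodes carry over; removing an
    input or output node shrinks the corresponding role set.
    """
    drop = sorted({net.index_of(x) for x in nodes})
    keep = np.setdiff1d(np.arange(net.n_nodes), drop)
    A = net.adjacency[np.ix_(keep, keep)]
    names = (
        [net.node_names[i] for i in keep]
        if net.node_names is not None
        else None
    )
    roles = net.roles[keep] if net.roles is not None else None
    return DirectedNetwork(A, names, roles)
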