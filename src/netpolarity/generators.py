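"""Seeded generators: ring lattices, small-world and random networks,
polarity-assignment schemes, and hub planting.

The generators reproduce the model-network families the propagation
analysis is calibrated on:

* a directed ring lattice (RL) with an arbitrary edge count, laid out
  over nearest neighbours as evenly as possible;
* a directed Watts–Strogatz small-world network (SW): the ring lattice
  with each edge head independently rewired with probability ``p``;
* an Erdős–Rényi random network (ER) with independent edges.

Polarity schemes mirror the experimental manipulations: uniformly
random role sets, contiguous input/output arcs on opposite sides of the
ring, random/separated/reversed reassignment of existing roles, and
planting of provincial / connector / kinless hubs by re-targeting
existing edges (node and edge counts conserved).

All functions are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import DirectedNetwork, NetworkValidationError, RoleCounts

__all__ = [
    "SWConfig",
    "ERConfig",
    "HubPlantConfig",
    "make_ring_lattice",
    "make_small_world",
    "make_er",
    "assign_io_random",
    "assign_io_opposite_clusters",
    "reassign_io",
    "plant_hubs",
]

#: default network size matched to the C. elegans somatic connectome
DEFAULT_N_NODES = 279
DEFAULT_N_EDGES = 2194
#: ER connection probability giving ~2194 expected edges on 279 nodes
DEFAULT_ER_P = 0.0283
#: role sizes: sensory (input), interneuron, motor (output)
DEFAULT_ROLE_COUNTS = RoleCounts(88, 82, 109)


@dataclass
class SWConfig:
    """Directed Watts–Strogatz small-world network parameters."""

    n_nodes: int = DEFAULT_N_NODES
    n_edges: int = DEFAULT_N_EDGES
    rewiring_p: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rewiring_p <= 1.0:
            raise ValueError(f"rewiring_p must be in [0,1], got {self.rewiring_p}")
        if self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError("n_edges exceeds n_nodes*(n_nodes-1)")


@dataclass
class ERConfig:
    """Erdős–Rényi random network parameters (self-loops forbidden)."""

    n_nodes: int = DEFAULT_N_NODES
    connection_p: float = DEFAULT_ER_P
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.connection_p <= 1.0:
            raise ValueError(
                f"connection_p must be in [0,1], got {self.connection_p}"
            )


@dataclass
class HubPlantConfig:
    """Parameters for planting hubs of a given class into a network.

    ``hub_total_degree`` is the in+out degree each planted hub is raised
    to by re-targeting existing edges; planting conserves node and edge
    counts.
    """

    n_hubs: int = 15
    hub_class: str = "kinless"
    hub_total_degree: int = 40
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.hub_class not in ("provincial", "connector", "kinless"):
            raise ValueError(f"unknown hub class {self.hub_class!r}")


def _ring_offsets(k: int) -> list[int]:
    """First k ring offsets alternating sides: +1, -1, +2, -2, ..."""
    out = []
    step = 1
    while len(out) < k:
        out.append(step)
        if len(out) < k:
            out.append(-step)
        step += 1
    return out


def make_ring_lattice(
    n_nodes: int = DEFAULT_N_NODES,
    n_edges: int = DEFAULT_N_EDGES,
    seed: int | None = None,
) -> DirectedNetwork:
    """Directed ring lattice with exactly ``n_edges`` edges.

    Every node sends ``floor(n_edges / n_nodes)`` out-edges to its
    nearest ring neighbours, alternating sides (1st clockwise, 1st
    counter-clockwise, 2nd clockwise, ...).  The remaining
    ``n_edges mod n_nodes`` out-edges go to the next-nearest unused
    neighbour of nodes drawn uniformly without replacement (seeded), so
    the out-degree is as even as possible: every node has ``floor`` or
    ``ceil`` of the mean out-degree.
    """
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError("n_edges exceeds n_nodes*(n_nodes-1)")
    k, extra = divmod(n_edges, n_nodes)
    if k >= n_nodes:  # alternating offsets would wrap onto the diagonal
        raise ValueError("edge count too dense for a ring layout")
    A = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    offsets = _ring_offsets(k)
    for off in offsets:
        idx = np.arange(n_nodes)
        A[idx, (idx + off) % n_nodes] = 1
    if extra:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(n_nodes, size=extra, replace=False)
        next_off = _ring_offsets(k + 1)[k]
        A[chosen, (chosen + next_off) % n_nodes] = 1
    return DirectedNetwork(A)


def make_small_world(cfg: SWConfig) -> DirectedNetwork:
    """Directed Watts–Strogatz small-world network.

    Starts from :func:`make_ring_lattice` and, independently with
    probability ``rewiring_p``, re-targets the head of each edge to a
    uniformly random node, redrawing on self-loops and duplicates.
    The edge count is conserved exactly.
    """
    # the lattice consumes cfg.seed directly so that p=0 reproduces
    # make_ring_lattice(seed) exactly; rewiring uses a derived stream
    net = make_ring_lattice(cfg.n_nodes, cfg.n_edges, cfg.seed)
    rng = np.random.default_rng(
        None if cfg.seed is None else [cfg.seed, 0x5757]
    )
    A = net.adjacency
    n = cfg.n_nodes
    tails, heads = np.nonzero(A)
    for t, h in zip(tails, heads):
        if rng.random() >= cfg.rewiring_p:
            continue
        A[t, h] = 0
        while True:
            new_h = int(rng.integers(n))
            if new_h != t and not A[t, new_h]:
                break
        A[t, new_h] = 1
    return DirectedNetwork(A)


def make_er(cfg: ERConfig) -> DirectedNetwork:
    """Erdős–Rényi random digraph: each ordered non-self pair is an edge
    independently with probability ``connection_p``."""
    rng = np.random.default_rng(cfg.seed)
    A = (rng.random((cfg.n_nodes, cfg.n_nodes)) < cfg.connection_p).astype(
        np.int8
    )
    np.fill_diagonal(A, 0)
    return DirectedNetwork(A)


# -- polarity assignment --------------------------------------------------


def _check_counts(n_nodes: int, counts: RoleCounts) -> None:
    if counts.n_input + counts.n_inter + counts.n_output != n_nodes:
        raise NetworkValidationError(
            f"role counts {tuple(counts)} do not sum to n_nodes={n_nodes}"
        )
    if min(counts) < 0:
        raise NetworkValidationError("role counts must be nonnegative")


def assign_io_random(
    net: DirectedNetwork,
    counts: RoleCounts = DEFAULT_ROLE_COUNTS,
    seed: int | None = None,
) -> DirectedNetwork:
    """Uniformly random disjoint input/inter/output sets of given sizes."""
    counts = RoleCounts(*counts)
    _check_counts(net.n_nodes, counts)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(net.n_nodes)
    roles = np.empty(net.n_nodes, dtype=object)
    roles[perm[: counts.n_input]] = "input"
    roles[perm[counts.n_input : counts.n_input + counts.n_inter]] = "inter"
    roles[perm[counts.n_input + counts.n_inter :]] = "output"
    return DirectedNetwork(
        net.adjacency.copy(),
        list(net.node_names) if net.node_names is not None else None,
        roles,
    )


def assign_io_opposite_clusters(
    net: DirectedNetwork,
    counts: RoleCounts = DEFAULT_ROLE_COUNTS,
    seed: int | None = None,
) -> DirectedNetwork:
    """Contiguous input and output arcs on opposite sides of the ring.

    Node indices are taken as ring positions (meaningful for RL/SW
    networks).  Inputs occupy one contiguous arc, outputs the
    diametrically opposite arc, and the two internode arcs in between
    split the remaining nodes (ties toward the clockwise arc).  The
    seeded rotation randomises where the input arc starts.
    """
    counts = RoleCounts(*counts)
    _check_counts(net.n_nodes, counts)
    if counts.n_input == 0 or counts.n_output == 0:
        raise NetworkValidationError(
            "opposite-cluster polarity needs nonempty input and output arcs"
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(net.n_nodes))
    inter_cw = (counts.n_inter + 1) // 2
    layout = (
        ["input"] * counts.n_input
        + ["inter"] * inter_cw
        + ["output"] * counts.n_output
        + ["inter"] * (counts.n_inter - inter_cw)
    )
    roles = np.empty(net.n_nodes, dtype=object)
    for pos, role in enumerate(layout):
        roles[(start + pos) % net.n_nodes] = role
    return DirectedNetwork(
        net.adjacency.copy(),
        list(net.node_names) if net.node_names is not None else None,
        roles,
    )


def reassign_io(
    net: DirectedNetwork,
    scheme: str,
    partition=None,
    seed: int | None = None,
) -> DirectedNetwork:
    """Reassign existing polarity roles by one of three schemes.

    ``rand``
        Roles redrawn uniformly at random, class sizes preserved.
    ``separated``
        Modules of ``partition`` are labelled input-side or output-side;
        input roles are drawn only within input-side modules and output
        roles only within output-side modules (sizes preserved), so no
        module mixes inputs and outputs.
    ``reversed``
        Input and output roles are interchanged; inter unchanged.
    """
    counts = net.role_counts()
    if scheme == "rand":
        return assign_io_random(net, counts, seed)
    if scheme == "reversed":
        roles = net.roles.copy()
        roles[net.input_nodes] = "output"
        roles[net.output_nodes] = "input"
        return DirectedNetwork(
            net.adjacency.copy(),
            list(net.node_names) if net.node_names is not None else None,
            roles,
        )
    if scheme == "separated":
        if partition is None:
            raise NetworkValidationError(
                "scheme='separated' requires a ModulePartition"
            )
        return _separated_io(net, counts, partition, seed)
    raise ValueError(f"unknown reassignment scheme {scheme!r}")


def _separated_io(net, counts: RoleCounts, partition, seed) -> DirectedNetwork:
    rng = np.random.default_rng(seed)
    module_of = np.asarray(partition.module_of)
    mods = np.unique(module_of)
    sizes = {m: int((module_of == m).sum()) for m in mods}
    # Label each module input-side or output-side so that each side has
    # enough nodes; greedy by decreasing size onto the needier side,
    # over seeded shuffles in case of near-tight splits.
    for _ in range(200):
        order = sorted(mods, key=lambda m: sizes[m], reverse=True)
        rng.shuffle(mods)  # tie-break variety across attempts
        cap_in = cap_out = 0
        side: dict[int, str] = {}
        for m in order:
            deficit_in = counts.n_input - cap_in
            deficit_out = counts.n_output - cap_out
            if deficit_in >= deficit_out:
                side[m] = "in"
                cap_in += sizes[m]
            else:
                side[m] = "out"
                cap_out += sizes[m]
        if cap_in >= counts.n_input and cap_out >= counts.n_output:
            break
    else:
        raise NetworkValidationError(
            "separated I/O infeasible: no module split provides "
            f"{counts.n_input} input and {counts.n_output} output slots "
            f"(module sizes {sorted(sizes.values(), reverse=True)})"
        )
    roles = np.full(net.n_nodes, "inter", dtype=object)
    in_pool = np.flatnonzero([side[m] == "in" for m in module_of])
    out_pool = np.flatnonzero([side[m] == "out" for m in module_of])
    roles[rng.choice(in_pool, counts.n_input, replace=False)] = "input"
    roles[rng.choice(out_pool, counts.n_output, replace=False)] = "output"
    return DirectedNetwork(
        net.adjacency.copy(),
        list(net.node_names) if net.node_names is not None else None,
        roles,
    )


# -- hub planting ---------------------------------------------------------


def _select_hub_nodes(
    cfg: HubPlantConfig, partition, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw hub nodes uniformly, but (for classes that concentrate links
    within the hub's own module) only from modules large enough to
    absorb ~half the degree target in each direction."""
    if cfg.hub_class == "kinless":
        return rng.choice(n, size=cfg.n_hubs, replace=False)
    module_of = np.asarray(partition.module_of)
    sizes = {m: int((module_of == m).sum()) for m in np.unique(module_of)}
    # distinct own-module partners needed per direction: provincial
    # hubs place every link in-module, connectors half
    frac = 2 if cfg.hub_class == "provincial" else 4
    need = -(-cfg.hub_total_degree // frac)
    hubs: list[int] = []
    hubs_in: dict[int, int] = {m: 0 for m in sizes}
    for _ in range(cfg.n_hubs):
        eligible = [
            v
            for v in range(n)
            if v not in hubs
            and sizes[module_of[v]] - 1 - hubs_in[module_of[v]] >= need
        ]
        if not eligible:
            raise NetworkValidationError(
                f"cannot place {cfg.n_hubs} {cfg.hub_class} hubs of degree "
                f"{cfg.hub_total_degree}: no module has enough free nodes"
            )
        v = int(rng.choice(eligible))
        hubs.append(v)
        hubs_in[module_of[v]] += 1
    return np.asarray(hubs)


def plant_hubs(
    net: DirectedNetwork,
    cfg: HubPlantConfig,
    partition,
    hub_nodes: Sequence[int] | None = None,
) -> tuple[DirectedNetwork, np.ndarray]:
    """Plant ``n_hubs`` hubs of a given class by re-targeting edges.

    The designated nodes are *replaced* by hubs: their existing links
    are removed, and each hub is rebuilt to exactly
    ``hub_total_degree`` (in+out) with partners chosen per class —
    provincial hubs connect only within their own module, kinless hubs
    uniformly over the whole network, connector hubs 50/50.  Every
    link added beyond those freed is paid for by harvesting an edge
    between two non-hub nodes, drawn uniformly from the wiring of the
    opposite locality to what the class creates: provincial and
    connector hubs (which anchor modules) consume inter-module edges,
    kinless hubs consume intra-module edges — planting thus re-routes
    background wiring through the hubs rather than shifting the
    network's density.  Node and edge counts are conserved exactly;
    in- and out-edges are added alternately so hubs gain balanced
    degree.

    Returns the perturbed network and the array of hub node indices.
    """
    rng = np.random.default_rng(cfg.seed)
    n = net.n_nodes
    if cfg.n_hubs > n:
        raise NetworkValidationError("more hubs requested than nodes")
    if hub_nodes is None:
        hubs = _select_hub_nodes(cfg, partition, n, rng)
    else:
        hubs = np.asarray([net.index_of(h) for h in hub_nodes])
    hub_set = set(int(h) for h in hubs)
    A = net.adjacency.copy()
    module_of = np.asarray(partition.module_of)

    def degree(v: int) -> int:
        return int(A[v, :].sum() + A[:, v].sum())

    def saturated(v: int) -> bool:
        return v in hub_set and degree(v) >= cfg.hub_total_degree

    def pick_partner(hub: int) -> int | None:
        """Partner per class; other hubs are allowed until they reach
        their own degree target (keeping every hub's final degree
        exact)."""
        if cfg.hub_class == "provincial":
            own = True
        elif cfg.hub_class == "kinless":
            own = False
        else:  # connector
            own = rng.random() < 0.5
        if own:
            pool = np.flatnonzero(module_of == module_of[hub])
            pool = pool[pool != hub]
            if pool.size == 0:
                raise NetworkValidationError(
                    f"hub {hub} is alone in its module; cannot plant "
                    "provincial links"
                )
            w = int(pool[rng.integers(pool.size)])
        else:
            w = int(rng.integers(n))
            if w == hub:
                return None
        return None if saturated(w) else w

    # strip every designated hub's existing links first; the freed edge
    # budget pays for part of the rebuilt hub degree
    hub_list = list(hub_set)
    freed = int(A[hub_list, :].sum() + A[:, hub_list].sum())
    freed -= int(A[np.ix_(hub_list, hub_list)].sum())  # hub-hub counted once
    A[hub_list, :] = 0
    A[:, hub_list] = 0
    budget = freed  # edges we may add without harvesting

    harvest_intra = cfg.hub_class == "kinless"

    def harvest() -> None:
        tails, heads = np.nonzero(A)
        ok = ~(np.isin(tails, hub_list) | np.isin(heads, hub_list))
        same = module_of[tails] == module_of[heads]
        pref = ok & (same if harvest_intra else ~same)
        if pref.any():
            ok = pref
        cand = np.flatnonzero(ok)
        if cand.size == 0:
            raise NetworkValidationError(
                "no non-hub edges left to harvest for hub planting"
            )
        pick = int(cand[rng.integers(cand.size)])
        A[tails[pick], heads[pick]] = 0

    for hub in hubs:
        hub = int(hub)
        want_out = True
        attempts = 0
        while degree(hub) < cfg.hub_total_degree:
            attempts += 1
            if attempts > 100 * cfg.hub_total_degree:
                raise NetworkValidationError(
                    f"hub degree target {cfg.hub_total_degree} infeasible "
                    f"for node {hub} ({cfg.hub_class})"
                )
            w = pick_partner(hub)
            if w is None:
                continue
            new_edge = (hub, w) if want_out else (w, hub)
            if A[new_edge]:
                continue
            if budget > 0:
                budget -= 1
            else:
                harvest()
            A[new_edge] = 1
            want_out = not want_out
    for _ in range(budget):
        # freed more links than the hubs re-absorbed (small degree
        # target): return the surplus as uniform non-hub edges
        while True:
            u, v = int(rng.integers(n)), int(rng.integers(n))
            if u != v and u not in hub_set and v not in hub_set and not A[u, v]:
                A[u, v] = 1
                break
    out = DirectedNetwork(
        A,
        list(net.node_names) if net.node_names is not None else None,
        net.roles.copy() if net.roles is not None else None,
    )
    return out, hubs
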