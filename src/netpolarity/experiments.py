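"""Seeded multi-realization experiments: propagation baselines over
network ensembles, rewiring sweeps, polarity reassignment, and hub
planting / removal.

Every experiment derives child seeds deterministically from a master
seed, so each is reproducible bit-for-bit from (config, master_seed).
The canonical per-network summary is the level-2 pair (V2, H2): level 2
is the highest propagation level at which network families still
separate clearly (at levels 3-4 both degrees saturate near 1 for most
families).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .generators import (
    DEFAULT_ROLE_COUNTS,
    ERConfig,
    HubPlantConfig,
    SWConfig,
    assign_io_opposite_clusters,
    assign_io_random,
    make_er,
    make_ring_lattice,
    make_small_world,
    plant_hubs,
    reassign_io,
)
from .netstats import ModulePartition, find_modules
from .network import DirectedNetwork, NetworkValidationError, RoleCounts
from .propagation import propagation_profile

logger = logging.getLogger("netpolarity")

__all__ = [
    "ExperimentResult",
    "SweepResult",
    "child_seeds",
    "run_realizations",
    "aggregate",
    "sweep_rewiring",
    "hub_removal_sweep",
    "hub_creation_experiment",
    "io_reassignment_experiment",
    "modularity_overlay",
    "overlay_outside_fraction",
]

SUMMARY_LEVEL = 2


def child_seeds(master_seed: int | None, n: int) -> np.ndarray:
    """Deterministic per-realization seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n, dtype=np.uint32) % (2**31)


@dataclass
class ExperimentResult:
    """Propagation summary of one seeded realization."""

    network_label: str
    realization_seed: int
    levels: list[int]
    V: list[float | None]
    H: list[float]
    metadata: dict = field(default_factory=dict)

    @property
    def V2(self) -> float | None:
        return self.V[SUMMARY_LEVEL] if len(self.V) > SUMMARY_LEVEL else None

    @property
    def H2(self) -> float | None:
        return self.H[SUMMARY_LEVEL] if len(self.H) > SUMMARY_LEVEL else None


@dataclass
class SweepResult:
    """Per-step (V2, H2) aggregates of a perturbation sweep.

    Step 0 is the unperturbed network.
    """

    steps: list[int]
    v2_mean: list[float]
    v2_sd: list[float]
    h2_mean: list[float]
    h2_sd: list[float]
    n_undefined: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.steps,
                "V2_mean": self.v2_mean,
                "V2_sd": self.v2_sd,
                "H2_mean": self.h2_mean,
                "H2_sd": self.h2_sd,
                "n_undefined": self.n_undefined,
            }
        )


def _generate(family: str, gen_config, seed: int) -> DirectedNetwork:
    if family == "RL":
        cfg = gen_config or SWConfig(rewiring_p=0.0)
        return make_ring_lattice(cfg.n_nodes, cfg.n_edges, seed)
    if family == "SW":
        cfg = gen_config or SWConfig()
        return make_small_world(
            SWConfig(cfg.n_nodes, cfg.n_edges, cfg.rewiring_p, seed)
        )
    if family == "ER":
        cfg = gen_config or ERConfig()
        return make_er(ERConfig(cfg.n_nodes, cfg.connection_p, seed))
    raise ValueError(f"unknown network family {family!r}")


def _assign(
    net: DirectedNetwork,
    io_scheme: str,
    counts: RoleCounts,
    seed: int,
) -> DirectedNetwork:
    if io_scheme == "random":
        return assign_io_random(net, counts, seed)
    if io_scheme == "opposite":
        return assign_io_opposite_clusters(net, counts, seed)
    if io_scheme == "keep":
        if net.roles is None:
            raise NetworkValidationError(
                "io_scheme='keep' needs a network with roles"
            )
        return net
    raise ValueError(f"unknown io scheme {io_scheme!r}")


def run_realizations(
    family: str,
    gen_config=None,
    io_scheme: str = "random",
    role_counts: RoleCounts = DEFAULT_ROLE_COUNTS,
    n_realizations: int = 100,
    max_level: int = 4,
    master_seed: int | None = None,
    network: DirectedNetwork | None = None,
    label: str | None = None,
    include_new_nodes: bool = False,
) -> list[ExperimentResult]:
    """Propagation profiles over seeded realizations.

    For families RL/SW/ER a fresh network is generated per realization;
    for ``family='file'`` the supplied ``network`` is reused and only
    the (stochastic) role assignment varies per realization.
    """
    seeds = child_seeds(master_seed, 2 * n_realizations)
    results = []
    for r in range(n_realizations):
        gen_seed, io_seed = int(seeds[2 * r]), int(seeds[2 * r + 1])
        if family == "file":
            if network is None:
                raise NetworkValidationError("family='file' needs a network")
            net = network
        else:
            net = _generate(family, gen_config, gen_seed)
        net = _assign(net, io_scheme, role_counts, io_seed)
        prof = propagation_profile(
            net, max_level, include_new_nodes=include_new_nodes
        )
        results.append(
            ExperimentResult(
                network_label=label or family,
                realization_seed=gen_seed,
                levels=prof.levels,
                V=prof.V,
                H=prof.H,
                metadata={
                    "family": family,
                    "io_scheme": io_scheme,
                    "io_seed": io_seed,
                    "gen_config": asdict(gen_config) if gen_config else None,
                    "new_nodes_mean": prof.new_nodes_mean,
                    "mean_pathways": prof.mean_pathways,
                },
            )
        )
    return results


def aggregate(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """Per-level mean +- SD of V and H across realizations.

    Undefined V values (zero-variance channel matrices) are dropped
    from the V aggregates and counted in ``n_undefined``.
    """
    levels = results[0].levels
    rows = []
    for li, l in enumerate(levels):
        vs = [r.V[li] for r in results if li < len(r.V)]
        defined = [v for v in vs if v is not None]
        hs = [r.H[li] for r in results]
        rows.append(
            {
                "level": l,
                "V_mean": float(np.mean(defined)) if defined else np.nan,
                "V_sd": float(np.std(defined, ddof=1))
                if len(defined) > 1
                else np.nan,
                "n_undefined": len(vs) - len(defined),
                "H_mean": float(np.mean(hs)),
                "H_sd": float(np.std(hs, ddof=1)) if len(hs) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _v2h2(results: Sequence[ExperimentResult]) -> dict:
    v2 = [r.V2 for r in results]
    defined = [v for v in v2 if v is not None]
    h2 = [r.H2 for r in results]
    return {
        "V2_mean": float(np.mean(defined)) if defined else np.nan,
        "V2_sd": float(np.std(defined, ddof=1)) if len(defined) > 1 else np.nan,
        "H2_mean": float(np.mean(h2)),
        "H2_sd": float(np.std(h2, ddof=1)) if len(h2) > 1 else np.nan,
        "n_undefined": len(v2) - len(defined),
    }


def sweep_rewiring(
    p_values: Sequence[float],
    base_config: SWConfig | None = None,
    role_counts: RoleCounts = DEFAULT_ROLE_COUNTS,
    n_realizations: int = 100,
    max_level: int = 4,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """(V2, H2) as a function of the small-world rewiring probability.

    Traces the vertical/horizontal trade-off: locality (low p) favours
    vertical propagation, randomness (high p) horizontal.
    """
    base = base_config or SWConfig()
    rows = []
    for k, p in enumerate(sorted(p_values)):
        cfg = SWConfig(base.n_nodes, base.n_edges, p)
        res = run_realizations(
            "SW",
            cfg,
            "random",
            role_counts,
            n_realizations,
            max_level,
            None if master_seed is None else master_seed + k,
        )
        rows.append({"p": p, **_v2h2(res)})
    return pd.DataFrame(rows)


def hub_removal_sweep(
    net: DirectedNetwork,
    n_hubs: int = 15,
    max_level: int = 4,
    partition: ModulePartition | None = None,
) -> SweepResult:
    """Remove the top-degree hubs cumulatively, one per step.

    Hubs are ranked once on the intact network by total (in+out)
    degree (no re-ranking during the sweep).  After each removal V2/H2
    are recomputed on the reduced network; removed input/output nodes
    shrink the channel matrix.  The sweep stops early (with a logged
    reason) if a removal would empty the input or output set.

    The supplied network is deterministic here, so each step yields a
    single value; SDs are reported as 0 for interface uniformity with
    stochastic sweeps.
    """
    from .netstats import classify_hubs

    if net.roles is None:
        raise NetworkValidationError("hub removal needs polarity roles")
    part = partition or find_modules(net, seed=0)
    report = classify_hubs(net, part, n_hubs)
    order = [r.node for r in report]
    steps, v2m, v2s, h2m, h2s, nundef = [], [], [], [], [], []
    current = net
    removed: list[int] = []
    name_of = {i: net._label(i) for i in order}
    for step in range(n_hubs + 1):
        prof = propagation_profile(
            current, max_level, include_new_nodes=False
        )
        v2 = prof.V[SUMMARY_LEVEL]
        steps.append(step)
        v2m.append(np.nan if v2 is None else v2)
        v2s.append(0.0)
        h2m.append(prof.H[SUMMARY_LEVEL])
        h2s.append(0.0)
        nundef.append(int(v2 is None))
        if step == n_hubs:
            break
        removed.append(order[step])
        # rebuild from the intact network so original hub indices stay valid
        nxt = _remove_by_original_index(net, removed)
        counts = nxt.role_counts()
        if counts.n_input == 0 or counts.n_output == 0:
            logger.warning(
                "hub removal stopped after %d removals: input or output "
                "set exhausted",
                step,
            )
            break
        current = nxt
    logger.info(
        "hub removal order: %s", [name_of[i] for i in removed]
    )
    return SweepResult(steps, v2m, v2s, h2m, h2s, nundef)


def _remove_by_original_index(
    net: DirectedNetwork, removed: Sequence[int]
) -> DirectedNetwork:
    from .network import subnetwork_without

    return subnetwork_without(net, removed)


def hub_creation_experiment(
    base_config: SWConfig | None = None,
    hub_classes: Sequence[str] = ("provincial", "connector", "kinless"),
    hub_plant: HubPlantConfig | None = None,
    role_counts: RoleCounts = DEFAULT_ROLE_COUNTS,
    n_realizations: int = 100,
    max_level: int = 4,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Plant hubs of each class into fresh SW networks and compare
    (V2, H2) against the unplanted baseline.

    Per realization: generate an SW network, detect its modules, plant
    ``n_hubs`` hubs of the class by seeded edge re-targeting, randomly
    assign roles, and profile.  The baseline row uses the same
    generator seeds without planting.
    """
    base = base_config or SWConfig()
    plant_base = hub_plant or HubPlantConfig()
    rows = []
    baseline = run_realizations(
        "SW", base, "random", role_counts, n_realizations, max_level,
        master_seed, label="SW-baseline",
    )
    rows.append({"hub_class": "baseline", **_v2h2(baseline)})
    seeds = child_seeds(master_seed, 3 * n_realizations)
    for hub_class in hub_classes:
        results = []
        for r in range(n_realizations):
            gen_seed = int(seeds[3 * r])
            plant_seed = int(seeds[3 * r + 1])
            io_seed = int(seeds[3 * r + 2])
            net = make_small_world(
                SWConfig(base.n_nodes, base.n_edges, base.rewiring_p, gen_seed)
            )
            part = find_modules(net, seed=plant_seed, n_restarts=5)
            cfg = HubPlantConfig(
                plant_base.n_hubs,
                hub_class,
                plant_base.hub_total_degree,
                plant_seed,
            )
            planted, _hubs = plant_hubs(net, cfg, part)
            planted = assign_io_random(planted, role_counts, io_seed)
            prof = propagation_profile(
                planted, max_level, include_new_nodes=False
            )
            results.append(
                ExperimentResult(
                    f"SW-{hub_class}", gen_seed, prof.levels, prof.V, prof.H
                )
            )
        rows.append({"hub_class": hub_class, **_v2h2(results)})
    return pd.DataFrame(rows)


def io_reassignment_experiment(
    net: DirectedNetwork,
    schemes: Sequence[str] = ("original", "rand", "separated", "reversed"),
    n_realizations: int = 100,
    max_level: int = 4,
    master_seed: int | None = None,
    partition: ModulePartition | None = None,
) -> pd.DataFrame:
    """(V2, H2) of a polarised network under role-reassignment schemes.

    Deterministic schemes (original, reversed) run once; stochastic
    ones (rand, separated, opposite) run over seeded realizations.
    """
    if net.roles is None:
        raise NetworkValidationError("reassignment needs existing roles")
    part = partition
    seeds = child_seeds(master_seed, max(1, n_realizations))
    rows = []
    for scheme in schemes:
        if scheme == "original":
            variants = [net]
        elif scheme == "reversed":
            variants = [reassign_io(net, "reversed")]
        elif scheme in ("rand", "separated"):
            if scheme == "separated" and part is None:
                part = find_modules(net, seed=0)
            variants = [
                reassign_io(net, scheme, part, int(s)) for s in seeds
            ]
        elif scheme == "opposite":
            variants = [
                assign_io_opposite_clusters(net, net.role_counts(), int(s))
                for s in seeds
            ]
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        results = []
        for k, v in enumerate(variants):
            prof = propagation_profile(v, max_level, include_new_nodes=False)
            results.append(
                ExperimentResult(scheme, int(seeds[min(k, len(seeds) - 1)]),
                                 prof.levels, prof.V, prof.H)
            )
        rows.append({"scheme": scheme, **_v2h2(results),
                     "n_realizations": len(variants)})
    return pd.DataFrame(rows)


def plot_v2h2(points: pd.DataFrame, path, label_col: str | None = None) -> None:
    """Scatter networks on the V2-H2 plane (optional static image).

    ``points`` needs columns V2_mean / H2_mean and, if available,
    V2_sd / H2_sd for error bars.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    xerr = points["H2_sd"] if "H2_sd" in points else None
    yerr = points["V2_sd"] if "V2_sd" in points else None
    ax.errorbar(
        points["H2_mean"], points["V2_mean"], xerr=xerr, yerr=yerr,
        fmt="o", capsize=3,
    )
    if label_col and label_col in points:
        for _, row in points.iterrows():
            ax.annotate(str(row[label_col]),
                        (row["H2_mean"], row["V2_mean"]),
                        textcoords="offset points", xytext=(5, 5))
    ax.set_xlabel("H$_2$ (horizontal propagation)")
    ax.set_ylabel("V$_2$ (vertical propagation)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def modularity_overlay(
    net: DirectedNetwork, partition: ModulePartition
) -> pd.DataFrame:
    """Boolean input x output mask: does the channel share a module?

    Joinable to the channel matrices to ask how much high-level
    connectivity falls outside the level-0 module structure.
    """
    module_of = np.asarray(partition.module_of)
    inputs = net.input_nodes
    outputs = net.output_nodes
    mask = module_of[inputs][:, None] == module_of[outputs][None, :]
    names = net.node_names
    return pd.DataFrame(
        mask,
        index=[names[i] for i in inputs] if names else list(inputs),
        columns=[names[j] for j in outputs] if names else list(outputs),
    )


def overlay_outside_fraction(
    net: DirectedNetwork,
    partition: ModulePartition,
    level: int = 3,
) -> float:
    """Fraction of channels connected at ``level`` whose input and
    output nodes do NOT share a module."""
    from .propagation import channel_matrices

    cms = channel_matrices(net, level)
    conn = cms.connected(level)
    mask = modularity_overlay(net, partition).to_numpy()
    if conn.sum() == 0:
        return 0.0
    return float((conn & ~mask).sum() / conn.sum())
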