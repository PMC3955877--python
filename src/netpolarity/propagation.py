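"""Walk counting across propagation levels, channel connectivity
matrices, and vertical/horizontal propagation degrees.

Terminology
-----------
A *channel* is an ordered (input node, output node) pair.  The
*propagation level* ``l`` is the number of intermediate nodes on a
walk from an input to an output node, so a level-``l`` pathway is a
walk of length ``l + 1``; walks may revisit nodes (recurrent pathways
count).  The number of level-``l`` pathways between input ``i`` and
output ``j`` is the ``(i, j)`` entry of ``A^(l+1)``.

The channel connectivity matrix at level ``l`` is

    M(i, j)_l = log10( m(i, j)_l + b ),       b = 0.1 by default,

computed over all n_in x n_out channels; the small offset keeps the
logarithm finite on disconnected channels (m = 0 maps to -1).

From the matrices two propagation degrees are derived:

* **vertical** ``V_l``: the Pearson correlation between the flattened
  ``M_l`` and ``M_{l+1}``.  High values mean the input->output pattern
  has stabilised — each additional intermediate node multiplies
  pathway counts without reshaping the pattern.
* **horizontal** ``h(i)_l`` / ``H_l``: per input node, the fraction of
  output nodes reached by at least one pathway (cumulatively, at any
  level up to ``l``, by default); ``H_l`` averages over inputs.

Walk counts are kept in exact integer arithmetic throughout (counts
grow exponentially with level and would silently lose exactness in
float64 past 2**53); floats appear only inside the final log10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import DirectedNetwork, NetworkValidationError

__all__ = [
    "ChannelMatrixSet",
    "PropagationProfile",
    "UNDEFINED",
    "channel_matrices",
    "vertical_degree",
    "horizontal_profile",
    "cumulative_horizontal",
    "new_node_counts",
    "propagation_profile",
    "walk_count_matrix",
]

#: marker returned where a Pearson correlation has no defined value
#: (zero variance in one of the matrices); distinct from a valid 0.0
UNDEFINED = None

DEFAULT_B = 0.1

# int64 matrix products are exact as long as every accumulated dot
# product stays below 2**63; bound: n * max_entry_prev * max_entry_A
_INT64_SAFE = 2**62


def walk_count_matrix(net: DirectedNetwork, length: int) -> np.ndarray:
    """Exact ``A**length`` — the count of walks of that length between
    every ordered node pair.

    Uses int64 while provably overflow-free, switching to Python big
    integers (object dtype) beyond that, so counts are exact at any
    level.
    """
    if length < 1:
        raise ValueError("walk length must be >= 1")
    A = net.adjacency.astype(np.int64)
    out = A
    for _ in range(length - 1):
        out = _exact_matmul(out, A)
    return out


def _exact_matmul(X: np.ndarray, A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    if X.dtype == np.int64:
        bound = int(X.max(initial=0)) * int(A.max(initial=0)) * n
        if bound < _INT64_SAFE:
            return X @ A
        X = X.astype(object)
    return X @ A.astype(object)


@dataclass
class ChannelMatrixSet:
    """Raw and log-transformed channel connectivity matrices per level.

    ``raw_counts[l]`` is the n_in x n_out matrix of exact pathway
    counts ``m(i, j)_l`` (entries of ``A^(l+1)`` restricted to
    input rows / output columns); ``log_matrix[l]`` is
    ``log10(raw + b)``.
    """

    levels: list[int]
    raw_counts: list[np.ndarray]
    log_matrix: list[np.ndarray]
    b: float
    input_nodes: np.ndarray
    output_nodes: np.ndarray
    input_names: list[str] | None = None
    output_names: list[str] | None = None

    @property
    def n_in(self) -> int:
        return len(self.input_nodes)

    @property
    def n_out(self) -> int:
        return len(self.output_nodes)

    def level_index(self, l: int) -> int:
        try:
            return self.levels.index(l)
        except ValueError:
            raise NetworkValidationError(
                f"level {l} not computed (have {self.levels})"
            )

    def connected(self, l: int) -> np.ndarray:
        """Boolean mask of channels connected at level l (m != 0)."""
        raw = self.raw_counts[self.level_index(l)]
        return np.array([[x != 0 for x in row] for row in raw]) \
            if raw.dtype == object else raw != 0

    def to_long_frame(self):
        """All levels as one long table (input, output, level, count,
        log_value); counts of big-integer magnitude stay exact Python
        ints in an object column."""
        import pandas as pd

        rows = []
        in_labels = self.input_names or [str(i) for i in self.input_nodes]
        out_labels = self.output_names or [str(j) for j in self.output_nodes]
        for li, l in enumerate(self.levels):
            raw = self.raw_counts[li]
            logm = self.log_matrix[li]
            for a, ilab in enumerate(in_labels):
                for bcol, jlab in enumerate(out_labels):
                    rows.append(
                        (ilab, jlab, l, int(raw[a, bcol]), float(logm[a, bcol]))
                    )
        return pd.DataFrame(
            rows, columns=["input", "output", "level", "count", "log_value"]
        )

    def save_level_csv(self, l: int, path) -> None:
        import pandas as pd

        raw = self.raw_counts[self.level_index(l)]
        pd.DataFrame(
            raw,
            index=self.input_names or [str(i) for i in self.input_nodes],
            columns=self.output_names or [str(j) for j in self.output_nodes],
        ).to_csv(path)


def _log10_offset(raw: np.ndarray, b: float) -> np.ndarray:
    """log10(m + b) elementwise, exact-int safe for huge counts."""
    if raw.dtype != object:
        return np.log10(raw.astype(np.float64) + b)
    out = np.empty(raw.shape, dtype=np.float64)
    flat_in, flat_out = raw.ravel(), out.ravel()
    for k, m in enumerate(flat_in):
        if m < 2**53:
            flat_out[k] = math.log10(int(m) + b)
        else:  # b is negligible at this magnitude; log10 of int is exact-ish
            flat_out[k] = math.log10(m)
    return out


def channel_matrices(
    net: DirectedNetwork,
    max_level: int,
    b: float = DEFAULT_B,
) -> ChannelMatrixSet:
    """Channel connectivity matrices for levels 0..max_level.

    Level ``l`` holds the exact counts of walks of length ``l + 1``
    from each input node to each output node, plus their log transform
    ``M = log10(m + b)``.
    """
    if max_level < 0:
        raise ValueError("max_level must be >= 0")
    inputs = net.input_nodes
    outputs = net.output_nodes
    if inputs.size == 0 or outputs.size == 0:
        raise NetworkValidationError(
            "channel matrices need at least one input and one output node"
        )
    A = net.adjacency.astype(np.int64)
    power = A
    raw_list, log_list = [], []
    for l in range(max_level + 1):
        if l > 0:
            power = _exact_matmul(power, A)
        raw = power[np.ix_(inputs, outputs)].copy()
        raw_list.append(raw)
        log_list.append(_log10_offset(raw, b))
    names = net.node_names
    return ChannelMatrixSet(
        levels=list(range(max_level + 1)),
        raw_counts=raw_list,
        log_matrix=log_list,
        b=b,
        input_nodes=inputs,
        output_nodes=outputs,
        input_names=[names[i] for i in inputs] if names else None,
        output_names=[names[j] for j in outputs] if names else None,
    )


def vertical_degree(cms: ChannelMatrixSet, l: int) -> float | None:
    """Degree of vertical propagation V_l.

    Pearson correlation between the flattened log matrices of levels
    ``l`` and ``l + 1`` over all channels.  Returns :data:`UNDEFINED`
    (None) when either matrix has zero variance — the correlation is
    mathematically undefined there and is flagged rather than imputed.
    """
    x = cms.log_matrix[cms.level_index(l)].ravel()
    y = cms.log_matrix[cms.level_index(l + 1)].ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return UNDEFINED
    return float(stats.pearsonr(x, y).statistic)


def horizontal_profile(
    cms: ChannelMatrixSet, l: int
) -> tuple[np.ndarray, float]:
    """Strict per-level horizontal propagation.

    ``h(i)_l`` = fraction of output nodes with at least one level-l
    pathway from input i; returns (h per input, mean H_l).
    """
    conn = cms.connected(l)
    h = conn.mean(axis=1)
    return h, float(h.mean())


def cumulative_horizontal(
    cms: ChannelMatrixSet, l: int
) -> tuple[np.ndarray, float]:
    """Cumulative horizontal propagation: a channel counts as connected
    if it has a pathway at ANY level up to and including ``l``.

    This is the default reading of "outputs that have been connected by
    level l" and is monotone non-decreasing in the level.
    """
    cms.level_index(l)  # validate
    conn = np.zeros((cms.n_in, cms.n_out), dtype=bool)
    for k in cms.levels:
        if k > l:
            break
        conn |= cms.connected(k)
    h = conn.mean(axis=1)
    return h, float(h.mean())


def new_node_counts(
    net: DirectedNetwork, max_level: int
) -> np.ndarray:
    """Mean number of NEW intermediate nodes entering the pathways of a
    channel at each level.

    For channel (i, j) and level l the participating set is
    ``S_l = {v : some split a in [1..l] has a walk i->v of length a and
    a walk v->j of length l+1-a}``; the new nodes at level l are those
    of ``S_l`` not seen at any lower level.  Level 0 pathways have no
    intermediate nodes, so the level-0 entry is 0.  Returns the
    per-level mean over all channels, for levels 0..max_level.
    """
    inputs = net.input_nodes
    outputs = net.output_nodes
    if inputs.size == 0 or outputs.size == 0:
        raise NetworkValidationError(
            "new-node counting needs input and output nodes"
        )
    n = net.n_nodes
    A = net.adjacency.astype(bool)
    # boolean reachability by exactly-k-step walks, k = 1..max_level+1
    reach = [A]
    for _ in range(max_level):
        reach.append((reach[-1].astype(np.int64) @ A.astype(np.int64)) > 0)
    means = np.zeros(max_level + 1)
    seen = np.zeros((inputs.size, outputs.size, n), dtype=bool)
    for l in range(1, max_level + 1):
        part = np.zeros_like(seen)
        for a in range(1, l + 1):
            fwd = reach[a - 1][inputs, :]          # i -> v in a steps
            bwd = reach[l - a][:, outputs]         # v -> j in l+1-a steps
            part |= fwd[:, None, :] & bwd.T[None, :, :]
        new = part & ~seen
        means[l] = new.sum(axis=2).mean()
        seen |= part
    return means


@dataclass
class PropagationProfile:
    """Per-level summary of a polarised network's propagation."""

    levels: list[int]
    V: list[float | None] = field(default_factory=list)
    h_per_input: list[np.ndarray] = field(default_factory=list)
    H: list[float] = field(default_factory=list)
    new_nodes_mean: list[float] = field(default_factory=list)
    mean_pathways: list[float] = field(default_factory=list)

    @property
    def v_levels(self) -> list[int]:
        """Levels at which V is reported (needs level l+1): 0..L-1."""
        return self.levels[:-1]


def propagation_profile(
    net: DirectedNetwork,
    max_level: int = 4,
    b: float = DEFAULT_B,
    cumulative: bool = True,
    include_new_nodes: bool = True,
) -> PropagationProfile:
    """Full propagation profile of a polarised network.

    Bundles the channel matrices with the vertical degree V_l
    (levels 0..max_level-1), the horizontal degree H_l and its
    per-input components (cumulative by default), the mean number of
    new intermediate nodes per level, and the mean pathway count per
    channel per level.
    """
    cms = channel_matrices(net, max_level, b)
    prof = PropagationProfile(levels=list(cms.levels))
    for l in cms.levels[:-1]:
        prof.V.append(vertical_degree(cms, l))
    for l in cms.levels:
        h, H = (
            cumulative_horizontal(cms, l)
            if cumulative
            else horizontal_profile(cms, l)
        )
        prof.h_per_input.append(h)
        prof.H.append(H)
        raw = cms.raw_counts[cms.level_index(l)]
        total = int(sum(int(x) for x in raw.ravel()))
        prof.mean_pathways.append(total / raw.size)
    if include_new_nodes:
        prof.new_nodes_mean = list(new_node_counts(net, max_level))
    return prof
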