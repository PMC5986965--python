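"""Back-projection of discriminative weights to connections, seeds, networks.

The PCA loadings are linear coefficients over the selected FC features,
so each selected connection can be scored by the magnitude of its
coefficients.  Two weighting modes:

* ``loading_magnitude`` (default) — a connection's weight on component
  c is |loading|; the aggregate is the mean over the kept components;
* ``svm_backprojection`` — the SVM score-space weights are pushed back
  through the loadings, giving |Σ_c w_c · loading_fc| per connection.

Seed weights follow the half-split rule: each connection donates half
its weight to each endpoint; a seed's cumulative weight is the mean of
the half-weights it receives over its discriminating connections (so
total *summed* seed weight equals total connection weight —
conservation).  Connections are further partitioned into strengthened
vs weakened (sign of the post − pre group-mean change, on the signed
correlation scale) × motor vs non-motor (at least one endpoint in a
motor network).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import SeedAtlas
from .classify import SvmModel
from .connectivity import devectorize, index_to_pair
from .features import PcaBasis

__all__ = [
    "ConnectionWeightTable",
    "SeedWeightTable",
    "DirectionPartition",
    "connection_weights",
    "seed_weights",
    "direction_partition",
    "partition_table",
    "network_involvement",
    "write_edge_file",
]


@dataclass
class ConnectionWeightTable:
    """Per-selected-connection importance weights."""

    connection_indices: np.ndarray  # original FC-vector indices
    seed_i: np.ndarray
    seed_j: np.ndarray
    component_weights: np.ndarray  # m_selected × k
    aggregate: np.ndarray  # mean over kept components
    weighting_mode: str

    def as_frame(self, atlas: SeedAtlas | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "connection_index": self.connection_indices,
                "seed_i": self.seed_i,
                "seed_j": self.seed_j,
                "weight": self.aggregate,
            }
        )
        if atlas is not None:
            df["network_i"] = [atlas.network_of(int(i)) for i in self.seed_i]
            df["network_j"] = [atlas.network_of(int(j)) for j in self.seed_j]
        return df


@dataclass
class SeedWeightTable:
    seed_ids: np.ndarray
    cumulative_weight: np.ndarray  # mean of received half-weights
    half_weight_sum: np.ndarray  # summed half-weights (conserved quantity)
    n_connections: np.ndarray
    rank: np.ndarray  # 1 = highest cumulative weight

    def as_frame(self, atlas: SeedAtlas | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "seed_id": self.seed_ids,
                "rank": self.rank,
                "cumulative_weight": self.cumulative_weight,
                "half_weight_sum": self.half_weight_sum,
                "n_connections": self.n_connections,
            }
        )
        if atlas is not None:
            df["label"] = [atlas.seeds[int(i)].label for i in self.seed_ids]
            df["network"] = [atlas.network_of(int(i)) for i in self.seed_ids]
        return df.sort_values("rank").reset_index(drop=True)


def connection_weights(
    basis: PcaBasis,
    selected_indices: np.ndarray,
    s: int,
    model: SvmModel | None = None,
    mode: str = "loading_magnitude",
) -> ConnectionWeightTable:
    """Score each selected connection from the PCA loadings (and SVM).

    ``selected_indices`` are original FC-vector indices (aligned with
    the rows of ``basis.loadings``); ``s`` is the seed count behind that
    indexing.
    """
    selected_indices = np.asarray(selected_indices, dtype=int)
    k = basis.n_components_kept
    load = basis.loadings[:, :k]
    if load.shape[0] != selected_indices.size:
        raise ValueError("loadings rows must match the selected connections")
    if mode == "loading_magnitude":
        comp = np.abs(load)
        aggregate = comp.mean(axis=1)
    elif mode == "svm_backprojection":
        if model is None:
            raise ValueError("svm_backprojection mode requires a fitted SvmModel")
        contrib = load * model.weights[None, :k]
        comp = contrib
        aggregate = np.abs(contrib.sum(axis=1))
    else:
        raise ValueError(f"unknown weighting mode {mode!r}")
    i, j = index_to_pair(selected_indices, s)
    return ConnectionWeightTable(
        connection_indices=selected_indices,
        seed_i=np.asarray(i),
        seed_j=np.asarray(j),
        component_weights=comp,
        aggregate=aggregate,
        weighting_mode=mode,
    )


def seed_weights(conn: ConnectionWeightTable, atlas: SeedAtlas) -> SeedWeightTable:
    """Half-split connection weights onto seeds; cumulative = mean half-weight."""
    s = atlas.n_seeds
    if conn.seed_i.size and (conn.seed_i.min() < 0 or conn.seed_j.max() >= s):
        raise ValueError("connection endpoints outside the atlas")
    sums = np.zeros(s)
    counts = np.zeros(s, dtype=int)
    half = conn.aggregate / 2.0
    np.add.at(sums, conn.seed_i, half)
    np.add.at(sums, conn.seed_j, half)
    np.add.at(counts, conn.seed_i, 1)
    np.add.at(counts, conn.seed_j, 1)
    with np.errstate(invalid="ignore"):
        cumulative = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    order = np.argsort(-cumulative, kind="stable")
    rank = np.empty(s, dtype=int)
    rank[order] = np.arange(1, s + 1)
    return SeedWeightTable(
        seed_ids=np.arange(s),
        cumulative_weight=cumulative,
        half_weight_sum=sums,
        n_connections=counts,
        rank=rank,
    )


@dataclass
class DirectionPartition:
    """Strengthened/weakened × motor/non-motor breakdown of selected connections."""

    connection_indices: np.ndarray
    direction: np.ndarray  # "strengthened" | "weakened"
    motor: np.ndarray  # boolean, ≥1 endpoint in a motor network
    counts: np.ndarray  # 2×2 rows (strengthened, weakened) × cols (motor, non-motor)

    def summary(self) -> pd.DataFrame:
        c = self.counts
        return pd.DataFrame(
            {
                "Motor": [c[0, 0], c[1, 0], c[:, 0].sum()],
                "Non-motor": [c[0, 1], c[1, 1], c[:, 1].sum()],
                "Total": [c[0].sum(), c[1].sum(), c.sum()],
            },
            index=["Strengthened", "Weakened", "Overall"],
        )


def partition_table(counts: np.ndarray | list) -> pd.DataFrame:
    """Margins of a 2×2 (strengthened/weakened × motor/non-motor) count table."""
    c = np.asarray(counts, dtype=int)
    if c.shape != (2, 2) or np.any(c < 0):
        raise ValueError("counts must be a nonnegative 2×2 table")
    return DirectionPartition(
        connection_indices=np.array([], dtype=int),
        direction=np.array([]),
        motor=np.array([], dtype=bool),
        counts=c,
    ).summary()


def direction_partition(
    x_pre: np.ndarray,
    x_post: np.ndarray,
    selected_indices: np.ndarray,
    atlas: SeedAtlas,
    motor_networks=None,
    magnitude: bool = False,
) -> DirectionPartition:
    """Classify each selected connection by group-mean change and motor class.

    Strengthened iff mean(post) − mean(pre) > 0 on the signed
    correlation scale (``magnitude=True`` compares |mean| instead).
    Exact zero changes — impossible for continuous data — are labeled
    weakened with a warning.
    """
    selected_indices = np.asarray(selected_indices, dtype=int)
    if selected_indices.size == 0:
        raise ValueError("selection is empty")
    mu_pre = np.asarray(x_pre, float)[:, selected_indices].mean(axis=0)
    mu_post = np.asarray(x_post, float)[:, selected_indices].mean(axis=0)
    if magnitude:
        diff = np.abs(mu_post) - np.abs(mu_pre)
    else:
        diff = mu_post - mu_pre
    if np.any(diff == 0):
        warnings.warn("exact-tie group-mean change classified as weakened", stacklevel=2)
    strengthened = diff > 0
    p = x_pre.shape[1]
    # infer seed count behind the FC indexing from the vector length
    s = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
    i, j = index_to_pair(selected_indices, s)
    motor = np.array(
        [
            atlas.is_motor_seed(int(a), motor_networks) or atlas.is_motor_seed(int(b), motor_networks)
            for a, b in zip(np.atleast_1d(i), np.atleast_1d(j))
        ]
    )
    counts = np.array(
        [
            [np.sum(strengthened & motor), np.sum(strengthened & ~motor)],
            [np.sum(~strengthened & motor), np.sum(~strengthened & ~motor)],
        ],
        dtype=int,
    )
    return DirectionPartition(
        connection_indices=selected_indices,
        direction=np.where(strengthened, "strengthened", "weakened"),
        motor=motor,
        counts=counts,
    )


def network_involvement(
    selected_indices: np.ndarray,
    atlas: SeedAtlas,
    normalize: bool = False,
) -> dict[str, float]:
    """Discriminating-connection count per network.

    Raw mode: every connection increments both endpoint networks (a
    same-network connection increments its network twice — the
    handshake convention, so raw counts sum to 2 × n_selected).
    Normalized mode divides each count by the network's seed count.
    """
    selected_indices = np.asarray(selected_indices, dtype=int)
    s = atlas.n_seeds
    counts = {name: 0.0 for name in atlas.network_names}
    if selected_indices.size:
        i, j = index_to_pair(selected_indices, s)
        for a, b in zip(np.atleast_1d(i), np.atleast_1d(j)):
            counts[atlas.network_of(int(a))] += 1
            counts[atlas.network_of(int(b))] += 1
    if normalize:
        sizes = atlas.seeds_per_network()
        counts = {name: c / sizes[name] for name, c in counts.items() if sizes[name] > 0}
    return counts


def write_edge_file(
    conn: ConnectionWeightTable,
    directions: np.ndarray | None,
    s: int,
    path,
) -> None:
    """BrainNet ``.edge`` export: square matrix of signed aggregate weights.

    Sign encodes direction (+ strengthened, − weakened) when a
    direction array aligned with the connection table is given.
    """
    values = np.zeros(s * (s - 1) // 2)
    signed = conn.aggregate.copy()
    if directions is not None:
        signed = signed * np.where(np.asarray(directions) == "strengthened", 1.0, -1.0)
    values[conn.connection_indices] = signed
    m = devectorize(values, s, diagonal=0.0)
    np.savetxt(path, m, fmt="%.6g", delimiter="\t")
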