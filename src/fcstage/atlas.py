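"""Seed atlas: spherical ROIs grouped into functional brain networks.

The default template mirrors the widely used 236-seed / 13-network
resting-state parcellation (5 mm spheres at MNI coordinates, each seed
belonging to one named network such as "Default mode" or
"Sensory/somatomotor hand").  Downstream stages only use the seed order,
the network memberships, and the motor / non-motor split; coordinates
matter for visualization exports only.

Two file dialects are supported:

* a TSV table with header ``x_mm  y_mm  z_mm  network  label  radius_mm``
  (one row per seed; row order defines the 0-based ``seed_id``);
* the BrainNet Viewer ``.node`` format (whitespace-separated
  ``x y z color size label``) plus a color→network mapping.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Seed",
    "SeedAtlas",
    "DEFAULT_NETWORKS",
    "DEFAULT_MOTOR_NETWORKS",
    "load_atlas",
    "write_atlas",
    "load_node_file",
    "write_node_file",
    "default_atlas",
]

#: (network name, display color, expected seed count) for the default
#: 13-network template; counts sum to 236.
DEFAULT_NETWORKS: tuple[tuple[str, str, int], ...] = (
    ("Sensory/somatomotor hand", "#00ffff", 30),
    ("Sensory/somatomotor mouth", "#ff8000", 5),
    ("Cingulo-opercular task control", "#800080", 14),
    ("Auditory", "#ff00ff", 13),
    ("Default mode", "#ff0000", 58),
    ("Memory retrieval", "#808080", 5),
    ("Ventral attention", "#008080", 9),
    ("Visual", "#0000ff", 31),
    ("Fronto-parietal task control", "#ffff00", 25),
    ("Salience", "#000000", 18),
    ("Subcortical", "#804000", 13),
    ("Cerebellar", "#9fc5e8", 4),
    ("Dorsal attention", "#00ff00", 11),
)

#: Networks counted as "motor" when partitioning connections into
#: motor / non-motor (the two somatomotor networks).  Configurable in all
#: functions that use it.
DEFAULT_MOTOR_NETWORKS: frozenset[str] = frozenset(
    {"Sensory/somatomotor hand", "Sensory/somatomotor mouth"}
)

_DEFAULT_ATLAS_RESOURCE = "atlas_236_synthetic.tsv"


@dataclass(frozen=True)
class Seed:
    """One spherical ROI."""

    seed_id: int
    label: str
    mni_xyz: tuple[float, float, float]
    network: str
    radius_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"seed {self.seed_id}: radius_mm must be > 0")
        if len(self.mni_xyz) != 3 or not all(np.isfinite(self.mni_xyz)):
            raise ValueError(f"seed {self.seed_id}: malformed MNI coordinates")


@dataclass
class SeedAtlas:
    """Ordered seed list plus the network palette.

    ``networks`` is an ordered list of ``(name, color, expected_count)``;
    ``expected_count`` may be ``None`` for ad-hoc atlases, in which case it
    is filled from the actual seed memberships.
    """

    seeds: list[Seed]
    networks: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.seed_id for s in self.seeds]
        if ids != list(range(len(self.seeds))):
            raise ValueError("seed_id must be unique and contiguous 0..S-1")
        if not self.networks:
            order: dict[str, int] = {}
            for s in self.seeds:
                order.setdefault(s.network, len(order))
            counts = self.seeds_per_network()
            self.networks = [(n, "#888888", counts[n]) for n in order]
        names = {n for n, _, _ in self.networks}
        for s in self.seeds:
            if s.network not in names:
                raise ValueError(
                    f"seed {s.seed_id} ({s.label!r}): unknown network {s.network!r}"
                )

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    @property
    def network_names(self) -> list[str]:
        return [n for n, _, _ in self.networks]

    def seeds_per_network(self) -> dict[str, int]:
        """Seed count per network, over all networks in atlas order."""
        counts = {n: 0 for n, _, _ in self.networks} if self.networks else {}
        for s in self.seeds:
            counts[s.network] = counts.get(s.network, 0) + 1
        return counts

    def network_of(self, seed_id: int) -> str:
        return self._seed(seed_id).network

    def is_motor_seed(
        self, seed_id: int, motor_networks: Iterable[str] | None = None
    ) -> bool:
        """True iff the seed's network is in the configured motor set."""
        motor = frozenset(motor_networks) if motor_networks is not None else DEFAULT_MOTOR_NETWORKS
        return self._seed(seed_id).network in motor

    def motor_seed_ids(
        self, motor_networks: Iterable[str] | None = None
    ) -> np.ndarray:
        return np.array(
            [s.seed_id for s in self.seeds if self.is_motor_seed(s.seed_id, motor_networks)],
            dtype=int,
        )

    def coordinates(self) -> np.ndarray:
        """(S, 3) array of MNI coordinates in seed order."""
        return np.array([s.mni_xyz for s in self.seeds], dtype=float)

    def network_index(self, network: str) -> int:
        """1-based palette index (used as BrainNet color code)."""
        return self.network_names.index(network) + 1

    def validate_expected_counts(self) -> None:
        """Raise if actual per-network counts disagree with the palette."""
        actual = self.seeds_per_network()
        for name, _, expected in self.networks:
            if expected is not None and actual.get(name, 0) != expected:
                raise ValueError(
                    f"network {name!r}: expected {expected} seeds, found {actual.get(name, 0)}"
                )

    def _seed(self, seed_id: int) -> Seed:
        if not 0 <= seed_id < len(self.seeds):
            raise IndexError(f"seed_id {seed_id} out of range 0..{len(self.seeds) - 1}")
        return self.seeds[seed_id]


_TSV_COLUMNS = ["x_mm", "y_mm", "z_mm", "network", "label", "radius_mm"]


def load_atlas(
    path: str | Path,
    networks: Sequence[tuple[str, str, int]] | None = None,
) -> SeedAtlas:
    """Read a TSV atlas table; row order defines ``seed_id``.

    ``networks`` restricts membership to a fixed palette (rows naming any
    other network are rejected, with the offending row number).  Without
    it the palette is inferred from the file in order of first appearance.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    allowed = {n for n, _, _ in networks} if networks is not None else None
    seeds = []
    for row_number, (_, row) in enumerate(df.iterrows()):
        xyz = row[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"{path}: row {row_number}: malformed coordinates")
        if allowed is not None and row["network"] not in allowed:
            raise ValueError(
                f"{path}: row {row_number}: unknown network {row['network']!r}"
            )
        seeds.append(
            Seed(
                seed_id=row_number,
                label=str(row["label"]),
                mni_xyz=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                network=str(row["network"]),
                radius_mm=float(row["radius_mm"]),
            )
        )
    return SeedAtlas(seeds=seeds, networks=list(networks) if networks is not None else [])


def write_atlas(atlas: SeedAtlas, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`load_atlas` (round-trips)."""
    rows = [
        {
            "x_mm": s.mni_xyz[0],
            "y_mm": s.mni_xyz[1],
            "z_mm": s.mni_xyz[2],
            "network": s.network,
            "label": s.label,
            "radius_mm": s.radius_mm,
        }
        for s in atlas.seeds
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def load_node_file(
    path: str | Path,
    color_to_network: Mapping[int, str],
    networks: Sequence[tuple[str, str, int]] | None = None,
) -> SeedAtlas:
    """Read a BrainNet Viewer ``.node`` file (x y z color size label)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["x", "y", "z", "color", "size", "label"],
        comment="#",
    )
    seeds = []
    for row_number, (_, row) in enumerate(df.iterrows()):
        color = int(row["color"])
        if color not in color_to_network:
            raise ValueError(f"{path}: row {row_number}: unmapped color code {color}")
        seeds.append(
            Seed(
                seed_id=row_number,
                label=str(row["label"]),
                mni_xyz=(float(row["x"]), float(row["y"]), float(row["z"])),
                network=color_to_network[color],
                radius_mm=float(row["size"]),
            )
        )
    return SeedAtlas(seeds=seeds, networks=list(networks) if networks is not None else [])


def write_node_file(
    atlas: SeedAtlas,
    path: str | Path,
    sizes: np.ndarray | None = None,
) -> None:
    """Write a BrainNet ``.node`` file; color = 1-based network index.

    ``sizes`` overrides the node-size column (e.g. seed weights); by
    default the seed radius is used.
    """
    if sizes is None:
        sizes = np.array([s.radius_mm for s in atlas.seeds])
    sizes = np.asarray(sizes, dtype=float)
    if sizes.shape != (atlas.n_seeds,):
        raise ValueError("sizes must have one value per seed")
    with open(path, "w") as fh:
        for s, size in zip(atlas.seeds, sizes):
            label = s.label.replace(" ", "_")
            fh.write(
                f"{s.mni_xyz[0]:.1f}\t{s.mni_xyz[1]:.1f}\t{s.mni_xyz[2]:.1f}\t"
                f"{atlas.network_index(s.network)}\t{size:.6g}\t{label}\n"
            )


def default_atlas() -> SeedAtlas:
    """The packaged 236-seed / 13-network template.

    Network memberships and per-network counts follow the published
    template; the shipped coordinates are synthetic placeholders (the
    original coordinate list is not redistributed here), which affects
    visualization exports only, never pipeline logic.
    """
    ref = importlib.resources.files("fcstage.data") / _DEFAULT_ATLAS_RESOURCE
    with importlib.resources.as_file(ref) as p:
        atlas = load_atlas(p, networks=DEFAULT_NETWORKS)
    atlas.validate_expected_counts()
    return atlas
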