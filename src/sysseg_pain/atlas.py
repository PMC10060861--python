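"""Node-to-network partition atlases.

A partition assigns every cortical node (parcel) to exactly one resting-state
network. The segregation metric averages Fisher-z connectivity over the
within-network and between-network node-pair sets that this partition defines,
so the partition is the only anatomical input the pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical seven cortical resting-state networks.
SEVEN_NETWORKS = (
    "default",
    "somatomotor",
    "control",
    "dorsoattention",
    "salience_ventral_attention",
    "limbic",
    "visual",
)

# Node allocation of the default 100-node / 7-network partition. The counts
# approximate the familiar 100-parcel cortical parcellation; no downstream
# formula depends on the exact per-network counts, only on the grouping.
_DEFAULT_ALLOCATION = {
    "default": 24,
    "control": 13,
    "limbic": 10,
    "salience_ventral_attention": 12,
    "dorsoattention": 13,
    "somatomotor": 14,
    "visual": 14,
}


@dataclass(frozen=True)
class PartitionAtlas:
    """Immutable node -> network assignment.

    Parameters
    ----------
    node_labels : tuple of str
        One label per node, in node order (0-based internally).
    networks : tuple of str
        Network assignment per node, same length as ``node_labels``.
    """

    node_labels: tuple
    networks: tuple
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(self.node_labels) != len(self.networks):
            raise ValueError("node_labels and networks must have equal length")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")
        counts = pd.Series(self.networks).value_counts()
        small = counts[counts < 2]
        if not small.empty:
            raise ValueError(
                "each network needs at least 2 nodes for a within-network mean; "
                f"undersized: {sorted(small.index)}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def network_names(self) -> tuple:
        """Networks in first-appearance order."""
        seen = {}
        for net in self.networks:
            seen.setdefault(net, None)
        return tuple(seen)

    def nodes_of(self, network: str) -> np.ndarray:
        """0-based node indices belonging to ``network``."""
        idx = np.flatnonzero(np.asarray(self.networks, dtype=object) == network)
        if idx.size == 0:
            raise KeyError(f"unknown network {network!r}")
        return idx

    def membership(self) -> np.ndarray:
        """Integer network code per node (codes follow ``network_names`` order)."""
        order = {net: k for k, net in enumerate(self.network_names)}
        return np.array([order[n] for n in self.networks], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_label": list(self.node_labels), "network": list(self.networks)}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PartitionAtlas":
        missing = {"node_label", "network"} - set(df.columns)
        if missing:
            raise ValueError(f"partition table missing columns: {sorted(missing)}")
        return cls(tuple(df["node_label"].astype(str)), tuple(df["network"].astype(str)))


def default_partition() -> PartitionAtlas:
    """The package's default 100-node, 7-network partition.

    Nodes are ordered network-by-network with labels ``<network>_<k>``.
    """
    labels, nets = [], []
    for net in SEVEN_NETWORKS:
        for k in range(_DEFAULT_ALLOCATION[net]):
            labels.append(f"{net}_{k + 1}")
            nets.append(net)
    return PartitionAtlas(tuple(labels), tuple(nets))
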