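"""The non-redundant dataset container and its TSV serialization.

A dataset is a partition of chains into redundant clusters, each carrying a
representative chain and cluster-level annotations.  On disk it is one
cluster per row with six columns: Cluster ID, Representative, Redundant
Cluster (comma-separated members), Organism, Macromolecule Name, Rfam
Family Name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .pdbio import SchemaError

COLUMNS = ("Cluster ID", "Representative", "Redundant Cluster", "Organism",
           "Macromolecule Name", "Rfam Family Name")


@dataclass
class RedundantCluster:
    """A set of mutually redundant chains with one representative."""

    cluster_id: int
    representative: str
    members: frozenset[str]
    organism: str = ""
    macromolecule_names: tuple[str, ...] = ()
    rfam_families: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if self.representative not in self.members:
            raise ValueError(
                f"representative {self.representative} not among members")

    @property
    def sorted_members(self) -> list[str]:
        return sorted(self.members)

    def replace_id(self, cluster_id: int) -> "RedundantCluster":
        return RedundantCluster(cluster_id, self.representative, self.members,
                                self.organism, self.macromolecule_names,
                                self.rfam_families)


@dataclass
class NRDataset:
    """A versioned partition of RNA chains into redundant clusters."""

    clusters: list[RedundantCluster] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_ids: set[int] = set()
        seen_chains: set[str] = set()
        for cluster in self.clusters:
            if cluster.cluster_id in seen_ids:
                raise ValueError(f"duplicate cluster id {cluster.cluster_id}")
            seen_ids.add(cluster.cluster_id)
            overlap = seen_chains & cluster.members
            if overlap:
                raise ValueError(
                    f"chains in more than one cluster: {sorted(overlap)[:5]}")
            seen_chains.update(cluster.members)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def n_chains(self) -> int:
        return sum(len(c.members) for c in self.clusters)

    @property
    def chain_uids(self) -> set[str]:
        return {uid for c in self.clusters for uid in c.members}

    @property
    def representatives(self) -> list[str]:
        return [c.representative for c in self.clusters]

    def cluster_of(self, chain_uid: str) -> RedundantCluster | None:
        for cluster in self.clusters:
            if chain_uid in cluster.members:
                return cluster
        return None

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.clusters]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "Cluster ID": c.cluster_id,
            "Representative": c.representative,
            "Redundant Cluster": ",".join(c.sorted_members),
            "Organism": c.organism,
            "Macromolecule Name": ";".join(c.macromolecule_names),
            "Rfam Family Name": ";".join(c.rfam_families),
        } for c in self.clusters]
        return pd.DataFrame(rows, columns=list(COLUMNS))

    def __eq__(self, other) -> bool:
        if not isinstance(other, NRDataset):
            return NotImplemented
        return self.to_frame().equals(other.to_frame())


def write_dataset(ds: NRDataset, path: str | Path) -> Path:
    """Write the six-column TSV, one cluster per row."""
    path = Path(path)
    ds.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_dataset(path: str | Path) -> NRDataset:
    """Read a dataset TSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    clusters = []
    for _, row in df.iterrows():
        members = frozenset(m for m in row["Redundant Cluster"].split(",")
                            if m)
        clusters.append(RedundantCluster(
            cluster_id=int(row["Cluster ID"]),
            representative=row["Representative"],
            members=members,
            organism=row["Organism"],
            macromolecule_names=tuple(
                x for x in row["Macromolecule Name"].split(";") if x),
            rfam_families=tuple(
                x for x in row["Rfam Family Name"].split(";") if x),
        ))
    return NRDataset(clusters)
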