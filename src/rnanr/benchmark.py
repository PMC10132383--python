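"""Comparison of two clusterings of (partly) the same chains.

For every cluster of dataset A the *compatible* cluster of dataset B is the
one sharing the most common chains.  Cluster quality is summarized by the
mean pairwise RMSD and PSI over each cluster's common members; RMSD-diff and
PSI-diff are the differences between compatible clusters (negative RMSD-diff
and positive PSI-diff favour dataset A).  The overall similarity is the
percentage of common chains that fall inside their cluster's compatible
cluster.  All comparisons are restricted to chains present in both datasets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .chain import RNAChain
from .cluster import SimilarityCache, pair_similarity
from .config import DEFAULT_CONFIG, PipelineConfig
from .dataset import NRDataset


@dataclass(frozen=True)
class ClusterComparison:
    """Per-cluster row of a dataset comparison (None = Null)."""

    cluster_id: int
    compatible_id: int | None
    n_common: int
    avg_rmsd_a: float | None
    avg_rmsd_b: float | None
    rmsd_diff: float | None
    avg_psi_a: float | None
    avg_psi_b: float | None
    psi_diff: float | None


@dataclass
class ComparisonReport:
    """Outcome of comparing dataset A against dataset B."""

    common_chains: int
    similar_clusters: int
    common_reps: int
    overall_similarity: float | None
    per_cluster: list[ClusterComparison] = field(default_factory=list)

    @property
    def avg_rmsd_a(self) -> float | None:
        return _mean([r.avg_rmsd_a for r in self.per_cluster])

    @property
    def avg_psi_a(self) -> float | None:
        return _mean([r.avg_psi_a for r in self.per_cluster])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "Cluster ID": r.cluster_id,
            "Compatible Cluster ID": _nullable(r.compatible_id),
            "Common Chains": r.n_common,
            "Avg RMSD A": _nullable(r.avg_rmsd_a),
            "Avg RMSD B": _nullable(r.avg_rmsd_b),
            "RMSD-diff": _nullable(r.rmsd_diff),
            "Avg PSI A": _nullable(r.avg_psi_a),
            "Avg PSI B": _nullable(r.avg_psi_b),
            "PSI-diff": _nullable(r.psi_diff),
        } for r in self.per_cluster])


def _nullable(v):
    return "Null" if v is None else v


def _mean(values) -> float | None:
    vals = [v for v in values if v is not None]
    return sum(vals) / len(vals) if vals else None


def compatible_cluster(members: frozenset[str] | set[str],
                       other: NRDataset,
                       common: set[str] | None = None) -> int | None:
    """Id of the other-dataset cluster sharing the most common chains.

    Ties break on the smallest cluster id; zero overlap everywhere -> None.
    Only chains in `common` (both datasets) are counted when given.
    """
    members = set(members) if common is None else set(members) & common
    best_id, best_overlap = None, 0
    for cluster in sorted(other.clusters, key=lambda c: c.cluster_id):
        overlap = len(members & cluster.members)
        if overlap > best_overlap:
            best_id, best_overlap = cluster.cluster_id, overlap
    return best_id


def cluster_avg_metrics(members, chains: dict[str, RNAChain],
                        cfg: PipelineConfig = DEFAULT_CONFIG,
                        cache: SimilarityCache | None = None,
                        backend: str = "surrogate"):
    """(avg RMSD, avg PSI) over all unordered member pairs; singleton -> None.

    Pairs are compared on demand (docking route for identical sequences,
    structural aligner otherwise); incomparable pairs are skipped.
    """
    uids = sorted(members)
    if len(uids) < 2:
        return None, None
    rmsds, psis = [], []
    for uid_a, uid_b in itertools.combinations(uids, 2):
        sim = pair_similarity(chains[uid_a], chains[uid_b], cfg, cache,
                              backend)
        if sim.rmsd is not None:
            rmsds.append(sim.rmsd)
            psis.append(sim.psi)
    if not rmsds:
        return None, None
    return sum(rmsds) / len(rmsds), sum(psis) / len(psis)


def diff_metrics(avg_a, avg_b):
    """Differences of compatible clusters' averages; Null-propagating."""
    rmsd_a, psi_a = avg_a
    rmsd_b, psi_b = avg_b
    rmsd_diff = None if rmsd_a is None or rmsd_b is None else rmsd_a - rmsd_b
    psi_diff = None if psi_a is None or psi_b is None else psi_a - psi_b
    return rmsd_diff, psi_diff


def overall_similarity(ds_a: NRDataset, ds_b: NRDataset) -> float | None:
    """Percent of common chains inside their cluster's compatible cluster."""
    common = ds_a.chain_uids & ds_b.chain_uids
    if not common:
        return None
    by_id = {c.cluster_id: c for c in ds_b.clusters}
    shared = 0
    for cluster in ds_a.clusters:
        cid = compatible_cluster(cluster.members, ds_b, common)
        if cid is not None:
            shared += len(cluster.members & common & by_id[cid].members)
    return 100.0 * shared / len(common)


def compare_datasets(ds_a: NRDataset, ds_b: NRDataset,
                     chains: dict[str, RNAChain],
                     cfg: PipelineConfig = DEFAULT_CONFIG,
                     cache: SimilarityCache | None = None,
                     backend: str = "surrogate") -> ComparisonReport:
    """Full comparison report of dataset A against dataset B.

    Cluster averages are computed over common chains only, so "singleton"
    means a single *common* chain.  `chains` must cover the common chains.
    """
    common = ds_a.chain_uids & ds_b.chain_uids
    by_id_b = {c.cluster_id: c for c in ds_b.clusters}
    member_sets_b = {c.members & common for c in ds_b.clusters}
    reps_b = {c.representative for c in ds_b.clusters}

    similar = sum(1 for c in ds_a.clusters
                  if (c.members & common) and (c.members & common)
                  in member_sets_b)
    common_reps = sum(1 for c in ds_a.clusters if c.representative in reps_b)

    per_cluster = []
    for cluster in sorted(ds_a.clusters, key=lambda c: c.cluster_id):
        mine = cluster.members & common
        cid = compatible_cluster(cluster.members, ds_b, common)
        avg_a = cluster_avg_metrics(mine, chains, cfg, cache, backend)
        if cid is None:
            avg_b = (None, None)
        else:
            avg_b = cluster_avg_metrics(by_id_b[cid].members & common,
                                        chains, cfg, cache, backend)
        rmsd_diff, psi_diff = diff_metrics(avg_a, avg_b)
        per_cluster.append(ClusterComparison(
            cluster.cluster_id, cid, len(mine), avg_a[0], avg_b[0],
            rmsd_diff, avg_a[1], avg_b[1], psi_diff))

    return ComparisonReport(
        common_chains=len(common),
        similar_clusters=similar,
        common_reps=common_reps,
        overall_similarity=overall_similarity(ds_a, ds_b),
        per_cluster=per_cluster,
    )


def read_membership_tsv(path) -> NRDataset:
    """Ingest an external clustering from a simple membership TSV.

    Columns: cluster_id, chain_uid, representative (1/0 flag).  Converted
    once into the native dataset container for comparison.
    """
    from .dataset import RedundantCluster
    from .pdbio import SchemaError

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("cluster_id", "chain_uid", "representative"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    clusters = []
    for raw_id, sub in df.groupby("cluster_id", sort=True):
        members = frozenset(sub["chain_uid"])
        flagged = sub.loc[sub["representative"].isin(("1", "true", "True")),
                          "chain_uid"]
        rep = flagged.iloc[0] if len(flagged) else min(members)
        clusters.append(RedundantCluster(
            cluster_id=len(clusters) + 1, representative=rep,
            members=members))
    return NRDataset(clusters)
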