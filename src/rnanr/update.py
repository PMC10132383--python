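"""Incremental dataset update.

Instead of re-clustering everything, new chains are compared only against
the representatives (RPs) of the previous dataset version.  A new chain
similar to an RP (same organism when organism division is on, identity
>= 80%, RMSD < 4 A, SAR >= 80% with the new chain as SAR denominator) joins
that RP's cluster; the remaining new chains are clustered among themselves
by the full pipeline.  Prior clusters are never split or re-merged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .chain import RNAChain
from .cluster import (SimilarityCache, build_redundancy_graph,
                      cluster_chains, pair_similarity)
from .config import DEFAULT_CONFIG, PipelineConfig
from .dataset import NRDataset, RedundantCluster
from .pdbio import assign_organism
from .representative import select_representative
from .seqsim import chain_identity, eligible_pair
from .structsim import (ComparisonUnavailable, alignment_ratio, compare_pair,
                        docking_rmsd, structural_align)

logger = logging.getLogger(__name__)


@dataclass
class UpdateReport:
    """Change summary of one incremental update."""

    unmodified: int = 0
    modified: int = 0
    new: int = 0
    dropped: int = 0
    matched_chains: dict[str, str] = field(default_factory=dict)


def _update_similarity(new_chain: RNAChain, rep: RNAChain,
                       cfg: PipelineConfig, backend: str):
    """(identity, rmsd, sar) of a new chain against a representative.

    SAR uses the new chain's coordinate count as denominator (the new chain
    is the focus of the comparison).  Returns None when the pair is not
    length-eligible or cannot be compared.
    """
    if not eligible_pair(new_chain.polymer_length, rep.polymer_length, cfg):
        return None
    identity = chain_identity(new_chain, rep, cfg)
    if identity < cfg.identity_threshold:
        return None
    try:
        if identity >= 1.0:
            result = docking_rmsd(new_chain, rep, cfg)
        else:
            result = structural_align(new_chain, rep, cfg, backend)
        sar = alignment_ratio(result, new_chain, rep, mode="update")
    except ComparisonUnavailable:
        return None
    return identity, result.rmsd, sar


def match_new_chain(new_chain: RNAChain, reps: list[RNAChain],
                    cfg: PipelineConfig = DEFAULT_CONFIG,
                    organism_division: bool = True,
                    backend: str = "surrogate") -> str | None:
    """Best-matching representative uid for a new chain, or None.

    Among representatives passing all three thresholds, maximum similarity
    means lowest RMSD, then highest SAR, then highest identity (structure
    is the binding criterion); ties beyond that break on the smaller uid.
    """
    candidates = []
    for rep in sorted(reps, key=lambda c: c.chain_uid):
        if organism_division and (assign_organism(rep)
                                  != assign_organism(new_chain)):
            continue
        sim = _update_similarity(new_chain, rep, cfg, backend)
        if sim is None:
            continue
        identity, rmsd, sar = sim
        if rmsd < cfg.rmsd_threshold and sar >= cfg.sar_threshold:
            candidates.append((rmsd, -sar, -identity, rep.chain_uid))
    if not candidates:
        return None
    return min(candidates)[3]


def update_dataset(prev: NRDataset, prev_chains: list[RNAChain],
                   new_chains: list[RNAChain],
                   cfg: PipelineConfig = DEFAULT_CONFIG,
                   cache: SimilarityCache | None = None,
                   backend: str = "surrogate",
                   organism_division: bool = True
                   ) -> tuple[NRDataset, UpdateReport]:
    """One incremental update round.

    `new_chains` are assumed to have passed the update-mode filters.
    Clusters whose chains are entirely absent from `prev_chains` (withdrawn
    structures) are dropped; partially withdrawn clusters lose those
    members.  Returns the new dataset and a change report.
    """
    by_uid = {c.chain_uid: c for c in prev_chains}
    collisions = sorted(by_uid.keys() & {c.chain_uid for c in new_chains})
    if collisions:
        raise ValueError(
            f"chain uids present in both previous and new input: "
            f"{collisions[:5]}")
    report = UpdateReport()

    # Withdrawn-entry handling: restrict prior clusters to surviving chains.
    survivors: list[RedundantCluster] = []
    for cluster in prev.clusters:
        present = frozenset(uid for uid in cluster.members if uid in by_uid)
        if not present:
            logger.info("dropping cluster %d: all members withdrawn",
                        cluster.cluster_id)
            report.dropped += 1
            continue
        if present != cluster.members:
            logger.info("cluster %d: dropping withdrawn members %s",
                        cluster.cluster_id,
                        sorted(cluster.members - present))
            cluster = _rebuild_cluster(cluster, present, [], by_uid, cfg,
                                       cache, backend)
        survivors.append(cluster)

    reps = [by_uid[c.representative] for c in survivors]
    matches: dict[str, list[RNAChain]] = {}
    unmatched: list[RNAChain] = []
    for chain in sorted(new_chains, key=lambda c: c.chain_uid):
        rep_uid = match_new_chain(chain, reps, cfg, organism_division,
                                  backend)
        if rep_uid is None:
            unmatched.append(chain)
        else:
            matches.setdefault(rep_uid, []).append(chain)
            report.matched_chains[chain.chain_uid] = rep_uid

    out_clusters: list[RedundantCluster] = []
    for cluster in survivors:
        gained = matches.get(cluster.representative, [])
        if not gained:
            report.unmodified += 1
            out_clusters.append(cluster)
            continue
        report.modified += 1
        members = cluster.members | {c.chain_uid for c in gained}
        out_clusters.append(_rebuild_cluster(cluster, members, gained,
                                             by_uid, cfg, cache, backend))

    next_id = max((c.cluster_id for c in out_clusters), default=0) + 1
    if unmatched:
        fresh = cluster_chains(unmatched, cfg, cache, backend,
                               organism_division=organism_division,
                               first_cluster_id=next_id)
        report.new = len(fresh)
        out_clusters.extend(fresh.clusters)
    return NRDataset(out_clusters), report


def _rebuild_cluster(cluster: RedundantCluster, members: frozenset[str],
                     gained: list[RNAChain], by_uid: dict[str, RNAChain],
                     cfg: PipelineConfig, cache: SimilarityCache | None,
                     backend: str) -> RedundantCluster:
    """Re-select the representative of a modified cluster.

    Degrees are recomputed over all pairs of the enlarged cluster (needed
    for the quality score's d term).
    """
    pool = dict(by_uid)
    pool.update({c.chain_uid: c for c in gained})
    chains = [pool[uid] for uid in sorted(members)]
    sims = {}
    for a, b in itertools.combinations(chains, 2):
        if not eligible_pair(a.polymer_length, b.polymer_length, cfg):
            continue
        sims[(a.chain_uid, b.chain_uid)] = pair_similarity(
            a, b, cfg, cache, backend,
            skip_structure_below=cfg.identity_threshold)
    graph = build_redundancy_graph(chains, sims, cfg)
    degrees = {uid: graph.degree(uid) for uid in members}
    rep = select_representative(chains, degrees, cfg)
    return RedundantCluster(
        cluster_id=cluster.cluster_id, representative=rep, members=members,
        organism=cluster.organism,
        macromolecule_names=tuple(sorted(
            set(cluster.macromolecule_names)
            | {c.macromolecule_name for c in gained if c.macromolecule_name})),
        rfam_families=tuple(sorted(
            set(cluster.rfam_families)
            | {c.rfam_family for c in gained if c.rfam_family})),
    )
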