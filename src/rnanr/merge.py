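"""The without-organism-division dataset variant.

Cluster representatives are compared across organisms; whenever two
representatives satisfy the redundancy thresholds their clusters are pooled
(transitively).  Each pooled set is then fully re-compared pairwise and
re-clustered by connected components, so that no non-redundant chains end
up together.  Cluster count can only shrink: prior intra-organism edges are
re-established, so existing clusters never split.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx

from .chain import RNAChain
from .cluster import (SimilarityCache, build_redundancy_graph,
                      connected_components, pair_similarity)
from .config import DEFAULT_CONFIG, PipelineConfig
from .dataset import NRDataset, RedundantCluster
from .pdbio import assign_organism
from .representative import select_representative
from .seqsim import eligible_pair
from .structsim import is_redundant

logger = logging.getLogger(__name__)


def merge_across_organisms(ds: NRDataset, chains: list[RNAChain],
                           cfg: PipelineConfig = DEFAULT_CONFIG,
                           cache: SimilarityCache | None = None,
                           backend: str = "surrogate") -> NRDataset:
    """Merge redundant clusters across organisms and re-cluster.

    `ds` must be an organism-divided dataset over `chains`.  Returns a new
    dataset with ids reassigned from 1 in deterministic order; the Organism
    field of a merged cluster holds the semicolon-joined organism set.
    """
    by_uid = {c.chain_uid: c for c in chains}
    missing = ds.chain_uids - by_uid.keys()
    if missing:
        raise ValueError(f"dataset references unknown chains: "
                         f"{sorted(missing)[:5]}")

    # Representative-vs-representative merge graph over clusters.
    merge_graph = nx.Graph()
    merge_graph.add_nodes_from(c.cluster_id for c in ds.clusters)
    ordered = sorted(ds.clusters, key=lambda c: c.cluster_id)
    for ca, cb in itertools.combinations(ordered, 2):
        rep_a, rep_b = by_uid[ca.representative], by_uid[cb.representative]
        if not eligible_pair(rep_a.polymer_length, rep_b.polymer_length, cfg):
            continue
        sim = pair_similarity(rep_a, rep_b, cfg, cache, backend,
                              skip_structure_below=cfg.identity_threshold)
        if is_redundant(sim, cfg):
            merge_graph.add_edge(ca.cluster_id, cb.cluster_id)

    by_id = {c.cluster_id: c for c in ds.clusters}
    pooled_records = []  # (members frozenset, rep uid, chains, organisms)
    for pool_ids in nx.connected_components(merge_graph):
        pool_clusters = [by_id[cid] for cid in sorted(pool_ids)]
        organisms = sorted({c.organism for c in pool_clusters if c.organism})
        if len(pool_clusters) == 1:
            c = pool_clusters[0]
            pooled_records.append(
                (c.members, c.representative,
                 [by_uid[u] for u in c.sorted_members], organisms))
            continue
        logger.info("merging clusters %s across organisms %s",
                    sorted(pool_ids), organisms)
        members = [by_uid[uid] for cluster in pool_clusters
                   for uid in cluster.sorted_members]
        members.sort(key=lambda c: c.chain_uid)
        sims = {}
        for a, b in itertools.combinations(members, 2):
            if not eligible_pair(a.polymer_length, b.polymer_length, cfg):
                continue
            sims[(a.chain_uid, b.chain_uid)] = pair_similarity(
                a, b, cfg, cache, backend,
                skip_structure_below=cfg.identity_threshold)
        graph = build_redundancy_graph(members, sims, cfg)
        for comp in connected_components(graph):
            comp_chains = [by_uid[uid] for uid in sorted(comp)]
            degrees = {uid: graph.degree(uid) for uid in comp}
            rep = select_representative(comp_chains, degrees, cfg)
            comp_organisms = sorted({assign_organism(c) for c in comp_chains})
            pooled_records.append((comp, rep, comp_chains, comp_organisms))

    pooled_records.sort(key=lambda r: min(r[0]))
    clusters = []
    for cluster_id, (members, rep, comp_chains, organisms) in enumerate(
            pooled_records, 1):
        clusters.append(RedundantCluster(
            cluster_id=cluster_id, representative=rep, members=members,
            organism=";".join(organisms),
            macromolecule_names=tuple(sorted(
                {c.macromolecule_name for c in comp_chains
                 if c.macromolecule_name})),
            rfam_families=tuple(sorted(
                {c.rfam_family for c in comp_chains if c.rfam_family})),
        ))
    return NRDataset(clusters)
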