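"""Redundancy clustering: groups, graphs and connected components.

Within each organism, chains linked (transitively) by sequence identity
>= 80% among length-eligible pairs form Redundant Groups.  Inside a group
every pair is structurally compared and an undirected redundancy graph is
built (edge iff identity >= 80%, RMSD < 4 A and SAR >= 80%); its connected
components are the Redundant Clusters, each represented by the member with
the best quality score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .chain import RNAChain
from .config import DEFAULT_CONFIG, PipelineConfig
from .dataset import NRDataset, RedundantCluster
from .pdbio import assign_organism
from .representative import select_representative
from .seqsim import chain_identity, eligible_pair
from .structsim import PairSimilarity, compare_pair, is_redundant

logger = logging.getLogger(__name__)

CACHE_COLUMNS = ("uidA", "uidB", "identity", "rmsd", "n_aligned", "sar",
                 "psi", "method")


@dataclass(frozen=True)
class RedundantGroup:
    """Same-organism chains linked transitively by sequence identity."""

    organism: str
    members: frozenset[str]


class SimilarityCache:
    """Pairwise-comparison store keyed by canonically ordered uid pairs.

    Backed by an optional TSV file so re-runs skip already-computed pairs.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self._store: dict[tuple[str, str], PairSimilarity] = {}
        if self.path and self.path.exists():
            self._load()

    @staticmethod
    def _key(uid_a: str, uid_b: str) -> tuple[str, str]:
        return (uid_a, uid_b) if uid_a <= uid_b else (uid_b, uid_a)

    def get(self, uid_a: str, uid_b: str) -> PairSimilarity | None:
        return self._store.get(self._key(uid_a, uid_b))

    def put(self, sim: PairSimilarity) -> None:
        self._store[self._key(sim.uid_a, sim.uid_b)] = sim

    def __len__(self) -> int:
        return len(self._store)

    def _load(self) -> None:
        df = pd.read_csv(self.path, sep="\t", dtype=str,
                         keep_default_na=False)
        for col in CACHE_COLUMNS:
            if col not in df.columns:
                raise ValueError(
                    f"{self.path}: similarity cache missing column {col!r}")
        for _, row in df.iterrows():
            def num(val, cast=float):
                return cast(val) if val not in ("", "None") else None
            sim = PairSimilarity(
                row["uidA"], row["uidB"], float(row["identity"]),
                num(row["rmsd"]), int(row["n_aligned"]), num(row["sar"]),
                num(row["psi"]), row["method"])
            self._store[self._key(sim.uid_a, sim.uid_b)] = sim

    def save(self, path: str | Path | None = None) -> None:
        path = Path(path) if path else self.path
        if path is None:
            raise ValueError("no cache path configured")
        rows = []
        for key in sorted(self._store):
            s = self._store[key]
            rows.append({
                "uidA": s.uid_a, "uidB": s.uid_b,
                "identity": f"{s.identity:.6f}",
                "rmsd": "" if s.rmsd is None else f"{s.rmsd:.6f}",
                "n_aligned": s.n_aligned,
                "sar": "" if s.sar is None else f"{s.sar:.6f}",
                "psi": "" if s.psi is None else f"{s.psi:.6f}",
                "method": s.method,
            })
        pd.DataFrame(rows, columns=list(CACHE_COLUMNS)).to_csv(
            path, sep="\t", index=False)


def pair_similarity(chain_a: RNAChain, chain_b: RNAChain,
                    cfg: PipelineConfig = DEFAULT_CONFIG,
                    cache: SimilarityCache | None = None,
                    backend: str = "surrogate",
                    skip_structure_below: float | None = None
                    ) -> PairSimilarity:
    """Cached full pairwise comparison (canonical order, symmetric)."""
    if cache is not None:
        hit = cache.get(chain_a.chain_uid, chain_b.chain_uid)
        # A cached record whose structural stage was skipped is only
        # reusable if the caller would skip it too.
        if hit is not None and (
                hit.method != "none" or skip_structure_below is not None):
            return hit
    sim = compare_pair(chain_a, chain_b, cfg, backend=backend,
                       skip_structure_below=skip_structure_below)
    if cache is not None:
        cache.put(sim)
    return sim


def build_groups(chains: list[RNAChain],
                 cfg: PipelineConfig = DEFAULT_CONFIG) -> list[RedundantGroup]:
    """Redundant Groups of one organism: components of the identity graph.

    Edges join length-eligible pairs whose sequence identity reaches the
    threshold; singletons form their own group.
    """
    organisms = {assign_organism(c) for c in chains}
    if len(organisms) > 1:
        raise ValueError(
            f"build_groups expects a single organism, got {sorted(organisms)}")
    graph = nx.Graph()
    graph.add_nodes_from(c.chain_uid for c in chains)
    for a, b in itertools.combinations(sorted(chains,
                                              key=lambda c: c.chain_uid), 2):
        if not eligible_pair(a.polymer_length, b.polymer_length, cfg):
            continue
        if chain_identity(a, b, cfg) >= cfg.identity_threshold:
            graph.add_edge(a.chain_uid, b.chain_uid)
    organism = organisms.pop() if organisms else "others"
    return [RedundantGroup(organism, frozenset(comp))
            for comp in connected_components(graph)]


def build_redundancy_graph(members: list[RNAChain],
                           sims: dict[tuple[str, str], PairSimilarity],
                           cfg: PipelineConfig = DEFAULT_CONFIG) -> nx.Graph:
    """Graph over group members; edges where all three thresholds hold.

    Pairs whose comparison was unavailable contribute no edge.
    """
    graph = nx.Graph()
    graph.add_nodes_from(c.chain_uid for c in members)
    for (uid_a, uid_b), sim in sims.items():
        if is_redundant(sim, cfg):
            graph.add_edge(uid_a, uid_b)
    return graph


def connected_components(graph: nx.Graph) -> list[frozenset[str]]:
    """Maximal connected node sets, ordered by their smallest member."""
    comps = [frozenset(comp) for comp in nx.connected_components(graph)]
    return sorted(comps, key=min)


def _group_similarities(members: list[RNAChain], cfg: PipelineConfig,
                        cache: SimilarityCache | None, backend: str,
                        ) -> dict[tuple[str, str], PairSimilarity]:
    sims = {}
    ordered = sorted(members, key=lambda c: c.chain_uid)
    for a, b in itertools.combinations(ordered, 2):
        if not eligible_pair(a.polymer_length, b.polymer_length, cfg):
            continue
        sim = pair_similarity(a, b, cfg, cache, backend,
                              skip_structure_below=cfg.identity_threshold)
        sims[(a.chain_uid, b.chain_uid)] = sim
    return sims


def cluster_chains(chains: list[RNAChain],
                   cfg: PipelineConfig = DEFAULT_CONFIG,
                   cache: SimilarityCache | None = None,
                   backend: str = "surrogate",
                   organism_division: bool = True,
                   first_cluster_id: int = 1) -> NRDataset:
    """Run the full pipeline: organisms -> groups -> graphs -> clusters.

    With `organism_division` off, all chains are treated as one pool (used
    for the no-organism-division variant of the update pipeline).  Cluster
    ids are assigned from `first_cluster_id` in deterministic order
    (organism name, then smallest member uid).
    """
    by_chain = {c.chain_uid: c for c in chains}
    if len(by_chain) != len(chains):
        seen: set[str] = set()
        dupes = sorted({c.chain_uid for c in chains
                        if c.chain_uid in seen or seen.add(c.chain_uid)})
        raise ValueError(f"duplicate chain uids in input: {dupes[:5]}")

    partitions: dict[str, list[RNAChain]] = {}
    for chain in chains:
        label = assign_organism(chain) if organism_division else "merged"
        partitions.setdefault(label, []).append(chain)

    records = []  # (organism, component frozenset, representative, members)
    for organism in sorted(partitions):
        pool = partitions[organism]
        logger.info("clustering %d chains of organism %r", len(pool),
                    organism)
        if organism_division:
            groups = build_groups(pool, cfg)
        else:
            groups = _merged_groups(pool, cfg)
        for group in groups:
            members = [by_chain[uid] for uid in sorted(group.members)]
            sims = _group_similarities(members, cfg, cache, backend)
            graph = build_redundancy_graph(members, sims, cfg)
            for comp in connected_components(graph):
                comp_chains = [by_chain[uid] for uid in sorted(comp)]
                degrees = {uid: graph.degree(uid) for uid in comp}
                rep = select_representative(comp_chains, degrees, cfg)
                records.append((organism, comp, rep, comp_chains))

    records.sort(key=lambda r: (r[0], min(r[1])))
    clusters = []
    for offset, (organism, comp, rep, comp_chains) in enumerate(records):
        clusters.append(RedundantCluster(
            cluster_id=first_cluster_id + offset,
            representative=rep,
            members=comp,
            organism=organism,
            macromolecule_names=_aggregate(
                c.macromolecule_name for c in comp_chains),
            rfam_families=_aggregate(c.rfam_family for c in comp_chains),
        ))
    return NRDataset(clusters)


def _merged_groups(chains: list[RNAChain],
                   cfg: PipelineConfig) -> list[RedundantGroup]:
    """Identity groups ignoring organism labels (merged pool)."""
    graph = nx.Graph()
    graph.add_nodes_from(c.chain_uid for c in chains)
    for a, b in itertools.combinations(
            sorted(chains, key=lambda c: c.chain_uid), 2):
        if not eligible_pair(a.polymer_length, b.polymer_length, cfg):
            continue
        if chain_identity(a, b, cfg) >= cfg.identity_threshold:
            graph.add_edge(a.chain_uid, b.chain_uid)
    return [RedundantGroup("merged", frozenset(comp))
            for comp in connected_components(graph)]


def _aggregate(values) -> tuple[str, ...]:
    return tuple(sorted({v for v in values if v}))
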