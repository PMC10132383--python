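"""Structural comparison of RNA chains.

Two routes are used, mirroring how redundancy is assessed:

* **docking** — for pairs with 100% sequence identity: residues are paired by
  sequence position, superposed once with the Kabsch algorithm, and the RMSD
  is reported as the mean representative-atom distance over the paired
  residues ("average RMSD").
* **surrogate aligner** — for pairs below 100% identity: a sequence-seeded
  iterative superposition (Kabsch on the current inliers, re-select pairs
  closer than the 4-Angstrom cutoff, repeat until stable).  This stands in
  for an external global 3D aligner; an external binary can be plugged in
  through the config instead.

From an alignment result two derived quantities are computed: the structural
alignment ratio SAR (aligned nucleotides / coordinate-bearing nucleotides of
the shorter chain, or of the new chain in update mode) and PSI (percent of
aligned nucleotides relative to the shorter chain's polymer length).
"""

from __future__ import annotations

import re
import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chain import RNAChain
from .config import DEFAULT_CONFIG, PipelineConfig
from .seqsim import chain_identity, global_align

MAX_REFINE_ITERATIONS = 20

COMPLEMENTARY = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class ComparisonUnavailable(Exception):
    """Raised when a pair cannot be structurally compared.

    Such pairs contribute no redundancy edge: the chains are treated as
    non-redundant.
    """


@dataclass(frozen=True)
class StructAlignResult:
    """Outcome of a structural comparison of two chains."""

    rmsd: float
    n_aligned: int
    matched_pairs: tuple[tuple[int, int], ...]
    method: str  # docking | surrogate | external

    def __post_init__(self) -> None:
        if self.rmsd < 0 or self.n_aligned < 0:
            raise ValueError("rmsd and n_aligned must be non-negative")


@dataclass(frozen=True)
class PairSimilarity:
    """Full comparison record for a chain pair (canonical uid order)."""

    uid_a: str
    uid_b: str
    identity: float
    rmsd: float | None
    n_aligned: int
    sar: float | None
    psi: float | None
    method: str


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray):
    """Least-squares rigid superposition of A onto B.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_a @ rotation.T + translation`` minimizes the root-mean-square
    distance to ``coords_b``.  A proper rotation is enforced (no reflection).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if len(a) < 3:
        raise ValueError("superposition needs at least 3 points")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    h = (a - cen_a).T @ (b - cen_b)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cen_b - rot @ cen_a
    moved = a @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return rot, trans, rmsd


def _common_position_pairs(chain_a: RNAChain, chain_b: RNAChain):
    """Residue pairs sharing a sequence position with coordinates in both."""
    map_a = chain_a.coord_map()
    map_b = chain_b.coord_map()
    common = sorted(set(map_a) & set(map_b))
    pairs = tuple((p, p) for p in common)
    xa = np.array([map_a[p] for p in common]).reshape(-1, 3)
    xb = np.array([map_b[p] for p in common]).reshape(-1, 3)
    return pairs, xa, xb


def docking_rmsd(chain_a: RNAChain, chain_b: RNAChain,
                 cfg: PipelineConfig = DEFAULT_CONFIG) -> StructAlignResult:
    """Sequence-position docking for 100%-identity pairs.

    One global superposition over all position-paired residues; the reported
    RMSD is the arithmetic mean of the per-residue distances after the
    superposition, and `n_aligned` counts pairs closer than the cutoff.
    """
    pairs, xa, xb = _common_position_pairs(chain_a, chain_b)
    if len(pairs) < 3:
        raise ComparisonUnavailable(
            f"{chain_a.chain_uid} vs {chain_b.chain_uid}: fewer than 3 "
            "residues share coordinates"
        )
    rot, trans, _ = kabsch_superpose(xa, xb)
    dist = np.linalg.norm(xa @ rot.T + trans - xb, axis=1)
    n_aligned = int(np.sum(dist < cfg.aligned_distance_cutoff))
    return StructAlignResult(float(dist.mean()), n_aligned, pairs, "docking")


def _surrogate_align(chain_a: RNAChain, chain_b: RNAChain,
                     cfg: PipelineConfig) -> StructAlignResult:
    aln = global_align(chain_a.sequence, chain_b.sequence, cfg)
    map_a = chain_a.coord_map()
    map_b = chain_b.coord_map()
    cand = [(pa + 1, pb + 1) for pa, pb in aln.aligned_pairs
            if pa + 1 in map_a and pb + 1 in map_b]
    if len(cand) < 3:
        raise ComparisonUnavailable(
            f"{chain_a.chain_uid} vs {chain_b.chain_uid}: fewer than 3 "
            "alignable residues with coordinates"
        )
    xa = np.array([map_a[pa] for pa, _ in cand])
    xb = np.array([map_b[pb] for _, pb in cand])

    inliers = np.ones(len(cand), dtype=bool)
    dist = None
    for _ in range(MAX_REFINE_ITERATIONS):
        rot, trans, _ = kabsch_superpose(xa[inliers], xb[inliers])
        dist = np.linalg.norm(xa @ rot.T + trans - xb, axis=1)
        new_inliers = dist < cfg.aligned_distance_cutoff
        if new_inliers.sum() < 3:
            raise ComparisonUnavailable(
                f"{chain_a.chain_uid} vs {chain_b.chain_uid}: no stable "
                "inlier set of size >= 3"
            )
        if np.array_equal(new_inliers, inliers):
            break
        inliers = new_inliers
    rmsd = float(np.sqrt(np.mean(dist[inliers] ** 2)))
    matched = tuple(p for p, keep in zip(cand, inliers) if keep)
    return StructAlignResult(rmsd, int(inliers.sum()), matched, "surrogate")


def _external_align(chain_a: RNAChain, chain_b: RNAChain,
                    cfg: PipelineConfig) -> StructAlignResult:
    from .pdbio import write_chain_pdb

    if not cfg.external_aligner_cmd:
        raise ValueError("external backend requested but "
                         "external_aligner_cmd is not configured")
    with tempfile.TemporaryDirectory() as tmp:
        pa = Path(tmp) / f"{chain_a.chain_uid}.pdb"
        pb = Path(tmp) / f"{chain_b.chain_uid}.pdb"
        write_chain_pdb(chain_a, pa)
        write_chain_pdb(chain_b, pb)
        cmd = cfg.external_aligner_cmd.format(a=pa, b=pb)
        try:
            proc = subprocess.run(shlex.split(cmd), capture_output=True,
                                  text=True, check=True)
        except (OSError, subprocess.CalledProcessError) as exc:
            raise RuntimeError(f"external aligner failed: {exc}") from exc
    out = proc.stdout
    m_rmsd = re.search(r"RMSD\s*[=:]?\s*([0-9]+\.?[0-9]*)", out, re.I)
    m_aln = re.search(r"ALIGNED\s*[=:]?\s*([0-9]+)", out, re.I)
    if not (m_rmsd and m_aln):
        raise RuntimeError(
            "could not parse RMSD/aligned count from external aligner output"
        )
    return StructAlignResult(float(m_rmsd.group(1)), int(m_aln.group(1)),
                             (), "external")


def structural_align(chain_a: RNAChain, chain_b: RNAChain,
                     cfg: PipelineConfig = DEFAULT_CONFIG,
                     backend: str = "surrogate") -> StructAlignResult:
    """General structural alignment for pairs below 100% identity."""
    if chain_a.n_coords < 3 or chain_b.n_coords < 3:
        raise ComparisonUnavailable(
            f"{chain_a.chain_uid} vs {chain_b.chain_uid}: fewer than 3 "
            "coordinate-bearing residues"
        )
    if backend == "surrogate":
        return _surrogate_align(chain_a, chain_b, cfg)
    if backend == "external":
        return _external_align(chain_a, chain_b, cfg)
    raise ValueError(f"unknown structural alignment backend {backend!r}")


def _shorter_chain(chain_a: RNAChain, chain_b: RNAChain) -> RNAChain:
    """Shorter by polymer length; ties broken by smaller coordinate count."""
    key = lambda c: (c.polymer_length, c.n_coords)
    return min((chain_a, chain_b), key=key)


def alignment_ratio(result: StructAlignResult, chain_a: RNAChain,
                    chain_b: RNAChain, mode: str = "standard") -> float:
    """Structural alignment ratio (SAR), capped at 1.

    standard mode: denominator is the coordinate count of the shorter chain.
    update mode: denominator is the coordinate count of `chain_a`, the new
    chain under consideration.
    """
    if mode == "standard":
        denom = _shorter_chain(chain_a, chain_b).n_coords
    elif mode == "update":
        denom = chain_a.n_coords
    else:
        raise ValueError(f"unknown SAR mode {mode!r}")
    if denom == 0:
        raise ComparisonUnavailable("SAR undefined: no coordinate-bearing "
                                    "residues in the denominator chain")
    return min(1.0, result.n_aligned / denom)


def psi(result: StructAlignResult, chain_a: RNAChain,
        chain_b: RNAChain) -> float:
    """Percentage of structural identity relative to the shorter chain."""
    shorter_len = min(chain_a.polymer_length, chain_b.polymer_length)
    return min(100.0, 100.0 * result.n_aligned / shorter_len)


def compare_pair(chain_a: RNAChain, chain_b: RNAChain,
                 cfg: PipelineConfig = DEFAULT_CONFIG,
                 backend: str = "surrogate",
                 mode: str = "standard",
                 identity: float | None = None,
                 skip_structure_below: float | None = None) -> PairSimilarity:
    """Full pairwise comparison record.

    Routing: 100% sequence identity -> docking; otherwise the structural
    aligner.  In standard mode the chains are canonically ordered by uid
    first so every measure is symmetric.  When `skip_structure_below` is
    given and the identity falls below it, the structural stage is skipped
    (no redundancy edge is possible anyway).
    """
    if mode == "standard" and chain_b.chain_uid < chain_a.chain_uid:
        chain_a, chain_b = chain_b, chain_a
    if identity is None:
        identity = chain_identity(chain_a, chain_b, cfg)
    if skip_structure_below is not None and identity < skip_structure_below:
        return PairSimilarity(chain_a.chain_uid, chain_b.chain_uid, identity,
                              None, 0, None, None, "none")
    try:
        if identity >= 1.0:
            result = docking_rmsd(chain_a, chain_b, cfg)
        else:
            result = structural_align(chain_a, chain_b, cfg, backend)
        sar = alignment_ratio(result, chain_a, chain_b, mode)
        psi_val = psi(result, chain_a, chain_b)
    except ComparisonUnavailable:
        return PairSimilarity(chain_a.chain_uid, chain_b.chain_uid, identity,
                              None, 0, None, None, "unavailable")
    return PairSimilarity(chain_a.chain_uid, chain_b.chain_uid, identity,
                          result.rmsd, result.n_aligned, sar, psi_val,
                          result.method)


def is_redundant(sim: PairSimilarity,
                 cfg: PipelineConfig = DEFAULT_CONFIG) -> bool:
    """Redundancy edge test: identity >= 80%, RMSD < 4 A, SAR >= 80%."""
    return (sim.rmsd is not None and sim.sar is not None
            and sim.identity >= cfg.identity_threshold
            and sim.rmsd < cfg.rmsd_threshold
            and sim.sar >= cfg.sar_threshold)


def estimate_base_pairs(chain: RNAChain,
                        dist_range: tuple[float, float] = (15.0, 20.0)) -> int:
    """Crude base-pair count from representative-atom geometry.

    Stand-in for a proper annotation tool: complementary bases (Watson-Crick
    plus G-U) whose representative atoms lie 15-20 Angstrom apart are paired
    greedily, each residue at most once.  Only used when no base-pair
    annotation file is supplied.
    """
    if chain.n_coords < 2:
        return 0
    lo, hi = dist_range
    seq = chain.sequence
    pos = chain.positions
    diff = chain.xyz[:, None, :] - chain.xyz[None, :, :]
    dmat = np.linalg.norm(diff, axis=-1)
    mid = 0.5 * (lo + hi)
    candidates = []
    for i in range(len(pos)):
        for j in range(i + 3, len(pos)):
            if (seq[pos[i] - 1], seq[pos[j] - 1]) in COMPLEMENTARY:
                d = dmat[i, j]
                if lo <= d <= hi:
                    candidates.append((abs(d - mid), i, j))
    candidates.sort()
    used: set[int] = set()
    count = 0
    for _, i, j in candidates:
        if i not in used and j not in used:
            used.update((i, j))
            count += 1
    return count
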