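"""Representative selection by weighted quality score.

Every cluster member gets a quality score

    score = w1*r0 + w2*n0 + w3*b0 + w4*d0

from four cluster-normalized quantities: resolution r (lower is better, so
r0 = 1 - r/max r), coordinate-bearing residue count n, base-pair count b,
and redundancy-graph degree d (n0, b0, d0 are each divided by the cluster
maximum).  Default weights (0.4, 0.25, 0.25, 0.1) privilege resolution.
Score ties fall back to experimental method (X-ray first), polymer length,
release date, and finally the lexicographically smallest chain uid so that
selection is total and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chain import RNAChain
from .config import DEFAULT_CONFIG, PipelineConfig


@dataclass(frozen=True)
class QualityInputs:
    """Raw and normalized quality-score inputs for one cluster member."""

    chain_uid: str
    r: float | None
    n: int
    b: int
    d: int
    r0: float = 0.0
    n0: float = 0.0
    b0: float = 0.0
    d0: float = 0.0


def normalize_cluster_metrics(
        raw: list[QualityInputs]) -> list[QualityInputs]:
    """Normalize r, n, b, d within one cluster.

    n, b and d are divided by their cluster maximum (a maximum of 0 maps
    everyone to 0).  r0 = 1 - r / max(r); chains without a resolution get
    the worst value, r0 = 0.
    """
    if not raw:
        raise ValueError("cannot normalize an empty cluster")
    max_n = max(q.n for q in raw)
    max_b = max(q.b for q in raw)
    max_d = max(q.d for q in raw)
    resolutions = [q.r for q in raw if q.r is not None]
    max_r = max(resolutions) if resolutions else None

    def norm(value: float, maximum: float) -> float:
        return value / maximum if maximum > 0 else 0.0

    out = []
    for q in raw:
        r0 = 0.0
        if q.r is not None and max_r:
            r0 = 1.0 - q.r / max_r
        out.append(QualityInputs(q.chain_uid, q.r, q.n, q.b, q.d,
                                 r0=r0, n0=norm(q.n, max_n),
                                 b0=norm(q.b, max_b), d0=norm(q.d, max_d)))
    return out


def quality_score(q: QualityInputs,
                  cfg: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Weighted quality score in [0, 1]."""
    w1, w2, w3, w4 = cfg.weights
    return w1 * q.r0 + w2 * q.n0 + w3 * q.b0 + w4 * q.d0


def method_rank(method: str, cfg: PipelineConfig = DEFAULT_CONFIG) -> int:
    """Rank of an experimental method label; lower is more trusted."""
    label = (method or "").upper()
    for rank, key in enumerate(cfg.method_rank):
        if key in label:
            return rank
    return len(cfg.method_rank)


def select_representative(chains: list[RNAChain], degrees: dict[str, int],
                          cfg: PipelineConfig = DEFAULT_CONFIG) -> str:
    """Pick the representative chain uid for one cluster.

    `degrees` maps chain uid to its redundancy-graph degree within the
    cluster.  Highest quality score wins; ties are resolved by method rank,
    longer polymer length, latest release date, then smallest uid.
    """
    if not chains:
        raise ValueError("cannot select a representative of an empty cluster")
    scores = score_cluster(chains, degrees, cfg)

    def sort_key(chain: RNAChain):
        return (
            -round(scores[chain.chain_uid], 12),
            method_rank(chain.method, cfg),
            -chain.polymer_length,
            # latest release date preferred; unknown dates sort last
            chain.release_date == "",
            tuple(-ord(c) for c in chain.release_date),
            chain.chain_uid,
        )

    return min(chains, key=sort_key).chain_uid


def score_cluster(chains: list[RNAChain], degrees: dict[str, int],
                  cfg: PipelineConfig = DEFAULT_CONFIG) -> dict[str, float]:
    """Quality score per member uid (cluster-normalized)."""
    raw = [QualityInputs(c.chain_uid, c.resolution, c.n_coords, c.base_pairs,
                         degrees.get(c.chain_uid, 0)) for c in chains]
    normalized = normalize_cluster_metrics(raw)
    return {q.chain_uid: quality_score(q, cfg) for q in normalized}
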