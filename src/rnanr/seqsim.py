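"""Global sequence alignment and sequence identity.

Sequence identity between two chains is the number of identically matched
aligned nucleotides of an optimal Needleman-Wunsch global alignment divided
by the length of the shorter chain.  Two chains are only compared at all
when the longer one is at most twice the length of the shorter one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig

#: Characters that never count as identical, even when aligned to themselves.
AMBIGUOUS = frozenset("NX")


@dataclass(frozen=True)
class SeqAlignment:
    """Result of a global alignment of two sequences.

    `aligned_pairs` holds 0-based (posA, posB) index pairs, strictly
    increasing in both coordinates; `n_identical` counts pairs whose
    nucleotides are equal and unambiguous.
    """

    aligned_pairs: tuple[tuple[int, int], ...]
    n_identical: int
    score: float

    def __post_init__(self) -> None:
        pairs = self.aligned_pairs
        for (a0, b0), (a1, b1) in zip(pairs, pairs[1:]):
            if a1 <= a0 or b1 <= b0:
                raise ValueError("aligned pairs must increase in both coords")


def eligible_pair(len_a: int, len_b: int,
                  cfg: PipelineConfig = DEFAULT_CONFIG) -> bool:
    """True when two chain lengths are close enough to warrant comparison.

    The longer chain must be no longer than ``length_ratio_max`` (default 2)
    times the shorter chain.
    """
    if len_a < 1 or len_b < 1:
        raise ValueError("chain lengths must be >= 1")
    return max(len_a, len_b) <= cfg.length_ratio_max * min(len_a, len_b)


# Traceback codes.  On score ties the preference order is: diagonal
# (match/mismatch), then gap in A (consume B), then gap in B.
_DIAG, _GAP_A, _GAP_B = 0, 1, 2


def global_align(seq_a: str, seq_b: str,
                 cfg: PipelineConfig = DEFAULT_CONFIG) -> SeqAlignment:
    """Optimal Needleman-Wunsch global alignment with linear gap penalty.

    Scoring defaults: match +1, mismatch -1, gap -2.  Ambiguous letters
    (N, X) align like any other letter but are scored as mismatches and are
    never counted identical.  Tie-breaking is deterministic: prefer a
    match/mismatch column, then a gap in `seq_a`.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(seq_a), len(seq_b)
    match, mismatch, gap = cfg.match_score, cfg.mismatch_score, cfg.gap_score

    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    amb = np.frombuffer("".join(sorted(AMBIGUOUS)).encode(), dtype=np.uint8)
    usable_a = ~np.isin(a, amb)
    # Substitution matrix row per character of A against all of B.
    eq = a[:, None] == b[None, :]
    identical = eq & usable_a[:, None]
    sub = np.where(identical, match, mismatch)

    score = np.empty((n + 1, m + 1))
    trace = np.empty((n + 1, m + 1), dtype=np.uint8)
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    trace[0, :] = _GAP_A
    trace[:, 0] = _GAP_B
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + gap  # gap in B: consume a_i only
        row = score[i]
        trow = trace[i]
        prev = row[0]
        for j in range(1, m + 1):
            d, u = diag[j - 1], up[j - 1]
            left = prev + gap  # gap in A: consume b_j only
            if d >= u and d >= left:
                prev = d
                trow[j] = _DIAG
            elif left >= u:
                prev = left
                trow[j] = _GAP_A
            else:
                prev = u
                trow[j] = _GAP_B
            row[j] = prev

    pairs: list[tuple[int, int]] = []
    n_identical = 0
    i, j = n, m
    while i > 0 or j > 0:
        t = trace[i, j]
        if t == _DIAG and i > 0 and j > 0:
            i -= 1
            j -= 1
            pairs.append((i, j))
            if identical[i, j]:
                n_identical += 1
        elif t == _GAP_A and j > 0:
            j -= 1
        else:
            i -= 1
    pairs.reverse()
    return SeqAlignment(tuple(pairs), n_identical, float(score[n, m]))


def sequence_identity(aln: SeqAlignment, len_a: int, len_b: int) -> float:
    """Identity fraction: identical aligned nucleotides / shorter length."""
    return aln.n_identical / min(len_a, len_b)


def chain_identity(chain_a, chain_b,
                   cfg: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Sequence identity of two chains (full polymer sequences)."""
    aln = global_align(chain_a.sequence, chain_b.sequence, cfg)
    return sequence_identity(aln, chain_a.polymer_length,
                             chain_b.polymer_length)
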