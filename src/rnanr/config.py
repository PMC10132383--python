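"""Pipeline configuration.

All thresholds of the redundancy definition live here: two RNA chains of the
same organism are redundant when their sequence identity is >= 80%, their
superposition RMSD is < 4 Angstrom and their structural alignment ratio (SAR)
is >= 80%.  The quality-score weights (resolution, coordinate completeness,
base pairs, graph degree) must sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the non-redundant dataset pipeline.

    Parameters
    ----------
    min_length : int
        Minimum polymer length (nt) for a chain to enter the dataset.
    identity_threshold : float
        Sequence-identity threshold (fraction) for Redundant Group membership.
    rmsd_threshold : float
        RMSD upper bound (Angstrom, strict) for a redundancy edge.
    sar_threshold : float
        Structural-alignment-ratio lower bound (fraction, inclusive).
    aligned_distance_cutoff : float
        Two superposed nucleotides closer than this (Angstrom) count as
        structurally aligned.
    max_missing_frac_update : float
        Update mode only: chains missing more than this fraction of residue
        coordinates are dropped.
    weights : tuple
        (w1, w2, w3, w4) for resolution, coordinate count, base pairs and
        chain degree in the quality score; must sum to 1.
    length_ratio_max : float
        Sequence comparison is skipped when the longer chain exceeds this
        multiple of the shorter chain's length.
    representative_atom_priority : tuple
        Atom names tried in order to pick one representative atom per residue.
    match_score, mismatch_score, gap_score : float
        Needleman-Wunsch scoring (linear gaps).
    external_aligner_cmd : str or None
        Command template for an external structural aligner, with ``{a}`` and
        ``{b}`` placeholders for single-chain PDB paths.  None = use the
        built-in iterative-superposition surrogate.
    method_rank : tuple
        Substrings (upper-cased match) ordering experimental methods from the
        most to the least trusted for representative tie-breaking.
    """

    min_length: int = 20
    identity_threshold: float = 0.80
    rmsd_threshold: float = 4.0
    sar_threshold: float = 0.80
    aligned_distance_cutoff: float = 4.0
    max_missing_frac_update: float = 0.95
    weights: tuple[float, float, float, float] = (0.4, 0.25, 0.25, 0.1)
    length_ratio_max: float = 2.0
    representative_atom_priority: tuple[str, ...] = ("C3'", "C1'", "P")
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0
    external_aligner_cmd: str | None = None
    method_rank: tuple[str, ...] = ("X-RAY", "ELECTRON MICROSCOPY", "NMR")

    def __post_init__(self) -> None:
        if len(self.weights) != 4:
            raise ValueError("weights must have four entries (w1..w4)")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(
                f"quality-score weights must sum to 1, got {sum(self.weights)}"
            )
        for name in ("min_length", "rmsd_threshold", "aligned_distance_cutoff",
                     "length_ratio_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("identity_threshold", "sar_threshold",
                     "max_missing_frac_update"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a ``key = value`` config file; unknown keys are an error."""
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
            kwargs[key] = _coerce(key, value)
        return cls(**kwargs)


def _coerce(key: str, value: str):
    if key == "min_length":
        return int(value)
    if key == "weights":
        return tuple(float(x) for x in value.split(","))
    if key in ("representative_atom_priority", "method_rank"):
        return tuple(x.strip() for x in value.split(","))
    if key == "external_aligner_cmd":
        return value or None
    return float(value)


DEFAULT_CONFIG = PipelineConfig()
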