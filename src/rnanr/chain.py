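"""In-memory model of a single RNA polymer chain.

A chain carries its full polymer sequence (which may be longer than the set
of residues that were actually resolved in the experiment) plus one
representative-atom coordinate per resolved residue.  All distance
computations in the pipeline operate on these representative atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Characters allowed in a chain sequence.  Unknown or unmappable modified
#: nucleotides are recorded as N (or X when the deposition itself says X).
SEQUENCE_ALPHABET = frozenset("ACGUNX")


@dataclass
class RNAChain:
    """One RNA chain extracted from a structure file.

    Attributes
    ----------
    pdb_id : str
        Four-character accession (upper-cased).
    chain_id : str
        Author chain identifier.
    sequence : str
        One-letter polymer sequence over A/C/G/U/N/X.
    polymer_length : int
        Length of the deposited polymer entity in nucleotides.  May exceed
        the number of residues with coordinates.
    positions : numpy.ndarray of int
        1-based sequence positions of the residues that have coordinates,
        strictly increasing.
    xyz : numpy.ndarray, shape (n_coords, 3)
        Representative-atom coordinates (Angstrom), aligned with `positions`.
    resolution : float or None
        Structure resolution in Angstrom; None when not applicable (NMR).
    method : str
        Experimental method label, e.g. "X-RAY DIFFRACTION".
    release_date : str
        ISO date, empty when unknown.
    organism : str
        Source organism; empty when the deposition gives none, the literal
        "synthetic construct" for re-engineered chains.
    macromolecule_name : str
        PDB molecule description.
    base_pairs : int
        Number of base pairs (quality-score *b*), 0 until annotated.
    rfam_family : str
        Rfam family accession/name, "undefined" when unmapped.
    """

    pdb_id: str
    chain_id: str
    sequence: str
    polymer_length: int
    positions: np.ndarray
    xyz: np.ndarray
    resolution: float | None = None
    method: str = ""
    release_date: str = ""
    organism: str = ""
    macromolecule_name: str = ""
    base_pairs: int = 0
    rfam_family: str = "undefined"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if len(self.positions) != len(self.xyz):
            raise ValueError("positions and xyz must have equal length")
        if self.n_coords > self.polymer_length:
            raise ValueError("more coordinates than polymer residues")
        if self.n_coords > len(self.sequence):
            raise ValueError("more coordinates than sequence positions")
        if len(self.positions) and (
            np.any(np.diff(self.positions) <= 0)
            or self.positions[0] < 1
            or self.positions[-1] > len(self.sequence)
        ):
            raise ValueError(
                "coordinate positions must be strictly increasing indices "
                "into the sequence"
            )
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)}")

    @property
    def chain_uid(self) -> str:
        """'PDBID_CHAIN' identifier, e.g. '6F4H_B'."""
        return f"{self.pdb_id}_{self.chain_id}"

    @property
    def n_coords(self) -> int:
        """Number of residues with a representative-atom coordinate."""
        return len(self.positions)

    @property
    def missing_frac(self) -> float:
        """Fraction of polymer residues without coordinates."""
        return 1.0 - self.n_coords / self.polymer_length

    def coord_map(self) -> dict[int, np.ndarray]:
        """Mapping 1-based sequence position -> xyz."""
        return {int(p): self.xyz[i] for i, p in enumerate(self.positions)}

    def with_uid(self, pdb_id: str, chain_id: str) -> "RNAChain":
        return replace(self, pdb_id=pdb_id, chain_id=chain_id)

    def copy(self, **updates) -> "RNAChain":
        out = replace(self, **updates)
        out.positions = out.positions.copy()
        out.xyz = out.xyz.copy()
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"RNAChain({self.chain_uid}, {self.polymer_length} nt, "
                f"{self.n_coords} with coords, organism={self.organism!r})")
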