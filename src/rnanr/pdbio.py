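"""Structure-file I/O and chain-level filters.

Reads PDB and mmCIF files into :class:`~rnanr.chain.RNAChain` records (one
per RNA polymer chain; protein, DNA and hybrid chains are excluded), applies
the inclusion filters, attaches annotations, and writes minimal single- or
multi-chain PDB files for fixtures and external-aligner hand-off.

mmCIF is the richer dialect: the polymer sequence comes from the canonical
one-letter entity sequence (modified nucleotides already mapped to their
parent base), coordinates are indexed by ``label_seq_id``, and per-entity
source organisms are honoured.  For PDB-format input the sequence comes from
SEQRES when present and residue numbers are taken as 1-based sequence
positions (how this package writes its own fixtures); without SEQRES the
observed residues define the sequence.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.MMCIF2Dict import MMCIF2Dict

from .chain import RNAChain
from .config import DEFAULT_CONFIG, PipelineConfig

logger = logging.getLogger(__name__)

RNA_RESIDUES = {"A", "C", "G", "U", "I", "N"}
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DI", "DU"}
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "SEC", "PYL", "MSE", "UNK",
}

RNA_POLYMER_TYPE = "polyribonucleotide"


class StructureParseError(Exception):
    """A structure file could not be read or understood."""


class SchemaError(Exception):
    """A tabular input is missing a required column."""


# ---------------------------------------------------------------------------
# parsing


def parse_structure(path: str | Path, fmt: str = "auto") -> list[RNAChain]:
    """Parse a structure file into RNA chain records.

    Parameters
    ----------
    path : path to a PDB or mmCIF file.
    fmt : "pdb", "mmcif" or "auto" (sniff from suffix, then content).

    Returns one record per RNA polymer chain; a structure containing no RNA
    chains yields an empty list.  Multi-model structures use the first model.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such structure file: {path}")
    if fmt == "auto":
        fmt = _sniff_format(path)
    try:
        if fmt == "mmcif":
            return _parse_mmcif(path)
        if fmt == "pdb":
            return _parse_pdb(path)
    except StructureParseError:
        raise
    except Exception as exc:
        raise StructureParseError(f"could not parse {path}: {exc}") from exc
    raise ValueError(f"unknown structure format {fmt!r}")


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    head = path.read_text(errors="replace")[:2048]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def _aslist(value) -> list:
    return value if isinstance(value, list) else [value]


def _cif_first(d: dict, *keys: str) -> str | None:
    for key in keys:
        if key in d:
            vals = _aslist(d[key])
            if vals and vals[0] not in ("?", "."):
                return str(vals[0])
    return None


def _clean_seq(raw: str) -> str:
    seq = "".join(raw.split()).upper()
    return "".join(c if c in "ACGUX" else "N" for c in seq)


def _entity_organisms(d: dict) -> dict[str, str]:
    """entity_id -> source organism name, from any of the source categories."""
    out: dict[str, str] = {}
    for id_key, name_key in (
        ("_entity_src_nat.entity_id", "_entity_src_nat.pdbx_organism_scientific"),
        ("_entity_src_gen.entity_id", "_entity_src_gen.pdbx_gene_src_scientific_name"),
        ("_pdbx_entity_src_syn.entity_id", "_pdbx_entity_src_syn.organism_scientific"),
    ):
        if id_key in d and name_key in d:
            for eid, name in zip(_aslist(d[id_key]), _aslist(d[name_key])):
                if name not in ("?", ".") and eid not in out:
                    out[str(eid)] = str(name)
    return out


def _parse_mmcif(path: Path) -> list[RNAChain]:
    d = MMCIF2Dict(str(path))
    if "_atom_site.id" not in d and "_atom_site.Cartn_x" not in d:
        raise StructureParseError(f"{path}: no atom records found")
    pdb_id = (_cif_first(d, "_entry.id") or path.stem).upper()

    # RNA polymer entities and their canonical sequences.
    entity_seq: dict[str, str] = {}
    for eid, ptype, seq in zip(
        _aslist(d.get("_entity_poly.entity_id", [])),
        _aslist(d.get("_entity_poly.type", [])),
        _aslist(d.get("_entity_poly.pdbx_seq_one_letter_code_can", [])),
    ):
        if str(ptype).strip().lower() == RNA_POLYMER_TYPE:
            entity_seq[str(eid)] = _clean_seq(str(seq))

    descriptions = dict(zip(
        (str(e) for e in _aslist(d.get("_entity.id", []))),
        (str(v) for v in _aslist(d.get("_entity.pdbx_description", []))),
    ))
    src_method = dict(zip(
        (str(e) for e in _aslist(d.get("_entity.id", []))),
        (str(v) for v in _aslist(d.get("_entity.src_method", []))),
    ))
    organisms = _entity_organisms(d)

    resolution = _cif_first(
        d, "_refine.ls_d_res_high", "_em_3d_reconstruction.resolution",
        "_reflns.d_resolution_high")
    method = (_cif_first(d, "_exptl.method") or "").upper()
    dates = [v for v in _aslist(d.get("_pdbx_audit_revision_history.revision_date", []))
             if v not in ("?", ".")]
    release_date = min(dates) if dates else (
        _cif_first(d, "_pdbx_database_status.recvd_initial_deposition_date") or "")

    atoms = _atom_site_rows(d)
    chains: list[RNAChain] = []
    priority = {name: rank for rank, name
                in enumerate(DEFAULT_CONFIG.representative_atom_priority)}
    for (asym, eid), residues in atoms.items():
        if eid not in entity_seq:
            continue
        seq = entity_seq[eid]
        picked: dict[int, tuple[int, np.ndarray]] = {}
        for pos, atom_name, xyz in residues:
            if not 1 <= pos <= len(seq):
                continue
            rank = priority.get(atom_name, len(priority))
            if pos not in picked or rank < picked[pos][0]:
                picked[pos] = (rank, xyz)
        if not picked:
            continue
        positions = np.array(sorted(picked), dtype=int)
        coords = np.array([picked[p][1] for p in positions])
        organism = organisms.get(eid, "")
        if src_method.get(eid, "").lower() == "syn":
            organism = "synthetic construct"
        chains.append(RNAChain(
            pdb_id=pdb_id, chain_id=asym, sequence=seq,
            polymer_length=len(seq), positions=positions, xyz=coords,
            resolution=float(resolution) if resolution else None,
            method=method, release_date=release_date, organism=organism,
            macromolecule_name=descriptions.get(eid, ""),
        ))
    chains.sort(key=lambda c: c.chain_uid)
    return chains


def _atom_site_rows(d: dict):
    """Group first-model polymer atom rows by (auth_asym_id, entity_id)."""
    xs = _aslist(d["_atom_site.Cartn_x"])
    ys = _aslist(d["_atom_site.Cartn_y"])
    zs = _aslist(d["_atom_site.Cartn_z"])
    n = len(xs)

    def col(key, default=""):
        return _aslist(d[key]) if key in d else [default] * n

    asyms = col("_atom_site.auth_asym_id") \
        if "_atom_site.auth_asym_id" in d else col("_atom_site.label_asym_id")
    entities = col("_atom_site.label_entity_id", "1")
    seq_ids = col("_atom_site.label_seq_id", ".")
    atom_names = col("_atom_site.label_atom_id")
    altlocs = col("_atom_site.label_alt_id", ".")
    models = col("_atom_site.pdbx_PDB_model_num", "1")
    first_model = models[0]

    grouped: dict[tuple[str, str], list] = {}
    for i in range(n):
        if models[i] != first_model or seq_ids[i] in (".", "?"):
            continue
        if altlocs[i] not in (".", "?", "A"):
            continue
        name = atom_names[i].strip('"')
        xyz = np.array([float(xs[i]), float(ys[i]), float(zs[i])])
        grouped.setdefault((str(asyms[i]), str(entities[i])), []).append(
            (int(seq_ids[i]), name, xyz))
    return grouped


def _parse_pdb(path: Path) -> list[RNAChain]:
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    header = structure.header or {}
    pdb_id = (_read_header_idcode(path) or header.get("idcode")
              or path.stem).upper()
    resolution = header.get("resolution")
    method = (header.get("structure_method") or "").upper()
    release_date = _read_header_date(path)
    seqres = _read_seqres(path)
    chain_organism, chain_molecule = _read_compnd_source(path)

    model = next(iter(structure))
    chains: list[RNAChain] = []
    for chain in model:
        residues = [r for r in chain
                    if r.get_id()[0] == " " or _is_rna_resname(r.get_resname())]
        resnames = [r.get_resname().strip() for r in residues]
        if not resnames:
            continue
        if any(rn in AMINO_ACIDS or rn in DNA_RESIDUES for rn in resnames):
            continue  # protein, DNA or hybrid chain
        if not any(rn in RNA_RESIDUES for rn in resnames):
            continue
        seq = seqres.get(chain.id)
        if seq is None:
            seq = "".join(rn if rn in "ACGU" else "N" for rn in resnames)
            positions = list(range(1, len(residues) + 1))
        else:
            positions = [r.get_id()[1] for r in residues]
            if any(not 1 <= p <= len(seq) for p in positions):
                raise StructureParseError(
                    f"{path}: chain {chain.id} residue numbers do not index "
                    "the SEQRES sequence (expected 1-based positions)")
        picked: dict[int, np.ndarray] = {}
        for pos, residue in zip(positions, residues):
            atom = _representative_atom(residue)
            if atom is not None:
                picked[pos] = atom
        if not picked:
            continue
        pos_arr = np.array(sorted(picked), dtype=int)
        chains.append(RNAChain(
            pdb_id=pdb_id, chain_id=chain.id, sequence=seq,
            polymer_length=len(seq), positions=pos_arr,
            xyz=np.array([picked[p] for p in pos_arr]),
            resolution=float(resolution) if resolution is not None else None,
            method=method, release_date=str(release_date),
            organism=chain_organism.get(chain.id, ""),
            macromolecule_name=chain_molecule.get(chain.id, ""),
        ))
    chains.sort(key=lambda c: c.chain_uid)
    return chains


def _is_rna_resname(name: str) -> bool:
    return name.strip() in RNA_RESIDUES


def _representative_atom(residue) -> np.ndarray | None:
    for name in DEFAULT_CONFIG.representative_atom_priority:
        if name in residue:
            return residue[name].get_coord().astype(float)
    for atom in residue:
        return atom.get_coord().astype(float)
    return None


def _read_seqres(path: Path) -> dict[str, str]:
    """Chain id -> one-letter sequence from SEQRES records."""
    seqs: dict[str, list[str]] = {}
    for line in path.read_text().splitlines():
        if not line.startswith("SEQRES"):
            continue
        chain_id = line[11].strip()
        names = line[19:].split()
        letters = [n if n in "ACGU" else ("X" if n == "X" else "N")
                   for n in names]
        seqs.setdefault(chain_id, []).extend(letters)
    return {cid: "".join(parts) for cid, parts in seqs.items()}


def _read_header_idcode(path: Path) -> str:
    """PDB id from the HEADER record (cols 63-66)."""
    for line in path.read_text().splitlines():
        if line.startswith("HEADER"):
            return line[62:66].strip()
        if line.startswith(("ATOM", "SEQRES")):
            break
    return ""


def _read_header_date(path: Path) -> str:
    """ISO release date from the HEADER record (DD-MON-YY, cols 51-59)."""
    for line in path.read_text().splitlines():
        if line.startswith("HEADER") and len(line) >= 59:
            raw = line[50:59].strip()
            try:
                day, mon, yy = raw.split("-")
                month = _MONTHS.index(mon.upper()) + 1
                year = 2000 + int(yy) if int(yy) < 50 else 1900 + int(yy)
                return f"{year:04d}-{month:02d}-{int(day):02d}"
            except (ValueError, IndexError):
                return ""
        if line.startswith(("ATOM", "SEQRES")):
            break
    return ""


def _read_compnd_source(path: Path):
    """Chain id -> organism / molecule from COMPND+SOURCE, case preserved.

    Bio.PDB's header parser lower-cases these values, which would break the
    round trip and the organism partition, so the token fields are read
    directly.
    """
    per_mol: dict[str, dict[str, str]] = {}
    current_id: str | None = None
    for line in path.read_text().splitlines():
        record = line[:6].strip()
        if record not in ("COMPND", "SOURCE"):
            if record in ("ATOM", "SEQRES", "HETATM"):
                break
            continue
        for spec in line[10:].strip().split(";"):
            if ":" not in spec:
                continue
            key, value = (p.strip() for p in spec.split(":", 1))
            key = key.upper()
            if key == "MOL_ID":
                current_id = value
                per_mol.setdefault(current_id, {})
            elif key in ("MOLECULE", "CHAIN", "ORGANISM_SCIENTIFIC"):
                if current_id is not None:
                    per_mol[current_id].setdefault(key, value)
    organism: dict[str, str] = {}
    molecule: dict[str, str] = {}
    for fields in per_mol.values():
        chains = [c.strip() for c in fields.get("CHAIN", "").split(",")
                  if c.strip()]
        for cid in chains:
            if fields.get("ORGANISM_SCIENTIFIC"):
                organism[cid] = fields["ORGANISM_SCIENTIFIC"]
            if fields.get("MOLECULE"):
                molecule[cid] = fields["MOLECULE"]
    return organism, molecule


# ---------------------------------------------------------------------------
# filters and annotations


def filter_chains(chains: list[RNAChain],
                  cfg: PipelineConfig = DEFAULT_CONFIG,
                  update_mode: bool = False) -> list[RNAChain]:
    """Apply the inclusion filters, preserving input order.

    Chains shorter than ``min_length`` nucleotides are dropped.  In update
    mode, chains missing more than ``max_missing_frac_update`` of their
    residue coordinates are additionally dropped.
    """
    kept = []
    for chain in chains:
        if chain.polymer_length < cfg.min_length:
            continue
        if update_mode and chain.missing_frac > cfg.max_missing_frac_update:
            continue
        kept.append(chain)
    return kept


def assign_organism(chain: RNAChain) -> str:
    """Organism partition label for a chain.

    Re-engineered chains fall under "synthetic construct"; chains without
    source information are pooled under the pseudo-organism "others".
    """
    organism = (chain.organism or "").strip()
    if not organism or organism in ("?", "."):
        return "others"
    if organism.lower() == "synthetic construct":
        return "synthetic construct"
    return organism


def read_two_column_tsv(path: str | Path, key_col: str,
                        value_col: str) -> dict[str, str]:
    """Read a headered TSV into a dict; malformed rows warn and are skipped."""
    mapping: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    if not lines:
        return mapping
    header = lines[0].rstrip("\n").split("\t")
    for col in (key_col, value_col):
        if col not in header:
            raise SchemaError(f"{path}: missing required column {col!r}")
    ki, vi = header.index(key_col), header.index(value_col)
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) <= max(ki, vi) or not parts[ki].strip():
            logger.warning("%s:%d: malformed row skipped", path, lineno)
            continue
        mapping[parts[ki].strip()] = parts[vi].strip()
    return mapping


def annotate(chains: list[RNAChain],
             rfam_map: dict[str, str] | str | Path | None = None,
             bp_map: dict[str, int] | str | Path | None = None,
             use_heuristic_bp: bool = True) -> list[RNAChain]:
    """Attach Rfam families and base-pair counts (in place; returns chains).

    `rfam_map` maps PDB IDs to family names ("undefined" when absent);
    `bp_map` maps chain uids to base-pair counts.  Chains without a
    base-pair annotation fall back to the built-in geometric heuristic
    (or 0 when disabled).
    """
    if isinstance(rfam_map, (str, Path)):
        rfam_map = read_two_column_tsv(rfam_map, "pdb_id", "rfam_family")
    if isinstance(bp_map, (str, Path)):
        raw = read_two_column_tsv(bp_map, "chain_uid", "base_pairs")
        bp_map = {}
        for uid, val in raw.items():
            try:
                bp_map[uid] = int(val)
            except ValueError:
                logger.warning("base-pair annotation for %s is not an "
                               "integer: %r (skipped)", uid, val)
    for chain in chains:
        if rfam_map is not None:
            chain.rfam_family = rfam_map.get(chain.pdb_id, "undefined")
        if bp_map is not None and chain.chain_uid in bp_map:
            chain.base_pairs = bp_map[chain.chain_uid]
        elif chain.base_pairs == 0 and use_heuristic_bp:
            from .structsim import estimate_base_pairs

            chain.base_pairs = estimate_base_pairs(chain)
    return chains


# ---------------------------------------------------------------------------
# PDB writing (fixtures, external-aligner hand-off)

_MONTHS = ("JAN", "FEB", "MAR", "APR", "MAY", "JUN",
           "JUL", "AUG", "SEP", "OCT", "NOV", "DEC")


def _pdb_date(iso: str) -> str:
    try:
        y, m, day = iso.split("-")
        return f"{int(day):02d}-{_MONTHS[int(m) - 1]}-{y[2:]}"
    except (ValueError, IndexError):
        return "01-JAN-00"


def write_chain_pdb(chains: RNAChain | list[RNAChain],
                    path: str | Path) -> Path:
    """Write chains as a minimal legal PDB file.

    One representative atom (C3') is emitted per coordinate-bearing residue;
    SEQRES carries the full polymer sequence so missing residues survive a
    round trip.  All chains must share one pdb_id; single-character chain
    ids only (a PDB format limit).
    """
    if isinstance(chains, RNAChain):
        chains = [chains]
    if not chains:
        raise ValueError("nothing to write")
    pdb_ids = {c.pdb_id for c in chains}
    if len(pdb_ids) > 1:
        raise ValueError(f"chains span several entries: {sorted(pdb_ids)}")
    for c in chains:
        if len(c.chain_id) != 1:
            raise ValueError(
                f"PDB format cannot hold chain id {c.chain_id!r}; "
                "use mmCIF for multi-character chain ids")
    first = chains[0]
    lines = [
        f"HEADER    RNA                                     "
        f"{_pdb_date(first.release_date)}   {first.pdb_id:<4}",
    ]
    lines += _continued_record("COMPND", [
        part
        for mol_id, chain in enumerate(chains, 1)
        for part in (f"MOL_ID: {mol_id};",
                     f"MOLECULE: {chain.macromolecule_name or 'RNA'};",
                     f"CHAIN: {chain.chain_id};")
    ])
    # Case is preserved (real PDB depositions are upper-case throughout, but
    # the round trip must not alter what was stored).
    lines += _continued_record("SOURCE", [
        part
        for mol_id, chain in enumerate(chains, 1)
        for part in (f"MOL_ID: {mol_id};",
                     f"ORGANISM_SCIENTIFIC: {chain.organism or ''};")
    ])
    lines.append(f"EXPDTA    {(first.method or 'X-RAY DIFFRACTION').upper()}"
                 .rstrip())
    if first.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {first.resolution:7.2f} "
                     "ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")
    for chain in chains:
        for ser, start in enumerate(range(0, len(chain.sequence), 13), 1):
            block = chain.sequence[start:start + 13]
            names = " ".join(f"{c:>3}" for c in block)
            lines.append(f"SEQRES {ser:3d} {chain.chain_id} "
                         f"{len(chain.sequence):4d}  {names}")
    serial = 1
    for chain in chains:
        for pos, xyz in zip(chain.positions, chain.xyz):
            resname = chain.sequence[pos - 1]
            lines.append(
                f"ATOM  {serial:5d}  C3' {resname:>3} {chain.chain_id}"
                f"{pos:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"  1.00  0.00           C")
            serial += 1
        lines.append("TER")
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_chain_cif(chains: RNAChain | list[RNAChain],
                    path: str | Path) -> Path:
    """Write chains as a minimal mmCIF file (one entity per chain).

    Unlike the PDB writer this supports multi-character chain ids.  The
    canonical entity sequence, per-entity source organism, resolution,
    method and release date all survive a round trip through
    :func:`parse_structure`.
    """
    if isinstance(chains, RNAChain):
        chains = [chains]
    if not chains:
        raise ValueError("nothing to write")
    pdb_ids = {c.pdb_id for c in chains}
    if len(pdb_ids) > 1:
        raise ValueError(f"chains span several entries: {sorted(pdb_ids)}")
    first = chains[0]
    q = lambda s: f'"{s}"' if (" " in s or not s) else s
    lines = [
        f"data_{first.pdb_id}",
        "#",
        f"_entry.id {first.pdb_id}",
        f"_exptl.method '{first.method or 'X-RAY DIFFRACTION'}'",
    ]
    if first.resolution is not None:
        lines.append(f"_refine.ls_d_res_high {first.resolution}")
    if first.release_date:
        lines.append("_pdbx_audit_revision_history.revision_date "
                     f"{first.release_date}")
    lines += ["#", "loop_", "_entity.id", "_entity.pdbx_description",
              "_entity.src_method"]
    for eid, chain in enumerate(chains, 1):
        src = ("syn" if (chain.organism or "").lower()
               == "synthetic construct" else "nat")
        lines.append(f"{eid} {q(chain.macromolecule_name or 'RNA')} {src}")
    lines += ["#", "loop_", "_entity_poly.entity_id", "_entity_poly.type",
              "_entity_poly.pdbx_seq_one_letter_code_can",
              "_entity_poly.pdbx_strand_id"]
    for eid, chain in enumerate(chains, 1):
        lines.append(f"{eid} polyribonucleotide {chain.sequence} "
                     f"{chain.chain_id}")
    organisms = [(eid, c.organism) for eid, c in enumerate(chains, 1)
                 if c.organism and c.organism.lower() != "synthetic construct"]
    if organisms:
        lines += ["#", "loop_", "_entity_src_nat.entity_id",
                  "_entity_src_nat.pdbx_organism_scientific"]
        lines += [f"{eid} '{org}'" for eid, org in organisms]
    lines += ["#", "loop_", "_atom_site.group_PDB", "_atom_site.id",
              "_atom_site.label_atom_id", "_atom_site.label_comp_id",
              "_atom_site.label_entity_id", "_atom_site.label_seq_id",
              "_atom_site.label_alt_id", "_atom_site.auth_asym_id",
              "_atom_site.Cartn_x", "_atom_site.Cartn_y",
              "_atom_site.Cartn_z", "_atom_site.pdbx_PDB_model_num"]
    serial = 1
    for eid, chain in enumerate(chains, 1):
        for pos, xyz in zip(chain.positions, chain.xyz):
            comp = chain.sequence[pos - 1]
            lines.append(
                f"ATOM {serial} \"C3'\" {comp} {eid} {pos} . "
                f"{chain.chain_id} {xyz[0]:.3f} {xyz[1]:.3f} {xyz[2]:.3f} 1")
            serial += 1
    lines.append("#")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def _continued_record(name: str, parts: list[str]) -> list[str]:
    lines = []
    for i, part in enumerate(parts):
        if i == 0:
            lines.append(f"{name}    {part}")
        else:
            lines.append(f"{name}  {i + 1:2d} {part}")
    return lines
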