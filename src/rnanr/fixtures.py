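"""Deterministic synthetic RNA chains with known ground truth.

The generator emits single-representative-atom chains on a parametric
helical backbone (constant 5.9-Angstrom spacing between consecutive
representative atoms, the typical P-P distance of an A-form RNA helix).
Families of near-identical chains are produced by perturbing a parent with
seeded coordinate noise, point mutations, 3'-truncations and coordinate
drops, which is what real redundant depositions of one molecule look like
at the representative-atom level.  No full nucleotide geometry or base
pairing is modelled; every pipeline distance uses the representative atom,
so nothing more is needed for end-to-end exercise of the method.

All outputs are reproducible bit-for-bit from (parameters, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .chain import RNAChain
from .pdbio import write_chain_pdb

#: Consecutive representative-atom spacing (Angstrom).
HELIX_RISE = 5.9
#: Helix radius (Angstrom) and twist per residue (radians): loosely A-form.
HELIX_RADIUS = 9.4
HELIX_TWIST = np.deg2rad(32.7)

_ORGANISM_POOL = (
    "Escherichia coli",
    "Saccharomyces cerevisiae",
    "Thermus thermophilus",
    "Homo sapiens",
    "synthetic construct",
)
_METHOD_POOL = ("X-RAY DIFFRACTION", "ELECTRON MICROSCOPY", "SOLUTION NMR")


def _helix_coords(n_residues: int) -> np.ndarray:
    """Helical backbone with constant consecutive-atom spacing HELIX_RISE."""
    chord = 2.0 * HELIX_RADIUS * np.sin(HELIX_TWIST / 2.0)
    if chord >= HELIX_RISE:
        raise ValueError("helix parameters exceed the configured spacing")
    axial = np.sqrt(HELIX_RISE**2 - chord**2)
    t = np.arange(n_residues)
    return np.column_stack([
        HELIX_RADIUS * np.cos(HELIX_TWIST * t),
        HELIX_RADIUS * np.sin(HELIX_TWIST * t),
        axial * t,
    ])


def make_helix_chain(n_residues: int, seed: int,
                     **overrides) -> RNAChain:
    """One synthetic chain on the parametric helix.

    Sequence, resolution, method, release date and organism are sampled
    from the seed; any RNAChain field can be overridden by keyword.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(list("ACGU"), size=n_residues))
    method = str(rng.choice(_METHOD_POOL))
    resolution = (None if method == "SOLUTION NMR"
                  else round(float(rng.uniform(1.5, 3.5)), 2))
    year = int(rng.integers(2000, 2022))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    fields = dict(
        pdb_id=f"S{seed % 1000:03d}",
        chain_id="A",
        sequence=sequence,
        polymer_length=n_residues,
        positions=np.arange(1, n_residues + 1),
        xyz=_helix_coords(n_residues),
        resolution=resolution,
        method=method,
        release_date=f"{year:04d}-{month:02d}-{day:02d}",
        organism=str(rng.choice(_ORGANISM_POOL)),
        macromolecule_name="SYNTHETIC HELIX RNA",
    )
    fields.update(overrides)
    return RNAChain(**fields)


def perturb_chain(chain: RNAChain, coord_sigma: float = 0.0,
                  mutation_rate: float = 0.0, truncate_frac: float = 0.0,
                  drop_coord_frac: float = 0.0, seed: int = 0,
                  pdb_id: str | None = None,
                  chain_id: str | None = None,
                  **overrides) -> RNAChain:
    """Seeded noisy copy of a chain: a simulated redundant deposition.

    Applies, in order: 3'-truncation of `truncate_frac` of the polymer,
    point mutations at `mutation_rate` (always to a different base),
    isotropic Gaussian coordinate noise of `coord_sigma` Angstrom, and
    removal of coordinates for `drop_coord_frac` of the residues.  The
    result gets a new uid (give `pdb_id`/`chain_id`, or a derived default).
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    for name, frac in (("truncate_frac", truncate_frac),
                       ("drop_coord_frac", drop_coord_frac)):
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)

    keep_len = max(4, chain.polymer_length
                   - int(round(truncate_frac * chain.polymer_length)))
    sequence = list(chain.sequence[:keep_len])
    keep_mask = chain.positions <= keep_len
    positions = chain.positions[keep_mask].copy()
    xyz = chain.xyz[keep_mask].copy()

    mutate = rng.random(keep_len) < mutation_rate
    for i in np.flatnonzero(mutate):
        others = [b for b in "ACGU" if b != sequence[i]]
        sequence[i] = str(rng.choice(others))

    if coord_sigma > 0:
        xyz = xyz + rng.normal(0.0, coord_sigma, size=xyz.shape)

    if drop_coord_frac > 0 and len(positions):
        keep = rng.random(len(positions)) >= drop_coord_frac
        if keep.sum() < 4:  # keep the chain structurally comparable
            keep[:] = False
            keep[rng.choice(len(positions), size=min(4, len(positions)),
                            replace=False)] = True
        positions = positions[keep]
        xyz = xyz[keep]

    fields = dict(
        pdb_id=pdb_id or f"P{seed % 1000:03d}",
        chain_id=chain_id or chain.chain_id,
        sequence="".join(sequence),
        polymer_length=keep_len,
        positions=positions,
        xyz=xyz,
        resolution=chain.resolution,
        method=chain.method,
        release_date=chain.release_date,
        organism=chain.organism,
        macromolecule_name=chain.macromolecule_name,
        base_pairs=chain.base_pairs,
        rfam_family=chain.rfam_family,
    )
    fields.update(overrides)
    return RNAChain(**fields)


def rigid_transform_chain(chain: RNAChain, seed: int = 0,
                          **overrides) -> RNAChain:
    """Copy with a seeded proper rigid transform applied to all coordinates."""
    rng = np.random.default_rng(seed)
    # Random proper rotation via QR decomposition.
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50, 50, size=3)
    return chain.copy(xyz=chain.xyz @ q.T + t, **overrides)


def make_redundant_benchmark(k_families: int, sizes: list[int],
                             organisms: str | list[str] = "Escherichia coli",
                             seed: int = 0,
                             n_singletons: int = 0,
                             out_dir: str | Path | None = None,
                             coord_sigma: float = 0.3,
                             mutation_rate: float = 0.03):
    """Planted redundant families with known partition and representatives.

    Each family derives from its own parent helix (distinct length and seed,
    hence structurally independent between families); members are
    perturbations within the redundancy thresholds (default 0.3-Angstrom
    coordinate noise, 3% mutations).  One member per family is given the
    strictly best metadata (lowest resolution value, complete coordinates,
    X-ray) so representative selection has a designated answer.  Optionally
    `n_singletons` structurally divergent lone chains are appended, and all
    chains are written as minimal PDB files under `out_dir`.

    Returns ``(chains, partition, intended_reps)`` where `partition` is a
    list of uid frozensets (families first, then singletons) and
    `intended_reps` the designated representative uid per family.
    """
    if len(sizes) != k_families:
        raise ValueError("len(sizes) must equal k_families")
    if isinstance(organisms, str):
        organisms = [organisms] * k_families
    if len(organisms) != k_families:
        raise ValueError("need one organism per family")

    chains: list[RNAChain] = []
    partition: list[frozenset[str]] = []
    intended_reps: list[str] = []
    rng = np.random.default_rng(seed)
    for fam in range(k_families):
        n_res = 30 + 8 * fam
        parent_seed = int(rng.integers(0, 2**31 - 1))
        parent = make_helix_chain(
            n_res, parent_seed,
            pdb_id=f"F{fam:01d}{seed % 100:02d}",
            organism=organisms[fam],
            method="ELECTRON MICROSCOPY",
            resolution=3.0,
            release_date="2015-06-01",
        )
        family_uids = []
        for m in range(sizes[fam]):
            member_seed = int(rng.integers(0, 2**31 - 1))
            member = perturb_chain(
                parent,
                coord_sigma=0.0 if m == 0 else coord_sigma,
                mutation_rate=0.0 if m == 0 else mutation_rate,
                seed=member_seed,
                pdb_id=f"F{fam:01d}{m:02d}",
                chain_id="A",
            )
            if m == 0:
                # Designated representative: strictly best quality inputs.
                member = member.copy(method="X-RAY DIFFRACTION",
                                     resolution=1.2,
                                     release_date="2020-01-15")
            else:
                member = member.copy(
                    resolution=round(2.5 + 0.1 * m, 2),
                    release_date=f"2016-0{min(m, 9)}-01",
                )
            chains.append(member)
            family_uids.append(member.chain_uid)
        partition.append(frozenset(family_uids))
        intended_reps.append(family_uids[0])

    for s in range(n_singletons):
        lone_seed = int(rng.integers(0, 2**31 - 1))
        lone = make_helix_chain(
            25 + 17 * s, lone_seed,
            pdb_id=f"L{s:01d}{seed % 100:02d}",
            organism=organisms[s % len(organisms)],
        )
        # Scramble the backbone so it is structurally divergent.
        scramble = np.random.default_rng(lone_seed + 1)
        lone = lone.copy(xyz=lone.xyz + scramble.normal(0, 8.0,
                                                        lone.xyz.shape))
        chains.append(lone)
        partition.append(frozenset([lone.chain_uid]))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for chain in chains:
            write_chain_pdb(chain, out_dir / f"{chain.pdb_id}.pdb")
        truth = {
            "partition": [sorted(p) for p in partition],
            "intended_representatives": intended_reps,
        }
        (out_dir / "ground_truth.json").write_text(
            json.dumps(truth, indent=2) + "\n")
    return chains, partition, intended_reps
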