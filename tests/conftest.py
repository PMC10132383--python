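"""Shared fixtures.

Real-structure worked examples are represented by SYNTHETIC STAND-INS:
the sandbox has no network access to the PDB, so the entries referenced in
the documented examples (6F4H; 4LX6/4TZX; the nine Cricket paralysis virus
chains) are emulated by generated chains that reproduce the documented
facts about those entries (identities, RMSD ranges, group/cluster layout).
Every such fixture is named ``synthetic_*`` and says so in its docstring;
they exercise the pipeline's computations on inputs with the same
structure, not the real deposited coordinates.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rnanr import RNAChain
from rnanr.fixtures import make_helix_chain, make_redundant_benchmark, perturb_chain

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def mutate_at(sequence: str, positions: list[int], rng) -> str:
    """Substitute (never silently) at the given 0-based positions."""
    seq = list(sequence)
    for pos in positions:
        seq[pos] = str(rng.choice([b for b in "ACGU" if b != seq[pos]]))
    return "".join(seq)


@pytest.fixture(scope="session")
def helix30() -> RNAChain:
    return make_helix_chain(30, seed=1, pdb_id="H030", chain_id="A",
                            organism="Escherichia coli")


@pytest.fixture(scope="session")
def benchmark432():
    """Planted benchmark: 3 families of sizes 4/3/2 plus 2 divergent lone
    chains, one organism."""
    return make_redundant_benchmark(3, [4, 3, 2], "Escherichia coli",
                                    seed=7, n_singletons=2)


@pytest.fixture(scope="session")
def synthetic_6f4h() -> list[RNAChain]:
    """Synthetic stand-in for the 6F4H worked example (B, D, F chains).

    Three depositions of the same ~90-nt molecule: identical sequences,
    sub-Angstrom coordinate scatter.  Emulates the documented facts (100%
    pairwise identity, docking RMSD < 1 A); not the real coordinates.
    """
    parent = make_helix_chain(90, seed=64, pdb_id="6F4H", chain_id="B",
                              organism="synthetic construct",
                              method="X-RAY DIFFRACTION", resolution=2.0)
    chains = [parent]
    for chain_id, seed in (("D", 65), ("F", 66)):
        chains.append(perturb_chain(parent, coord_sigma=0.25, seed=seed,
                                    pdb_id="6F4H", chain_id=chain_id))
    return chains


@pytest.fixture(scope="session")
def synthetic_4lx6_pair() -> tuple[RNAChain, RNAChain]:
    """Synthetic stand-in for the 4LX6_A vs 4TZX_X identity example.

    Two same-length 71-nt chains differing by 13 scattered substitutions,
    so an optimal ungapped global alignment matches 58 of 71 nucleotides:
    identity 58/71 = 81.7%, the documented value for the real pair.
    """
    rng = np.random.default_rng(417)
    a = make_helix_chain(71, seed=46, pdb_id="4LX6", chain_id="A",
                         organism="Bacillus subtilis")
    positions = sorted(rng.choice(71, size=13, replace=False))
    seq_b = mutate_at(a.sequence, positions, rng)
    b = perturb_chain(a, coord_sigma=0.4, seed=48, pdb_id="4TZX",
                      chain_id="X", sequence=seq_b)
    return a, b


CRPV_GROUP1 = ("4V92_AZ", "7JQC_i", "4D61_j", "4D5N_X", "5IT9_i",
               "6D9J_4", "6D90_4")
CRPV_GROUP2 = ("6W2S_0", "6W2T_A")
# Conformational subfamilies planted inside group 1 (the documented outcome
# is 4 structural clusters from these 7 chains; the membership split is the
# stand-in's own choice).
CRPV_SUBFAMILIES = (("4V92_AZ", "7JQC_i", "5IT9_i"), ("4D61_j", "4D5N_X"),
                    ("6D9J_4",), ("6D90_4",))


@pytest.fixture(scope="session")
def synthetic_crpv() -> list[RNAChain]:
    """Synthetic stand-in for the nine Cricket paralysis virus chains.

    Group 1: seven ~150-nt chains sharing one parent sequence (pairwise
    identity far above 80%) but planted in four conformational subfamilies
    (inter-subfamily backbone displacement far beyond the 4-A cutoff).
    Group 2: two chains of an unrelated sequence and shared conformation.
    Emulates the documented two-group, 4+1-cluster layout.
    """
    organism = "Cricket paralysis virus"
    rng = np.random.default_rng(992)
    parent1 = make_helix_chain(150, seed=900, organism=organism)
    chains: list[RNAChain] = []
    for sub_idx, subfamily in enumerate(CRPV_SUBFAMILIES):
        conf_rng = np.random.default_rng(910 + sub_idx)
        conformation = parent1.xyz + conf_rng.normal(0, 12.0,
                                                     parent1.xyz.shape)
        for uid in subfamily:
            pdb_id, chain_id = uid.split("_")
            seed = int(rng.integers(0, 2**31 - 1))
            member_rng = np.random.default_rng(seed)
            n_mut = int(member_rng.integers(2, 6))
            muts = sorted(member_rng.choice(150, n_mut, replace=False))
            chains.append(parent1.copy(
                pdb_id=pdb_id, chain_id=chain_id,
                sequence=mutate_at(parent1.sequence, muts, member_rng),
                xyz=conformation + member_rng.normal(0, 0.3,
                                                     conformation.shape),
                resolution=round(float(member_rng.uniform(2.0, 3.5)), 2),
            ))
    parent2 = make_helix_chain(150, seed=901, organism=organism)
    for uid, seed in zip(CRPV_GROUP2, (920, 921)):
        pdb_id, chain_id = uid.split("_")
        member_rng = np.random.default_rng(seed)
        muts = sorted(member_rng.choice(150, 3, replace=False))
        chains.append(parent2.copy(
            pdb_id=pdb_id, chain_id=chain_id,
            sequence=mutate_at(parent2.sequence, muts, member_rng),
            xyz=parent2.xyz + member_rng.normal(0, 0.3, parent2.xyz.shape),
        ))
    return chains


MINIMAL_CIF = """\
data_TEST
_entry.id TEST
_exptl.method 'X-RAY DIFFRACTION'
_refine.ls_d_res_high 2.10
_pdbx_audit_revision_history.revision_date 2019-05-08
#
loop_
_entity.id
_entity.pdbx_description
_entity.src_method
1 "RNA hairpin" nat
2 "RNA hairpin copy" nat
3 "some protein" man
#
loop_
_entity_poly.entity_id
_entity_poly.type
_entity_poly.pdbx_seq_one_letter_code_can
_entity_poly.pdbx_strand_id
1 polyribonucleotide {seq1} A
2 polyribonucleotide {seq2} B
3 polypeptide(L) MKV C
#
loop_
_entity_src_nat.entity_id
_entity_src_nat.pdbx_organism_scientific
1 'Escherichia coli'
2 'Escherichia coli'
#
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.label_atom_id
_atom_site.label_comp_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.label_alt_id
_atom_site.auth_asym_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.pdbx_PDB_model_num
{atoms}#
"""


def minimal_cif_text(n_residues: int = 25) -> str:
    """A small handwritten-style mmCIF: two 25-nt RNA chains + one protein."""
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGU"), size=n_residues))
    helix = make_helix_chain(n_residues, seed=5).xyz
    rows = []
    serial = 1
    for eid, asym in (("1", "A"), ("2", "B")):
        offset = 0.0 if asym == "A" else 30.0
        for pos in range(1, n_residues + 1):
            x, y, z = helix[pos - 1]
            rows.append(f"ATOM {serial} \"C3'\" {seq[pos - 1]} {eid} {pos} . "
                        f"{asym} {x + offset:.3f} {y:.3f} {z:.3f} 1\n")
            serial += 1
    # protein atoms: CA only, ignored by the RNA chain filter
    for pos in range(1, 4):
        rows.append(f"ATOM {serial} CA MET 3 {pos} . C "
                    f"{50 + pos}.0 0.0 0.0 1\n")
        serial += 1
    return MINIMAL_CIF.format(seq1=seq, seq2=seq, atoms="".join(rows))


@pytest.fixture()
def minimal_cif(tmp_path):
    path = tmp_path / "test.cif"
    path.write_text(minimal_cif_text())
    return path
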