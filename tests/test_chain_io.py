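"""Structure parsing, inclusion filters, annotations and dataset TSV I/O."""

import numpy as np
import pytest

from rnanr import (NRDataset, RedundantCluster, RNAChain, annotate,
                   assign_organism, filter_chains, parse_structure,
                   read_dataset, write_dataset)
from rnanr.config import DEFAULT_CONFIG
from rnanr.fixtures import make_helix_chain, perturb_chain
from rnanr.pdbio import SchemaError, StructureParseError, write_chain_pdb


class TestParseStructure:
    def test_mmcif_rna_chains(self, minimal_cif):
        chains = parse_structure(minimal_cif)
        assert [c.chain_uid for c in chains] == ["TEST_A", "TEST_B"]
        for c in chains:
            assert c.n_coords == 25
            assert c.polymer_length == 25
            assert c.organism == "Escherichia coli"
            assert c.resolution == 2.10
            assert c.method == "X-RAY DIFFRACTION"
            assert c.release_date == "2019-05-08"
            assert c.macromolecule_name.startswith("RNA hairpin")

    def test_protein_chain_excluded(self, minimal_cif):
        chains = parse_structure(minimal_cif)
        assert "TEST_C" not in {c.chain_uid for c in chains}

    def test_protein_only_structure_yields_empty_list(self, tmp_path):
        path = tmp_path / "prot.pdb"
        path.write_text(
            "HEADER    PROTEIN                                 01-JAN-20   "
            "XXXX\n"
            "ATOM      1  CA  MET A   1      11.000   6.000  -6.000  1.00"
            "  0.00           C\n"
            "ATOM      2  CA  ALA A   2      14.000   6.000  -6.000  1.00"
            "  0.00           C\n"
            "ATOM      3  CA  GLY A   3      17.000   6.000  -6.000  1.00"
            "  0.00           C\nEND\n")
        assert parse_structure(path) == []

    def test_dna_chain_excluded(self, tmp_path):
        path = tmp_path / "dna.pdb"
        path.write_text(
            "ATOM      1  C3'  DA A   1      11.000   6.000  -6.000  1.00"
            "  0.00           C\n"
            "ATOM      2  C3'  DC A   2      14.000   6.000  -6.000  1.00"
            "  0.00           C\nEND\n")
        assert parse_structure(path) == []

    def test_garbled_file_raises_named_error(self, tmp_path):
        path = tmp_path / "junk.cif"
        path.write_text("this is not a structure\n")
        with pytest.raises(StructureParseError, match="junk.cif"):
            parse_structure(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureParseError):
            parse_structure(tmp_path / "nope.pdb")

    def test_uids_unique_within_parse(self, minimal_cif):
        uids = [c.chain_uid for c in parse_structure(minimal_cif)]
        assert len(uids) == len(set(uids))


class TestPdbRoundTrip:
    def test_full_metadata_round_trip(self, tmp_path):
        chain = make_helix_chain(30, seed=3, pdb_id="T003",
                                 organism="Homo sapiens",
                                 method="X-RAY DIFFRACTION", resolution=1.9,
                                 release_date="2018-11-30")
        back = parse_structure(write_chain_pdb(chain, tmp_path / "c.pdb"))
        assert len(back) == 1
        got = back[0]
        for field in ("chain_uid", "sequence", "polymer_length",
                      "resolution", "method", "release_date", "organism",
                      "macromolecule_name"):
            assert getattr(got, field) == getattr(chain, field), field
        assert np.allclose(got.xyz, chain.xyz, atol=1e-3)

    def test_missing_coordinates_survive(self, tmp_path):
        chain = perturb_chain(make_helix_chain(40, seed=9, pdb_id="T009"),
                              drop_coord_frac=0.3, seed=10, pdb_id="T010")
        assert chain.n_coords < chain.polymer_length
        got = parse_structure(write_chain_pdb(chain, tmp_path / "d.pdb"))[0]
        assert got.sequence == chain.sequence
        assert np.array_equal(got.positions, chain.positions)
        assert got.polymer_length == chain.polymer_length


class TestFilterChains:
    @pytest.mark.parametrize("length,kept", [(19, False), (20, True),
                                             (150, True)])
    def test_min_length(self, length, kept):
        chain = make_helix_chain(max(length, 4), seed=1)
        chain = chain.copy(sequence=chain.sequence[:length],
                           polymer_length=length,
                           positions=chain.positions[:length],
                           xyz=chain.xyz[:length])
        assert (chain in filter_chains([chain])) is kept

    def test_update_mode_missing_coordinate_filter(self):
        full = make_helix_chain(100, seed=2)
        sparse = full.copy(positions=full.positions[:4], xyz=full.xyz[:4])
        assert sparse.missing_frac == pytest.approx(0.96)
        assert filter_chains([sparse], update_mode=True) == []
        assert filter_chains([sparse], update_mode=False) == [sparse]

    def test_idempotent_and_order_preserving(self):
        chains = [make_helix_chain(n, seed=n) for n in (25, 19, 40, 21)]
        once = filter_chains(chains)
        assert filter_chains(once) == once
        assert [c.polymer_length for c in once] == [25, 40, 21]


class TestAssignOrganism:
    def test_named_organism_passthrough(self, helix30):
        assert assign_organism(helix30) == "Escherichia coli"

    def test_missing_source_becomes_others(self, helix30):
        assert assign_organism(helix30.copy(organism="")) == "others"
        assert assign_organism(helix30.copy(organism="?")) == "others"

    def test_synthetic_construct(self, helix30):
        chain = helix30.copy(organism="synthetic construct")
        assert assign_organism(chain) == "synthetic construct"


class TestAnnotate:
    def test_rfam_lookup_and_default(self, helix30):
        chains = [helix30.copy(), helix30.copy(pdb_id="ZZZZ")]
        annotate(chains, rfam_map={"H030": "RF00005"}, use_heuristic_bp=False)
        assert chains[0].rfam_family == "RF00005"
        assert chains[1].rfam_family == "undefined"

    def test_base_pair_annotation_passthrough(self, helix30):
        chains = [helix30.copy()]
        annotate(chains, bp_map={"H030_A": 31}, use_heuristic_bp=False)
        assert chains[0].base_pairs == 31

    def test_malformed_tsv_row_skipped_with_warning(self, tmp_path, helix30,
                                                    caplog):
        tsv = tmp_path / "bp.tsv"
        tsv.write_text("chain_uid\tbase_pairs\nH030_A\t12\n\tbroken\n")
        chains = [helix30.copy()]
        with caplog.at_level("WARNING"):
            annotate(chains, bp_map=tsv, use_heuristic_bp=False)
        assert chains[0].base_pairs == 12
        assert any("malformed" in r.message for r in caplog.records)

    def test_tsv_missing_column_is_schema_error(self, tmp_path, helix30):
        tsv = tmp_path / "bad.tsv"
        tsv.write_text("pdb\tfam\nH030\tRF1\n")
        with pytest.raises(SchemaError, match="pdb_id"):
            annotate([helix30.copy()], rfam_map=tsv)


class TestDatasetTSV:
    @staticmethod
    def _dataset():
        return NRDataset([
            RedundantCluster(1, "6W2S_0", {"6W2S_0", "6W2T_A"},
                             organism="Cricket paralysis virus",
                             macromolecule_names=("IRES RNA",),
                             rfam_families=("RF00458",)),
            RedundantCluster(2, "H030_A", {"H030_A"},
                             organism="Escherichia coli"),
        ])

    def test_round_trip(self, tmp_path):
        ds = self._dataset()
        path = write_dataset(ds, tmp_path / "ds.tsv")
        assert read_dataset(path) == ds

    def test_two_member_cluster_is_one_row(self, tmp_path):
        path = write_dataset(self._dataset(), tmp_path / "ds.tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 3  # header + 2 clusters
        assert "6W2S_0,6W2T_A" in lines[1]

    def test_empty_dataset_is_header_only(self, tmp_path):
        path = write_dataset(NRDataset([]), tmp_path / "empty.tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == [
            "Cluster ID", "Representative", "Redundant Cluster", "Organism",
            "Macromolecule Name", "Rfam Family Name"]
        assert read_dataset(path) == NRDataset([])

    def test_missing_column_raises_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Cluster ID\tRepresentative\n1\tA_B\n")
        with pytest.raises(SchemaError, match="Redundant Cluster"):
            read_dataset(path)

    def test_partition_enforced(self):
        with pytest.raises(ValueError, match="more than one cluster"):
            NRDataset([
                RedundantCluster(1, "A_A", {"A_A", "B_B"}),
                RedundantCluster(2, "B_B", {"B_B"}),
            ])


class TestChainInvariants:
    def test_coords_cannot_exceed_sequence(self):
        with pytest.raises(ValueError):
            RNAChain("XXXX", "A", "ACGU", 4, np.arange(1, 6),
                     np.zeros((5, 3)))

    def test_positions_strictly_increasing(self):
        with pytest.raises(ValueError):
            RNAChain("XXXX", "A", "ACGUA", 5, [1, 1, 2],
                     np.zeros((3, 3)))

    def test_alphabet_enforced(self):
        with pytest.raises(ValueError, match="invalid sequence"):
            RNAChain("XXXX", "A", "ACGT", 4, [], np.zeros((0, 3)))
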