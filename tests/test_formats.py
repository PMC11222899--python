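"""Structure/topology/index writers, their round-trips, independent-parser
cross-checks (gemmi, MDAnalysis) and the output bundle."""


import warnings
import zipfile

import numpy as np
import pytest

from peptube import formats as F
from peptube.errors import FormatError
from peptube.cgmap import map_to_beads
from peptube.minimize import MinimizationConfig, write_minimization_config

from peptube.sequences import make_design, parse_sequence
from peptube.topology import generate_cg_topology


class TestPDB:
    def test_nanotube_has_eight_chains_and_eight_closure_records(self, octamer_model, tmp_path):
        path = F.write_pdb(octamer_model, tmp_path / "tube.pdb")
        text = path.read_text()
        chains = {l[21] for l in text.splitlines() if l.startswith("ATOM")}
        assert chains == set("ABCDEFGH")
        conect = [l for l in text.splitlines() if l.startswith("CONECT")]
        assert len(conect) == 8

    def test_round_trip_preserves_coordinates_to_pdb_precision(self, octamer_model, tmp_path):
        path = F.write_pdb(octamer_model, tmp_path / "tube.pdb")
        back = F.read_pdb(path)
        assert back.n_rings == 8
        for orig, rec in zip(octamer_model.rings, back.rings):
            assert len(rec.atoms) == len(orig.atoms)
            assert np.allclose(rec.coordinates(), orig.coordinates(), atol=1e-3)
            assert rec.cyclic

    def test_single_ring_uses_chain_a(self, ring8, tmp_path):
        text = F.write_pdb(ring8, tmp_path / "cp.pdb").read_text()
        chains = {l[21] for l in text.splitlines() if l.startswith("ATOM")}
        assert chains == {"A"}

    def test_duplicate_serial_is_a_parse_error_with_line(self, ring8, tmp_path):
        path = F.write_pdb(ring8, tmp_path / "cp.pdb")
        lines = path.read_text().splitlines()
        atoms = [l for l in lines if l.startswith("ATOM")]
        lines.insert(3, atoms[0])
        path.write_text("\n".join(lines))
        with pytest.raises(FormatError) as err:
            F.read_pdb(path)
        assert err.value.code == "PARSE_ERROR"
        assert err.value.line is not None

    def test_gemmi_reads_the_emitted_pdb(self, octamer_model, tmp_path):
        gemmi = pytest.importorskip("gemmi")
        path = F.write_pdb(octamer_model, tmp_path / "tube.pdb")
        st = gemmi.read_structure(str(path))
        model = st[0]
        assert len(model) == 8  # chains
        total = sum(len(res) for chain in model for res in chain)
        assert total == sum(len(r.atoms) for r in octamer_model.rings)

    def test_coarse_ring_round_trips_as_coarse(self, ring8, cg_mapping, tmp_path):
        cg = map_to_beads(ring8, cg_mapping)
        back = F.read_pdb(F.write_pdb(cg, tmp_path / "cg.pdb"))
        assert back.rings[0].resolution == "coarse"
        assert len(back.rings[0].atoms) == len(cg.atoms)


class TestGRO:
    def test_mdanalysis_reads_emitted_gro_in_nanometres(self, ring8, tmp_path):
        mda = pytest.importorskip("MDAnalysis")
        path = tmp_path / "cp.gro"
        F.write_gro(ring8, path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        assert len(u.atoms) == len(ring8.atoms)
        # MDAnalysis reports angstrom; our writer emitted nm
        assert np.allclose(u.atoms.positions, ring8.coordinates(), atol=1e-2)


class TestTopologyFiles:
    def test_molecule_itp_round_trip_term_sets(self, seq8, cg_mapping, cg_params):
        spec = generate_cg_topology(seq8, cg_mapping, cg_params, molecule_name="CP_R8")
        back = F.parse_molecule_itp(F.write_molecule_itp(spec))
        assert back.molecule_name == spec.molecule_name
        assert back.nrexcl == spec.nrexcl
        assert {b.indices for b in back.bonds} == {b.indices for b in spec.bonds}
        assert {a.indices for a in back.angles} == {a.indices for a in spec.angles}
        assert {(d.indices, d.improper) for d in back.dihedrals} == {
            (d.indices, d.improper) for d in spec.dihedrals
        }
        assert set(back.exclusions) == set(spec.exclusions)
        assert [p.charge for p in back.particles] == [p.charge for p in spec.particles]

    def test_mdanalysis_itp_parser_accepts_emitted_molecule(self, seq8, cg_mapping, cg_params, tmp_path):
        pytest.importorskip("MDAnalysis")
        from MDAnalysis.topology.ITPParser import ITPParser

        spec = generate_cg_topology(seq8, cg_mapping, cg_params, molecule_name="CP_R8")
        path = tmp_path / "mol.itp"
        path.write_text(F.write_molecule_itp(spec))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            top = ITPParser(str(path)).parse()
        assert top.n_atoms == len(spec.particles)
        assert len(top.bonds.values) == len(spec.bonds)
        assert len(top.angles.values) == len(spec.angles)

    def test_system_top_counts_collapse_in_stack_order(self, cg_mapping, cg_params):
        a = generate_cg_topology(parse_sequence("QAEA"), cg_mapping, cg_params, molecule_name="CP_A")
        b = generate_cg_topology(parse_sequence("WAWA"), cg_mapping, cg_params, molecule_name="CP_B")
        files = F.write_topology([a, b], "mix", molecule_order=["CP_A", "CP_A", "CP_B", "CP_A"])
        assert set(files) == {"CP_A.itp", "CP_B.itp", "system.top"}
        name, counts = F.parse_system_top(files["system.top"])
        assert name == "mix"
        assert counts == [("CP_A", 2), ("CP_B", 1), ("CP_A", 1)]

    def test_duplicate_molecule_names_rejected(self, cg_mapping, cg_params):
        a = generate_cg_topology(parse_sequence("QAEA"), cg_mapping, cg_params, molecule_name="CP")
        b = generate_cg_topology(parse_sequence("WAWA"), cg_mapping, cg_params, molecule_name="CP")
        with pytest.raises(FormatError) as err:
            F.write_topology([a, b], "dup")
        assert err.value.code == "DUPLICATE_MOLECULE_NAME"


class TestIndex:
    def test_eight_ring_model_yields_ten_groups(self, octamer_model):
        groups = F.make_index_groups(octamer_model)
        assert len(groups) == 10
        assert set(groups) == {"System", "Backbone"} | {f"CP{i}" for i in range(1, 9)}

    def test_ring_groups_partition_the_system(self, octamer_model):
        groups = F.make_index_groups(octamer_model)
        union = sorted(i for k, v in groups.items() if k.startswith("CP") for i in v)
        assert union == groups["System"]
        assert len(set(union)) == len(union)

    def test_indices_strictly_increase_within_groups(self, octamer_model):
        for indices in F.make_index_groups(octamer_model).values():
            assert all(a < b for a, b in zip(indices, indices[1:]))

    def test_index_file_round_trips(self, octamer_model):
        text = F.write_index_str(octamer_model)
        assert F.parse_index(text) == F.make_index_groups(octamer_model)


class TestBundle:
    def test_auto_name_encodes_profile_and_sequences(self):
        design = make_design(["RRKWLWLW"] * 8, ["antiparallel"] * 7)
        name = F.auto_name("MARTINI3.0", design)
        assert "MARTINI3.0" in name and "RRKWLWLW" in name

    def test_archive_members_and_determinism(self, ring8, tmp_path):
        bundle = F.BuildBundle()
        bundle.add("nanotube.pdb", F.write_pdb_str(ring8))
        bundle.add("index.ndx", F.write_index_str(ring8))
        bundle.add("min.mdp", write_minimization_config(MinimizationConfig()))
        p1 = F.write_bundle(bundle, tmp_path / "a.zip")
        p2 = F.write_bundle(bundle, tmp_path / "b.zip")
        assert p1.read_bytes() == p2.read_bytes()
        members = zipfile.ZipFile(p1).namelist()
        assert members.count("nanotube.pdb") == 1
        assert members.count("index.ndx") == 1
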