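"""Topology/trajectory model, PDB and XYZ round trips, selections."""

import io

import numpy as np
import pytest

from tndyn.core import (
    Atom,
    PDBFormatError,
    SelectionError,
    Topology,
    TopologyError,
    Trajectory,
    calpha,
    mass_of,
    parse_pdb_models,
    read_xyz_frames,
    resolve_selection,
    tn_resid,
    tni_switch,
    write_pdb_models,
    write_xyz_frames,
)


def _atom(i, name="CA", elem="C", resid=1, chain="C"):
    return Atom(i, name, elem, resid, "ALA", chain, mass_of(elem))


def _toy_topology(n=5):
    return Topology(
        atoms=tuple(_atom(i + 1, resid=i + 1) for i in range(n)),
        chain_roles={"C": "TnC"},
    )


def _toy_trajectory(n_frames=3, n_atoms=5, seed=0):
    rng = np.random.default_rng(seed)
    return Trajectory(
        topology=_toy_topology(n_atoms),
        coordinates=rng.uniform(-50, 50, size=(n_frames, n_atoms, 3)),
    )


PDB_2MODEL = """\
MODEL        1
ATOM      1  CA  ALA C   1      11.104  13.207   2.100  1.00  0.00           C
ATOM      2  CA  ALA C   2      14.104  12.207   1.100  1.00  0.00           C
ATOM      3  CA  ALA C   3       1.000   2.000   3.000  1.00  0.00           C
ATOM      4  CA  ALA C   4       4.000   5.000   6.000  1.00  0.00           C
HETATM    5  C1  LIG L   1       7.000   8.000   9.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA C   1      21.104  23.207  12.100  1.00  0.00           C
ATOM      2  CA  ALA C   2      24.104  22.207  11.100  1.00  0.00           C
ATOM      3  CA  ALA C   3      11.000  12.000  13.000  1.00  0.00           C
ATOM      4  CA  ALA C   4      14.000  15.000  16.000  1.00  0.00           C
HETATM    5  C1  LIG L   1      17.000  18.000  19.000  1.00  0.00           C
ENDMDL
END
"""


class TestParsePDB:
    def test_two_models_five_atoms(self):
        traj = parse_pdb_models(PDB_2MODEL)
        assert traj.n_frames == 2
        assert traj.topology.n_atoms == 5
        assert traj.coordinates[0, 0, 0] == pytest.approx(11.104)
        assert traj.coordinates[1, 4] == pytest.approx([17.0, 18.0, 19.0])

    def test_hetatm_chain_defaults_to_ligand_role(self):
        traj = parse_pdb_models(PDB_2MODEL)
        assert traj.topology.chain_roles == {"C": "other", "L": "ligand"}

    def test_chain_roles_override(self):
        traj = parse_pdb_models(PDB_2MODEL, chain_roles={"C": "TnC"})
        assert traj.topology.chain_roles["C"] == "TnC"

    def test_bare_block_without_model_keyword(self):
        bare = "\n".join(l for l in PDB_2MODEL.splitlines()[:6] if not l.startswith(("MODEL", "ENDMDL")))
        traj = parse_pdb_models(bare + "\n")
        assert traj.n_frames == 1
        assert traj.topology.n_atoms == 5

    def test_atom_count_mismatch_raises(self):
        lines = [l for l in PDB_2MODEL.splitlines() if "24.104" not in l]
        with pytest.raises(TopologyError, match="atom count mismatch"):
            parse_pdb_models("\n".join(lines))

    def test_unparseable_record_names_line(self):
        bad = PDB_2MODEL.replace("11.104", "xx.xxx")
        with pytest.raises(PDBFormatError, match="line 2"):
            parse_pdb_models(bad)

    def test_altloc_b_dropped(self):
        line = "ATOM      6  CB BALA C   4       1.000   1.000   1.000  1.00  0.00           C"
        lines = PDB_2MODEL.splitlines()
        lines.insert(6, line)  # inside model 1 only -> would mismatch if kept
        # also insert into model 2 to keep counts honest if it were kept
        traj = parse_pdb_models("\n".join(lines))
        assert traj.topology.n_atoms == 5


class TestWritePDB:
    def test_round_trip_preserves_topology_and_coords(self):
        traj = _toy_trajectory(n_frames=3)
        back = parse_pdb_models(write_pdb_models(traj))
        assert back.n_frames == 3
        np.testing.assert_allclose(back.coordinates, traj.coordinates, atol=1e-3)
        for a, b in zip(back.topology.atoms, traj.topology.atoms):
            assert (a.name, a.element, a.residue_index, a.residue_name, a.chain_id) == (
                b.name, b.element, b.residue_index, b.residue_name, b.chain_id,
            )

    def test_empty_frame_list_writes_zero_models(self):
        text = write_pdb_models(_toy_trajectory(), frame_indices=[])
        assert "MODEL" not in text and "ATOM" not in text

    def test_coordinate_exceeding_field_width(self):
        traj = _toy_trajectory()
        traj.coordinates[0, 0, 0] = 12345.0
        with pytest.raises(PDBFormatError, match="field width"):
            write_pdb_models(traj, [0])

    def test_out_of_range_frame_index(self):
        with pytest.raises(IndexError):
            write_pdb_models(_toy_trajectory(n_frames=2), [5])

    def test_round_trip_against_mdanalysis(self, tmp_path):
        """Independent cross-check: MDAnalysis reads our multi-model PDB and
        sees identical coordinates and residue numbering."""
        mda = pytest.importorskip("MDAnalysis")
        traj = _toy_trajectory(n_frames=2)
        path = tmp_path / "toy.pdb"
        path.write_text(write_pdb_models(traj))
        u = mda.Universe(str(path))
        assert len(u.atoms) == traj.topology.n_atoms
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        np.testing.assert_allclose(frames, traj.coordinates, atol=1e-3)
        assert list(u.atoms.resids) == [a.residue_index for a in traj.topology.atoms]


class TestXYZ:
    def test_round_trip(self):
        traj = _toy_trajectory(n_frames=4)
        back = read_xyz_frames(io.StringIO(write_xyz_frames(traj)), traj.topology)
        np.testing.assert_allclose(back.coordinates, traj.coordinates, atol=1e-6)

    def test_atom_count_mismatch(self):
        traj = _toy_trajectory()
        with pytest.raises(TopologyError, match="atom count mismatch"):
            read_xyz_frames(io.StringIO(write_xyz_frames(traj)), _toy_topology(4))


class TestTopologyInvariants:
    def test_non_contiguous_indices_rejected(self):
        with pytest.raises(TopologyError, match="contiguous"):
            Topology(atoms=(_atom(1), _atom(3)), chain_roles={"C": "TnC"})

    def test_unknown_chain_rejected(self):
        with pytest.raises(TopologyError, match="role"):
            Topology(atoms=(_atom(1, chain="Z"),), chain_roles={"C": "TnC"})

    def test_decreasing_residue_index_rejected(self):
        atoms = (_atom(1, resid=5), _atom(2, resid=3))
        with pytest.raises(TopologyError, match="decreases"):
            Topology(atoms=atoms, chain_roles={"C": "TnC"})

    def test_frame_atom_mismatch_rejected(self):
        with pytest.raises(TopologyError, match="atom count"):
            Trajectory(topology=_toy_topology(5), coordinates=np.zeros((2, 4, 3)))

    def test_nonfinite_coordinates_rejected(self):
        coords = np.zeros((1, 5, 3))
        coords[0, 0, 0] = np.nan
        with pytest.raises(TopologyError, match="finite"):
            Trajectory(topology=_toy_topology(5), coordinates=coords)


class TestSelections:
    def test_tni_switch_resolves_154_164(self, toy_model):
        idx = resolve_selection(toy_model.topology, tni_switch())
        atoms = [toy_model.topology.atoms[i] for i in idx]
        assert {a.residue_index for a in atoms} == set(range(154, 165))
        assert all(toy_model.topology.role_of(a) == "TnI" for a in atoms)

    def test_calpha_counts_full_chain(self, toy_model):
        assert len(resolve_selection(toy_model.topology, calpha("TnC"))) == 161
        assert len(resolve_selection(toy_model.topology, calpha("TnI"))) == 169
        assert len(resolve_selection(toy_model.topology, calpha("TnT"))) == 87

    def test_empty_selection_raises_with_name(self, toy_model):
        sel = tn_resid("TnC", 400, 410)
        with pytest.raises(SelectionError, match="TnC_400..410"):
            resolve_selection(toy_model.topology, sel)

    def test_resolution_is_deterministic_and_ascending(self, toy_model):
        sel = tni_switch() | tn_resid("TnC", 1, 10)
        a = resolve_selection(toy_model.topology, sel)
        b = resolve_selection(toy_model.topology, sel)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.diff(a) > 0)
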