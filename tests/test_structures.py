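"""PAH builders, dimer placement, solvent scenery and file round-trips."""
import numpy as np
import pytest

from pistack.model import SimSystem
from pistack.structures import (
    CC_BOND,
    CH_BOND,
    DimerGeometry,
    build_frozen_solvent_shell,
    build_pah,
    build_stacked_dimer,
    read_pdb,
    read_xyz,
    read_xyz_trajectory,
    write_pdb,
    write_xyz,
    write_xyz_trajectory,
)


class TestMonomers:
    @pytest.mark.parametrize(
        "kind,n_c,n_h",
        [("benzene", 6, 6), ("anthracene", 14, 10), ("phenanthrene", 14, 10)],
    )
    def test_chemical_formula(self, kind, n_c, n_h):
        mol = build_pah(kind)
        assert sum(t == "CA" for t in mol.type_labels) == n_c
        assert sum(t == "HA" for t in mol.type_labels) == n_h
        assert mol.n_atoms == n_c + n_h

    @pytest.mark.parametrize("kind", ["benzene", "anthracene", "phenanthrene"])
    def test_neutral_planar_ideal_geometry(self, kind):
        mol = build_pah(kind)
        assert abs(mol.total_charge) < 1e-9
        assert np.abs(mol.coords[:, 2]).max() < 1e-9  # planar by construction
        # all aromatic C-C contacts at the construction bond length
        carbons = mol.coords[[t == "CA" for t in mol.type_labels]]
        d = np.linalg.norm(carbons[:, None] - carbons[None], axis=-1)
        bonds = d[(d > 0.1) & (d < CC_BOND * 1.05)]
        assert np.allclose(bonds, CC_BOND, atol=1e-6)
        # each hydrogen exactly CH_BOND from its nearest carbon
        hydros = mol.coords[[t == "HA" for t in mol.type_labels]]
        dch = np.linalg.norm(hydros[:, None] - carbons[None], axis=-1).min(axis=1)
        assert np.allclose(dch, CH_BOND, atol=1e-6)

    def test_fusion_carbons_unchargeed_and_bare(self):
        mol = build_pah("anthracene")
        q = dict(zip(mol.atom_names, mol.charges))
        n_zero = sum(1 for n, c in zip(mol.atom_names, mol.charges) if n.startswith("C") and c == 0.0)
        assert n_zero == 4  # the ring-fusion carbons
        assert q["H1"] == pytest.approx(0.115)

    def test_unknown_kind_lists_supported(self):
        with pytest.raises(ValueError, match="benzene"):
            build_pah("coronene")

    def test_builders_deterministic(self):
        a, b = build_pah("phenanthrene"), build_pah("phenanthrene")
        assert np.array_equal(a.coords, b.coords)
        assert a.atom_names == b.atom_names


class TestDimers:
    def test_sandwich_stacks_atoms_exactly(self, benzene):
        sys2 = build_stacked_dimer(benzene, DimerGeometry(3.5))
        m1, m2 = sys2.molecules
        assert np.allclose(m2.coords - m1.coords, [0.0, 0.0, 3.5], atol=1e-12)

    def test_parallel_displaced_com_distance(self, benzene):
        sys2 = build_stacked_dimer(benzene, DimerGeometry(3.5, (1.6, 0.0)))
        assert sys2.com_separation() == pytest.approx(np.hypot(3.5, 1.6), abs=1e-9)

    def test_dimer_com_midway(self, anthracene):
        sys2 = build_stacked_dimer(anthracene, DimerGeometry(3.4, (1.0, 0.5), twist=30.0))
        mid = 0.5 * (sys2.molecules[0].com() + sys2.molecules[1].com())
        whole = np.vstack([m.coords for m in sys2.molecules])
        masses = np.concatenate([m.masses for m in sys2.molecules])
        com_all = (whole * masses[:, None]).sum(0) / masses.sum()
        assert np.allclose(mid, com_all, atol=1e-9)

    def test_twist_preserves_internal_geometry(self, anthracene):
        sys2 = build_stacked_dimer(anthracene, DimerGeometry(3.5, twist=90.0))
        d1 = np.linalg.norm(np.diff(sys2.molecules[0].coords, axis=0), axis=1)
        d2 = np.linalg.norm(np.diff(sys2.molecules[1].coords, axis=0), axis=1)
        assert np.allclose(d1, d2, atol=1e-9)

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(ValueError):
            DimerGeometry(0.0)


class TestSolventShell:
    @pytest.fixture(scope="class")
    def dimer(self, benzene):
        return build_stacked_dimer(benzene, DimerGeometry(3.5, (1.6, 0.0)))

    def test_exclusion_respected(self, dimer):
        shell = build_frozen_solvent_shell(dimer, thickness=5.0, exclusion=2.8, seed=1)
        waters = shell.static_atoms
        assert waters.n_atoms > 0 and waters.n_atoms % 3 == 0
        oxy = waters.coords[[t == "OH1" for t in waters.type_labels]]
        solute = dimer.mobile_coords()
        dmin = np.linalg.norm(oxy[:, None] - solute[None], axis=-1).min()
        assert dmin >= 2.8

    def test_tip3p_composition(self, dimer):
        shell = build_frozen_solvent_shell(dimer, thickness=4.5, exclusion=2.8, seed=2)
        w = shell.static_atoms
        assert w.total_charge == pytest.approx(0.0, abs=1e-9)
        oh = np.linalg.norm(w.coords[1] - w.coords[0])
        assert oh == pytest.approx(0.9572, abs=1e-9)

    def test_seeded_shell_is_bitwise_reproducible(self, dimer):
        s1 = build_frozen_solvent_shell(dimer, thickness=5.0, exclusion=2.8, seed=9)
        s2 = build_frozen_solvent_shell(dimer, thickness=5.0, exclusion=2.8, seed=9)
        assert np.array_equal(s1.static_atoms.coords, s2.static_atoms.coords)

    def test_impossible_placement_rejected(self, dimer):
        with pytest.raises(ValueError):
            build_frozen_solvent_shell(dimer, thickness=2.0, exclusion=2.8)
        with pytest.raises(ValueError):
            build_frozen_solvent_shell(dimer, thickness=0.0)


class TestFileRoundTrips:
    def test_xyz_roundtrip(self, anthracene, tmp_path):
        p = tmp_path / "a.xyz"
        write_xyz(p, anthracene.atom_names, anthracene.coords, comment="t= 1.5 ps")
        names, coords, comment = read_xyz(p)
        assert names == anthracene.atom_names
        assert np.allclose(coords, anthracene.coords, atol=1e-6)
        assert "1.5" in comment

    def test_xyz_trajectory_roundtrip(self, benzene, tmp_path):
        p = tmp_path / "traj.xyz"
        frames = [(0.0, benzene.coords), (2.0, benzene.coords + 1.0)]
        write_xyz_trajectory(p, benzene.atom_names, frames)
        back = read_xyz_trajectory(p)
        assert len(back) == 2
        assert np.allclose(back[1][1], benzene.coords + 1.0, atol=1e-6)
        assert "t= 2" in back[1][2]

    def test_pdb_roundtrip(self, anthracene, tmp_path):
        p = tmp_path / "a.pdb"
        write_pdb(p, anthracene.atom_names, anthracene.coords)
        names, coords, elements = read_pdb(p)
        assert names == anthracene.atom_names
        assert np.allclose(coords, anthracene.coords, atol=1e-3)
        assert elements[:1] == ["C"]

    def test_pdb_readable_by_mdanalysis(self, anthracene, tmp_path):
        """Cross-check the PDB dialect against an independent reader."""
        mda = pytest.importorskip("MDAnalysis")
        p = tmp_path / "a.pdb"
        write_pdb(p, anthracene.atom_names, anthracene.coords)
        u = mda.Universe(str(p))
        assert u.atoms.n_atoms == anthracene.n_atoms
        assert np.allclose(u.atoms.positions, anthracene.coords, atol=1e-3)
        assert list(u.atoms.names) == anthracene.atom_names

    def test_xyz_readable_by_mdanalysis(self, benzene, tmp_path):
        mda = pytest.importorskip("MDAnalysis")
        p = tmp_path / "b.xyz"
        write_xyz(p, benzene.atom_names, benzene.coords)
        u = mda.Universe(str(p))
        assert np.allclose(u.atoms.positions, benzene.coords, atol=1e-4)
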