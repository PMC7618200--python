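"""Structural geometry: parsing, superposition, SASA/BSA, contacts."""

import math

import numpy as np
import pytest

from spopdegron import (
    DEFAULT_RADII,
    Selection,
    StructureModel,
    buried_surface_area,
    ca_rmsd_paired,
    detect_hbonds,
    hydrophobic_contacts,
    interface_report,
    kabsch_superpose,
    load_structure,
    make_toy_complex,
    map_interface_to_degron,
    sasa,
    write_pdb,
)
from spopdegron.structure import AtomRecord, degron_index, sphere_points

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.40  0.00           C
END
"""


class TestLoading:
    def test_minimal_pdb_echo(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        model = load_structure(p)
        assert len(model) == 3
        ca = model.find_atom("A", 1, "CA")
        assert (ca.x, ca.y, ca.z) == pytest.approx((1.458, 0.0, 0.0))
        assert ca.element == "C"

    def test_mmcif_equivalence(self, tmp_path):
        import gemmi

        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        st = gemmi.read_structure(str(p))
        st.setup_entities()
        cif = tmp_path / "mini.cif"
        st.make_mmcif_document().write_file(str(cif))
        a = load_structure(p)
        b = load_structure(cif)
        assert len(a) == len(b)
        assert np.allclose(a.coords(), b.coords())
        assert [x.atom_name for x in a.atoms] == [x.atom_name for x in b.atoms]

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        model = load_structure(p)
        assert len(model) == 1
        assert model.atoms[0].x == pytest.approx(0.0)  # the 0.60 conformer

    def test_parse_failure_reports_path(self, tmp_path):
        p = tmp_path / "junk.cif"
        p.write_text("data_x\n_loop nonsense\n#####")
        with pytest.raises(IOError):
            load_structure(p)

    def test_write_pdb_roundtrip(self, tmp_path):
        model, _ = make_toy_complex("donor_acceptor", r=2.9)
        p = tmp_path / "toy.pdb"
        write_pdb(model, p)
        back = load_structure(p)
        assert len(back) == len(model)
        assert np.allclose(back.coords(), model.coords(), atol=1e-3)


class TestKabsch:
    def test_identity(self, rng):
        P = rng.normal(size=(10, 3))
        res = kabsch_superpose(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_exact_recovery_of_known_transform(self, rng):
        P = rng.normal(size=(12, 3))
        angle = 0.8
        R = np.array(
            [
                [math.cos(angle), -math.sin(angle), 0],
                [math.sin(angle), math.cos(angle), 0],
                [0, 0, 1],
            ]
        )
        t = np.array([1.0, -2.0, 3.0])
        Q = P @ R.T + t
        res = kabsch_superpose(P, Q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(res.rotation, R, atol=1e-8)
        assert np.allclose(res.translation, t, atol=1e-8)

    def test_proper_rotation_even_for_reflected_input(self, rng):
        P = rng.normal(size=(8, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirror image
        res = kabsch_superpose(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_rigid_invariance(self, rng):
        """RMSD is unchanged when both clouds get the same rigid motion."""
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        base = kabsch_superpose(P, Q).rmsd
        angle = 1.1
        R = np.array(
            [
                [1, 0, 0],
                [0, math.cos(angle), -math.sin(angle)],
                [0, math.sin(angle), math.cos(angle)],
            ]
        )
        t = np.array([5.0, 6.0, -7.0])
        moved = kabsch_superpose(P @ R.T + t, Q @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_matches_quaternion_grid_oracle(self, rng):
        """Agreement with a brute-force quaternion minimizer on random clouds."""

        def quat_to_rot(q):
            w, x, y, z = q / np.linalg.norm(q)
            return np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                    [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                    [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
                ]
            )

        def oracle_rmsd(P, Q):
            Pc = P - P.mean(axis=0)
            Qc = Q - Q.mean(axis=0)

            def cost(q):
                diff = Pc @ quat_to_rot(q).T - Qc
                return math.sqrt(np.mean(np.sum(diff * diff, axis=1)))

            # coarse deterministic quaternion grid, then shrinking refinement
            grid = np.array(
                [
                    [a, b, c, d]
                    for a in (-1, -0.5, 0.5, 1)
                    for b in (-1, -0.5, 0, 0.5, 1)
                    for c in (-1, -0.5, 0, 0.5, 1)
                    for d in (-1, -0.5, 0, 0.5, 1)
                ]
            )
            best_q = min(grid, key=cost)
            step = 0.5
            for _ in range(60):
                cands = [best_q]
                for axis in range(4):
                    for sgn in (-1, 1):
                        q = best_q.copy()
                        q[axis] += sgn * step
                        cands.append(q)
                best_q = min(cands, key=cost)
                step *= 0.8
            return cost(best_q)

        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        assert kabsch_superpose(P, Q).rmsd == pytest.approx(oracle_rmsd(P, Q), abs=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestPairedRmsd:
    def _model(self, positions, chain="A"):
        atoms = [
            AtomRecord(chain, i + 1, "GLY", "CA", "C", *map(float, p))
            for i, p in enumerate(positions)
        ]
        return StructureModel(atoms)

    def test_identical_structures(self):
        pos = [(0, 0, 0), (3, 0, 0), (0, 3, 0), (0, 0, 3), (3, 3, 3)]
        a = self._model(pos)
        b = self._model(pos, chain="B")
        pairs = [(("A", i), ("B", i)) for i in range(1, 6)]
        assert ca_rmsd_paired(a, b, pairs, presuperpose_on=pairs) == pytest.approx(0.0, abs=1e-10)

    def test_presuperposition_removes_global_shift(self):
        pos = [(0, 0, 0), (3, 0, 0), (0, 3, 0), (0, 0, 3), (3, 3, 3)]
        shifted = [(x + 1, y, z) for x, y, z in pos]
        a = self._model(pos)
        b = self._model(shifted, chain="B")
        pairs = [(("A", i), ("B", i)) for i in range(1, 6)]
        assert ca_rmsd_paired(a, b, pairs, presuperpose_on=pairs) == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_displacements(self):
        """Fit residues agree exactly; probe residues carry known offsets,
        so the RMSD is a pen-and-paper root mean square."""
        fit = [(0, 0, 0), (4, 0, 0), (0, 4, 0), (0, 0, 4)]
        probe_a = [(10, 0, 0), (0, 10, 0), (0, 0, 10), (10, 10, 0), (10, 0, 10)]
        offsets = [(1, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 1), (0, 0, 0)]
        probe_b = [tuple(p + o for p, o in zip(pa, off)) for pa, off in zip(probe_a, offsets)]
        a = self._model(fit + probe_a)
        b = self._model(fit + probe_b, chain="B")
        fit_pairs = [(("A", i), ("B", i)) for i in range(1, 5)]
        probe_pairs = [(("A", i), ("B", i)) for i in range(5, 10)]
        expected = math.sqrt(sum(x * x + y * y + z * z for x, y, z in offsets) / 5)
        got = ca_rmsd_paired(a, b, probe_pairs, presuperpose_on=fit_pairs)
        # presuperposition on the (exactly matching) fit set is near-identity
        # only approximately, since the probe offsets do not enter the fit
        assert got == pytest.approx(expected, rel=1e-6)

    def test_missing_calpha_named(self):
        a = self._model([(0, 0, 0), (3, 0, 0), (0, 3, 0)])
        b = self._model([(0, 0, 0), (3, 0, 0), (0, 3, 0)], chain="B")
        with pytest.raises(LookupError, match="B/9"):
            ca_rmsd_paired(a, b, [(("A", 1), ("B", 9))], None)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        model, truth = make_toy_complex("isolated_atoms", n=1)
        area = sasa(model)[0]
        expected = 4 * math.pi * (DEFAULT_RADII["C"] + 1.4) ** 2
        assert truth["sasa"][0] == pytest.approx(expected)
        assert area == pytest.approx(expected, rel=0.005)

    def test_distant_spheres_unoccluded(self):
        model, truth = make_toy_complex("two_spheres", d=100.0)
        areas = sasa(model)
        assert areas == pytest.approx(truth["sasa_isolated"], rel=0.005)
        assert truth["bsa_total"] == 0.0

    def test_overlapping_spheres_match_cap_formula(self):
        for d in (2.0, 3.5, 5.0):
            model, truth = make_toy_complex("two_spheres", d=d)
            areas = sasa(model)
            assert areas[0] == pytest.approx(truth["sasa"][0], rel=0.01)
            assert areas[1] == pytest.approx(truth["sasa"][1], rel=0.01)

    def test_quadrature_convergence(self):
        """Doubling the point count changes per-atom areas by < 0.5 %."""
        model, _ = make_toy_complex("two_spheres", d=2.5)
        coarse = sasa(model, points_per_atom=960)
        fine = sasa(model, points_per_atom=1920)
        assert np.all(np.abs(fine - coarse) / fine < 0.005)

    def test_deterministic(self):
        model, _ = make_toy_complex("two_spheres", d=2.5)
        assert np.array_equal(sasa(model), sasa(model))

    def test_unknown_element_needs_default_radius(self):
        atoms = [AtomRecord("A", 1, "UNK", "XE1", "XE", 0.0, 0.0, 0.0)]
        model = StructureModel(atoms)
        with pytest.raises(ValueError, match="XE"):
            sasa(model)
        area = sasa(model, default_radius=2.0)[0]
        assert area == pytest.approx(4 * math.pi * 3.4**2, rel=0.005)

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(500)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_total_sasa_cross_checked_against_mdtraj(self, tmp_path, rng):
        """Independent implementation check: total SASA of a random C/N/O/S
        cluster agrees with mdtraj's Shrake-Rupley (same radii) to < 1 %."""
        md = pytest.importorskip("mdtraj")
        elements = ["C", "N", "O", "C", "C", "O", "N", "C", "S", "C",
                    "C", "O", "N", "C", "C", "C", "O", "N", "C", "C"]
        atoms = [
            AtomRecord("A", i + 1, "GLY", f"{e}{i + 1}"[:4], e,
                       *map(float, rng.normal(scale=3.0, size=3)))
            for i, e in enumerate(elements)
        ]
        model = StructureModel(atoms)
        ours = float(sasa(model, points_per_atom=3000).sum())
        pdb = tmp_path / "cluster.pdb"
        write_pdb(model, pdb)
        traj = md.load(str(pdb))
        theirs = float(md.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960).sum()) * 100.0
        assert abs(ours - theirs) / theirs < 0.01


class TestBsa:
    def test_far_apart_chains_bury_nothing(self):
        model, _ = make_toy_complex("two_spheres", d=100.0)
        out = buried_surface_area(model, Selection(chain="A"), Selection(chain="B"))
        assert out["bsa_total"] == pytest.approx(0.0, abs=1e-6)

    def test_two_sphere_cap_oracle(self):
        model, truth = make_toy_complex("two_spheres", d=2.0)
        out = buried_surface_area(model, Selection(chain="A"), Selection(chain="B"))
        assert out["bsa_total"] == pytest.approx(truth["bsa_total"], rel=0.01)
        assert out["interface_area"] == pytest.approx(truth["bsa_total"] / 2, rel=0.01)

    def test_symmetric_and_nonnegative(self):
        model, _ = make_toy_complex("two_spheres", d=3.0)
        ab = buried_surface_area(model, Selection(chain="A"), Selection(chain="B"))
        ba = buried_surface_area(model, Selection(chain="B"), Selection(chain="A"))
        assert ab["bsa_total"] == pytest.approx(ba["bsa_total"], abs=1e-9)
        assert ab["bsa_total"] >= 0

    def test_overlapping_selections_rejected(self):
        model, _ = make_toy_complex("two_spheres", d=3.0)
        with pytest.raises(ValueError, match="disjoint"):
            buried_surface_area(model, Selection(chain="A"), Selection())


class TestHbonds:
    def test_toy_pair_within_cutoff(self):
        model, truth = make_toy_complex("donor_acceptor", r=2.9)
        bonds = detect_hbonds(model, Selection(chain="A"), Selection(chain="B"))
        assert len(bonds) == truth["n_hbonds"] == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].donor.atom_name == "N"
        assert bonds[0].acceptor.atom_name == "O"

    def test_beyond_cutoff_empty(self):
        model, truth = make_toy_complex("donor_acceptor", r=3.8)
        assert truth["n_hbonds"] == 0
        assert detect_hbonds(model, Selection(chain="A"), Selection(chain="B")) == []

    def test_symmetric_in_selections(self):
        model, _ = make_toy_complex("donor_acceptor", r=2.9)
        ab = detect_hbonds(model, Selection(chain="A"), Selection(chain="B"))
        ba = detect_hbonds(model, Selection(chain="B"), Selection(chain="A"))
        assert {(b.donor.key, b.acceptor.key) for b in ab} == {
            (b.donor.key, b.acceptor.key) for b in ba
        }

    def test_explicit_hydrogen_angle_filter(self):
        # donor N with an H pointing AWAY from the acceptor: rejected
        atoms = [
            AtomRecord("A", 1, "ALA", "N", "N", 0.0, 0.0, 0.0),
            AtomRecord("A", 1, "ALA", "H", "H", 1.0, 0.0, 0.0),  # opposite side
            AtomRecord("B", 2, "ALA", "O", "O", -2.9, 0.0, 0.0),
        ]
        model = StructureModel(atoms)
        assert detect_hbonds(model, Selection(chain="A"), Selection(chain="B")) == []
        # flip the hydrogen toward the acceptor: accepted
        atoms[1] = AtomRecord("A", 1, "ALA", "H", "H", -1.0, 0.0, 0.0)
        model = StructureModel(atoms)
        assert len(detect_hbonds(model, Selection(chain="A"), Selection(chain="B"))) == 1


class TestContactsAndMapping:
    def test_hydrophobic_contact_detection(self):
        atoms = [
            AtomRecord("A", 1, "LEU", "CD1", "C", 0.0, 0.0, 0.0),
            AtomRecord("B", 2, "PHE", "CZ", "C", 4.0, 0.0, 0.0),
            AtomRecord("B", 3, "SER", "CB", "C", 0.0, 4.0, 0.0),  # polar carbon
        ]
        model = StructureModel(atoms)
        contacts = hydrophobic_contacts(model, Selection(chain="A"), Selection(chain="B"))
        assert len(contacts) == 1
        assert contacts[0].atom_b.residue_name == "PHE"

    @pytest.mark.parametrize(
        "residue, anchor, expected",
        [(134, 134, 1), (130, 134, -4), (141, 134, 8), (138, 134, 5), (129, 134, -5)],
    )
    def test_degron_index_arithmetic(self, residue, anchor, expected):
        assert degron_index(residue, anchor) == expected

    def test_contact_mapping_with_flank(self):
        model, _ = make_toy_complex("donor_acceptor", r=2.9)
        report = interface_report(model, Selection(chain="A"), Selection(chain="B"))
        # donor is chain A residue 1; pretend the degron anchor is residue 1
        table = map_interface_to_degron(report, anchor=1, peptide_selection=Selection(chain="A"))
        assert list(table["index"]) == ["+1"]
        assert table.iloc[0]["hbonds"] == 1
        # with a motif range that excludes +1, the contact is labeled flank
        table2 = map_interface_to_degron(
            report, anchor=5, peptide_selection=Selection(chain="A"), motif_indices=range(1, 6)
        )
        assert list(table2["index"]) == ["flank"]

    def test_interface_report_json(self, tmp_path):
        model, _ = make_toy_complex("donor_acceptor", r=2.9)
        report = interface_report(model, Selection(chain="A"), Selection(chain="B"))
        out = tmp_path / "report.json"
        report.to_json(out)
        import json

        payload = json.loads(out.read_text())
        assert payload["buried_area_total"] >= 0
        assert len(payload["hbonds"]) == 1
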