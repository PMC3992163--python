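import numpy as np
import pytest

import ladkit as lk
from ladkit.structure import BackboneStructure, Residue
from ladkit.surface import TriMesh, VertexAssociation


def antipodal_pair(mesh):
    v = mesh.vertices
    j = int(np.argmin(np.linalg.norm(v + v[0], axis=1)))
    return 0, j


class TestVertexGeodesics:
    def test_source_equals_target_is_zero(self, icosphere4):
        assert lk.vertex_geodesics(icosphere4, [3], [3])[0, 0] == 0.0

    def test_adjacent_vertices_on_plane_give_edge_length(self):
        plane = lk.make_analytic_mesh("plane", n=5)
        # vertices 0 and 1 are grid neighbours 0.25 apart
        d = lk.vertex_geodesics(plane, [0], [1])[0, 0]
        assert d == pytest.approx(0.25, abs=1e-12)

    def test_straight_grid_path_equals_euclidean(self):
        plane = lk.make_analytic_mesh("plane", n=11)
        d = lk.vertex_geodesics(plane, [0], [10])[0, 0]
        assert d == pytest.approx(1.0, abs=1e-9)

    def test_icosphere_antipodal_distance_near_pi(self, icosphere4):
        i, j = antipodal_pair(icosphere4)
        d = lk.vertex_geodesics(icosphere4, [i], [j])[0, 0]
        assert d == pytest.approx(np.pi, rel=0.03)

    def test_geodesic_at_least_chord_everywhere(self, icosphere4):
        rng = np.random.default_rng(11)
        src = rng.choice(icosphere4.n_vertices, 15, replace=False)
        table = lk.vertex_geodesics(icosphere4, src, np.arange(icosphere4.n_vertices))
        chords = np.linalg.norm(
            icosphere4.vertices[src][:, None, :] - icosphere4.vertices[None, :, :], axis=2
        )
        assert np.all(table >= chords - 1e-9)

    def test_symmetry(self, icosphere4):
        idx = [0, 100, 500]
        t = lk.vertex_geodesics(icosphere4, idx, idx)
        np.testing.assert_allclose(t, t.T, atol=1e-9)

    def test_triangle_inequality_on_samples(self, icosphere4):
        rng = np.random.default_rng(5)
        idx = rng.choice(icosphere4.n_vertices, 12, replace=False)
        t = lk.vertex_geodesics(icosphere4, idx, idx)
        for i in range(len(idx)):
            for j in range(len(idx)):
                for k in range(len(idx)):
                    assert t[i, j] <= t[i, k] + t[k, j] + 1e-9

    def test_disconnected_pair_flagged_nan(self):
        tetra = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
        two = TriMesh(
            np.vstack([tetra, tetra + [10.0, 0, 0]]),
            np.vstack([faces, faces + 4]),
        )
        t = lk.vertex_geodesics(two, [0], [5])
        assert np.isnan(t[0, 0])


class TestAtomGD:
    def _assoc(self, mapping):
        return VertexAssociation(owner=mapping)

    def test_single_vertex_atoms_reduce_to_vertex_gd(self):
        assoc = self._assoc({0: (1, "CA"), 1: (2, "CA")})
        vgd = np.array([[0.0, 7.5], [7.5, 0.0]])
        assert lk.atom_gd(assoc, vgd, (1, "CA"), (2, "CA")) == 7.5

    def test_mean_over_vertex_pairs(self):
        # M = 2, N = 1 with vertex geodesics {3.0, 5.0} -> 4.0
        assoc = self._assoc({0: (1, "CA"), 1: (1, "CA"), 2: (2, "CA")})
        vgd = np.zeros((3, 3))
        vgd[0, 2] = vgd[2, 0] = 3.0
        vgd[1, 2] = vgd[2, 1] = 5.0
        assert lk.atom_gd(assoc, vgd, (1, "CA"), (2, "CA")) == pytest.approx(4.0)
        assert lk.atom_gd(assoc, vgd, (2, "CA"), (1, "CA")) == pytest.approx(4.0)

    def test_atom_without_vertices_errors(self):
        assoc = self._assoc({0: (1, "CA")})
        with pytest.raises(ValueError, match="no associated vertices"):
            lk.atom_gd(assoc, np.zeros((1, 1)), (1, "CA"), (2, "CA"))


def single_atom_residue(pos, xyz, tag="CA"):
    return Residue(seq_pos=pos, resname="ALA", atoms={tag: np.array(xyz, dtype=float)})


class TestResidueDistanceMatrix:
    def test_two_single_atom_residues_ed(self):
        s = BackboneStructure(
            id="t", residues=[single_atom_residue(1, (0, 0, 0)), single_atom_residue(2, (7.25, 0, 0))]
        )
        dmat = lk.residue_distance_matrix(s, metric="ED")
        assert dmat.values[0, 1] == pytest.approx(7.25)
        assert dmat.values[1, 0] == pytest.approx(7.25)
        assert dmat.values[0, 0] == 0.0

    def test_mean_over_atom_pairs_ed(self):
        # residue 1 has atoms at distances {2.0, 4.0} from residue 2's atom
        r1 = Residue(
            seq_pos=1,
            resname="ALA",
            atoms={"N": np.array([-2.0, 0, 0.0]), "CA": np.array([-4.0, 0, 0.0])},
        )
        r2 = single_atom_residue(2, (0, 0, 0))
        s = BackboneStructure(id="t", residues=[r1, r2])
        dmat = lk.residue_distance_matrix(s, metric="ED")
        assert dmat.values[0, 1] == pytest.approx(3.0)

    def test_gd_at_least_ed_on_sphere_shell(self, icosphere4):
        """Residue-level GD inherits GD >= ED from the vertex level."""
        # two fake residues owning vertex patches on the unit sphere
        owner = {}
        patch_a = [0, 1, 2]
        i, j = antipodal_pair(icosphere4)
        patch_b = [j]
        for v in patch_a:
            owner[v] = (1, "CA")
        for v in patch_b:
            owner[v] = (2, "CA")
        assoc = VertexAssociation(owner=owner)
        verts = sorted(owner)
        vidx = {v: k for k, v in enumerate(verts)}
        table = lk.vertex_geodesics(icosphere4, verts, verts)
        gd = lk.atom_gd(assoc, table, (1, "CA"), (2, "CA"), vertex_index=vidx)
        ed = np.mean(
            [np.linalg.norm(icosphere4.vertices[a] - icosphere4.vertices[j]) for a in patch_a]
        )
        assert gd >= ed

    def test_ed_matrix_exactly_rigid_invariant(self, helix10):
        from scipy.spatial.transform import Rotation

        from ladkit.synth import rigid_transform

        moved = rigid_transform(
            helix10, Rotation.from_euler("zyx", [17, 42, -8], degrees=True), translation=[1, 2, 3]
        )
        d0 = lk.residue_distance_matrix(helix10, metric="ED")
        d1 = lk.residue_distance_matrix(moved, metric="ED")
        np.testing.assert_allclose(d0.values, d1.values, atol=1e-9)

    def test_gd_pipeline_on_chain(self, helix10, helix10_mesh):
        mesh = lk.simplify_mesh(helix10_mesh, 0.15)
        assoc = lk.associate_vertices(mesh, helix10)
        gd = lk.residue_distance_matrix(helix10, assoc=assoc, mesh=mesh, metric="GD")
        ed = lk.residue_distance_matrix(helix10, assoc=assoc, metric="ED")
        assert gd.values.shape == ed.values.shape
        np.testing.assert_allclose(gd.values, gd.values.T, atol=1e-9)
        assert np.all(np.isfinite(gd.values))
        # averaged surface paths dominate averaged chords on a connected mesh
        off_diag = ~np.eye(len(gd), dtype=bool)
        assert np.all(gd.values[off_diag] > 0)

    def test_gd_requires_mesh(self, helix10):
        with pytest.raises(ValueError, match="GD requires"):
            lk.residue_distance_matrix(helix10, metric="GD")
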