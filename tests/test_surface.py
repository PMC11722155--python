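"""SAS areas, SES triangulation and external-surfacer interoperability."""

import numpy as np
import pytest

from gbcplx.errors import MeshFormatError
from gbcplx.io_structures import MolecularEntity
from gbcplx.surface import (
    compute_sas,
    extract_patches,
    fibonacci_sphere,
    generate_nanoshaper_input,
    parse_msms_surface,
    triangulate_ses,
)

from conftest import make_atom


class TestSas:
    def test_single_atom_closed_form(self, sphere_entity):
        sas = compute_sas(sphere_entity, probe_radius=1.4)
        exact = 4 * np.pi * (2.0 + 1.4) ** 2
        assert sas.total_area == pytest.approx(exact, rel=1e-12)

    def test_fully_buried_atom_zero_area(self):
        ent = MolecularEntity(
            [make_atom(1, (0, 0, 0), 1.0), make_atom(2, (0.2, 0, 0), 5.0)]
        )
        sas = compute_sas(ent)
        assert sas.per_atom_area[0] == 0.0

    def test_two_atom_overlap_vs_refined_sampling(self):
        ent = MolecularEntity(
            [make_atom(1, (0, 0, 0), 1.6), make_atom(2, (2.2, 0, 0), 1.5)]
        )
        coarse = compute_sas(ent, n_sphere_points=960)
        fine = compute_sas(ent, n_sphere_points=9600)
        assert coarse.total_area == pytest.approx(fine.total_area, rel=0.02)

    def test_far_pair_equals_sum_of_singles(self):
        a = MolecularEntity([make_atom(1, (0, 0, 0), 1.8)])
        b = MolecularEntity([make_atom(2, (100, 0, 0), 1.5)])
        ab = MolecularEntity(list(a.atoms) + list(b.atoms))
        assert compute_sas(ab).total_area == pytest.approx(
            compute_sas(a).total_area + compute_sas(b).total_area, rel=1e-12
        )


class TestSes:
    def test_single_atom_area_within_one_percent(self, sphere_surface):
        exact = 4 * np.pi * 2.0**2
        assert abs(sphere_surface.total_area - exact) / exact < 0.01

    def test_mesh_closed_and_normals_unit(self, sphere_surface):
        # closure was already enforced at construction; re-check edge counts
        tri = sphere_surface.triangles
        edges = np.sort(
            np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert np.all(counts == 2)
        norms = np.linalg.norm(sphere_surface.vertex_normals, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)

    def test_far_separated_atoms_give_two_sphere_components(self):
        ent = MolecularEntity(
            [make_atom(1, (0, 0, 0), 2.0), make_atom(2, (100, 0, 0), 2.0)]
        )
        surf = triangulate_ses(ent)
        assert surf.n_components == 2
        exact = 4 * np.pi * 4.0
        assert surf.total_area == pytest.approx(2 * exact, rel=0.01)

    def test_divergence_volume_matches_voxel_count(self, two_sphere_entity):
        surf = triangulate_ses(two_sphere_entity)
        # voxel-count oracle: SES interior = points at least a probe radius
        # from the accessible region, with the distance computed by exact
        # two-sphere geometry (nearest free spherical cap or the
        # intersection circle of the inflated spheres)
        h, rp = 0.2, 1.4
        pos, rad = two_sphere_entity.positions, two_sphere_entity.radii
        c1, c2 = pos
        R1, R2 = rad + rp
        lo, hi = pos.min(0) - 6, pos.max(0) + 6
        axes = [np.arange(lo[d], hi[d] + h, h) for d in range(3)]
        G = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        a1 = np.linalg.norm(G - c1, axis=1)
        a2 = np.linalg.norm(G - c2, axis=1)
        inside = (a1 < R1) | (a2 < R2)
        # projections onto each inflated sphere, valid where outside the other
        eps = 1e-12
        p1 = c1 + (G - c1) * (R1 / np.maximum(a1, eps))[:, None]
        p2 = c2 + (G - c2) * (R2 / np.maximum(a2, eps))[:, None]
        d1 = np.where(np.linalg.norm(p1 - c2, axis=1) >= R2, R1 - a1, np.inf)
        d2 = np.where(np.linalg.norm(p2 - c1, axis=1) >= R1, R2 - a2, np.inf)
        # distance to the intersection circle of the two inflated spheres
        dcc = np.linalg.norm(c2 - c1)
        u = (c2 - c1) / dcc
        t = (dcc**2 + R1**2 - R2**2) / (2 * dcc)
        rho = np.sqrt(R1**2 - t**2)
        s = (G - c1) @ u
        q = np.linalg.norm(G - c1 - s[:, None] * u[None, :], axis=1)
        dcirc = np.sqrt((s - t) ** 2 + (q - rho) ** 2)
        dist = np.minimum(np.minimum(d1, d2), dcirc)
        voxel_volume = float((inside & (dist >= rp)).sum()) * h**3
        assert surf.enclosed_volume() == pytest.approx(voxel_volume, rel=0.02)

    def test_volume_error_decreases_under_refinement(self, sphere_entity):
        exact = 4.0 / 3.0 * np.pi * 8.0
        errs = []
        for h, n in ((0.8, 256), (0.5, 1024), (0.25, 4096)):
            surf = triangulate_ses(sphere_entity, grid_spacing=h, n_surface_samples=n)
            errs.append(abs(surf.enclosed_volume() - exact) / exact)
        assert errs[0] > errs[1] > errs[2]


class TestPatches:
    def test_patch_areas_partition_mesh_area(self, sphere_surface, sphere_patches):
        assert sphere_patches.total_area == pytest.approx(
            sphere_surface.total_area, rel=1e-9
        )

    def test_single_atom_owns_every_patch(self, sphere_patches):
        assert np.all(sphere_patches.owner_atom == 0)

    def test_closure_of_weighted_normals(self, sphere_patches):
        resultant = (sphere_patches.normals * sphere_patches.areas[:, None]).sum(0)
        assert np.linalg.norm(resultant) / sphere_patches.total_area < 0.01

    def test_two_sphere_owner_split(self, two_sphere_entity, two_sphere_patches):
        owners = set(np.unique(two_sphere_patches.owner_atom))
        assert owners == {0, 1}


TETRA_VERT = """\
# comment
# comment
4 1 1.0
0.0 0.0 0.0 -0.577 -0.577 -0.577 0 1 0
1.0 0.0 0.0 1.0 0.0 0.0 0 1 0
0.0 1.0 0.0 0.0 1.0 0.0 0 1 0
0.0 0.0 1.0 0.0 0.0 1.0 0 1 0
"""

TETRA_FACE = """\
# comment
# comment
4 1 1.0
1 2 3 1 1
1 2 4 1 1
1 3 4 1 1
2 3 4 1 1
"""


class TestMsms:
    def test_tetrahedron_roundtrip(self, tmp_path):
        (tmp_path / "t.vert").write_text(TETRA_VERT)
        (tmp_path / "t.face").write_text(TETRA_FACE)
        surf = parse_msms_surface(tmp_path / "t.vert", tmp_path / "t.face")
        assert surf.n_vertices == 4
        assert len(surf.triangles) == 4
        assert surf.triangles.min() == 0  # converted to 0-based

    def test_zero_index_rejected(self, tmp_path):
        (tmp_path / "t.vert").write_text(TETRA_VERT)
        (tmp_path / "t.face").write_text(TETRA_FACE.replace("1 2 3", "0 2 3", 1))
        with pytest.raises(MeshFormatError):
            parse_msms_surface(tmp_path / "t.vert", tmp_path / "t.face")

    def test_header_count_mismatch_rejected(self, tmp_path):
        (tmp_path / "t.vert").write_text(TETRA_VERT.replace("4 1 1.0", "5 1 1.0"))
        (tmp_path / "t.face").write_text(TETRA_FACE)
        with pytest.raises(MeshFormatError):
            parse_msms_surface(tmp_path / "t.vert", tmp_path / "t.face")


class TestNanoshaperInput:
    def test_xyzr_one_line_per_atom(self, two_sphere_entity):
        xyzr, _ = generate_nanoshaper_input(two_sphere_entity)
        assert len(xyzr.strip().splitlines()) == 2

    def test_default_fallback_parameters(self, two_sphere_entity):
        _, prm = generate_nanoshaper_input(two_sphere_entity)
        assert "Grid_scale = 2" in prm
        assert "Grid_perfil = 95" in prm

    def test_rpns_leaves_existing_prm_untouched(self, two_sphere_entity, tmp_path, monkeypatch):
        from gbcplx.pipeline import RunConfig, prepare_surfacer_inputs

        monkeypatch.chdir(tmp_path)
        prm = tmp_path / "aux.prm"
        prm.write_text("user-tuned parameters\n")
        cfg = RunConfig(
            chains1="A",
            chains2="B",
            surfacer="nanoshaper-files",
            surface_base="aux",
            rpns=True,
        )
        prepare_surfacer_inputs(two_sphere_entity, cfg)
        assert prm.read_text() == "user-tuned parameters\n"
        assert (tmp_path / "aux.xyzr").exists()


def test_fibonacci_sphere_is_unit_and_balanced():
    pts = fibonacci_sphere(500)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.linalg.norm(pts.mean(0)) < 0.01
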