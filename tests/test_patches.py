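"""Particle patch construction, randomized controls, profiles."""

import numpy as np
import pytest

from memthick.graph import build_mesh_graph
from memthick.io import ParticleSet, SurfaceMesh, compute_triangle_geometry
from memthick.patches import (Patch, assign_patch_centers, build_patches,
                              curate_normals, ensemble_profile, patch_mean,
                              patch_profile, randomized_patches, Profile)
from memthick.phantom import (PhantomSpec, add_noise, make_bilayer_phantom,
                              place_particles)


@pytest.fixture(scope="module")
def flat():
    spec = PhantomSpec(geometry="plane", extent=40.0, mesh_edge=2.0,
                       margin=20.0)
    vol, mesh, _ = make_bilayer_phantom(spec)
    return vol, mesh, build_mesh_graph(mesh)


class TestAssignCenters:
    def test_far_particle_excluded_by_24nm_cutoff(self, flat):
        _, mesh, _ = flat
        p_near = mesh.centroids[10]
        p_far = mesh.centroids[10] + np.array([30.0, 0, 0])
        ps = ParticleSet(np.array([0, 1]), np.vstack([p_near, p_far]))
        centers, kept, excluded = assign_patch_centers(ps, mesh, 24.0)
        assert list(kept) == [0] and list(excluded) == [1]
        assert centers[0] == 10

    def test_particle_at_centroid_assigned_there(self, flat):
        _, mesh, _ = flat
        ps = ParticleSet(np.array([0]), mesh.centroids[[42]])
        centers, kept, _ = assign_patch_centers(ps, mesh)
        assert centers[0] == 42

    def test_matches_brute_force_nearest(self, flat, rng):
        _, mesh, _ = flat
        pts = mesh.centroids.mean(0) + rng.normal(0, 15, (20, 3))
        ps = ParticleSet(np.arange(20), pts)
        centers, kept, _ = assign_patch_centers(ps, mesh, max_dist=1e9)
        for pid, c in zip(kept, centers):
            d = np.linalg.norm(mesh.centroids - pts[pid], axis=1)
            assert d[c] == pytest.approx(d.min())


class TestBuildPatches:
    def test_radius_zero_is_singleton(self, flat):
        _, _, graph = flat
        patches = build_patches([5], graph, radius=0.0)
        assert list(patches[0].members) == [5]
        assert patches[0].center == 5

    def test_member_count_tracks_disc_area(self, flat):
        _, mesh, graph = flat
        center = int(np.argmin(np.linalg.norm(
            mesh.centroids - mesh.centroids.mean(0), axis=1)))
        radius = 10.0
        patch = build_patches([center], graph, radius)[0]
        expected = np.pi * radius**2 / mesh.areas.mean()
        assert patch.members.size == pytest.approx(expected, rel=0.2)

    def test_disjoint_components_give_disjoint_patches(self):
        spec = PhantomSpec(geometry="plane", extent=12.0, mesh_edge=3.0)
        _, m1, _ = make_bilayer_phantom(spec)
        m2 = SurfaceMesh(m1.vertices + np.array([50.0, 0, 0]),
                         m1.triangles.copy())
        both = SurfaceMesh(np.vstack([m1.vertices, m2.vertices]),
                           np.vstack([m1.triangles,
                                      m2.triangles + len(m1.vertices)]))
        compute_triangle_geometry(both)
        graph = build_mesh_graph(both)
        n1 = m1.n_triangles
        p = build_patches([0, n1], graph, radius=8.0)
        assert not set(p[0].members) & set(p[1].members)


class TestRandomizedPatches:
    def test_count_matched_and_separated(self, flat):
        _, mesh, graph = flat
        patches = randomized_patches(mesh, graph, mesh.valid, 6,
                                     min_sep=12.0, seed=3)
        assert len(patches) == 6
        centers = mesh.centroids[[p.center for p in patches]]
        d = np.linalg.norm(centers[:, None] - centers[None], axis=2)
        assert d[np.triu_indices(6, 1)].min() > 12.0
        assert all(p.kind == "randomized" for p in patches)

    def test_seed_determinism(self, flat):
        _, mesh, graph = flat
        a = randomized_patches(mesh, graph, mesh.valid, 5, seed=8)
        b = randomized_patches(mesh, graph, mesh.valid, 5, seed=8)
        assert [p.center for p in a] == [p.center for p in b]

    def test_infeasible_placement_reports(self, flat):
        _, mesh, graph = flat
        with pytest.raises(RuntimeError, match="achieved"):
            randomized_patches(mesh, graph, mesh.valid, 200,
                               min_sep=30.0, seed=1)


class TestPatchMean:
    def test_uniform_value(self, flat):
        _, mesh, graph = flat
        patch = build_patches([10], graph, 8.0)[0]
        v = np.full(mesh.n_triangles, 2.5)
        mean, n = patch_mean(v, mesh.areas, patch)
        assert mean == 2.5 and n == patch.members.size

    def test_area_weighting(self):
        verts = np.array([[0, 0, 0], [2, 0, 0], [0, 1, 0],
                          [2, 3, 0]], float)
        mesh = SurfaceMesh(verts, np.array([[0, 1, 2], [0, 1, 3]]))
        compute_triangle_geometry(mesh)        # areas 1 and 3
        patch = Patch(0, 0, np.array([0, 1]))
        values = np.array([0.0, 4.0])
        mean, _ = patch_mean(values, mesh.areas, patch)
        assert mean == pytest.approx(3.0)

    def test_matches_brute_force(self, flat, rng):
        _, mesh, graph = flat
        patch = build_patches([30], graph, 10.0)[0]
        v = rng.normal(size=mesh.n_triangles)
        mean, _ = patch_mean(v, mesh.areas, patch)
        a = mesh.areas[patch.members]
        assert mean == pytest.approx(
            float((v[patch.members] * a).sum() / a.sum()), rel=1e-12)

    def test_all_invalid_yields_missing(self, flat):
        _, mesh, graph = flat
        patch = build_patches([3], graph, 6.0)[0]
        v = np.full(mesh.n_triangles, np.nan)
        mean, n = patch_mean(v, mesh.areas, patch)
        assert np.isnan(mean) and n == 0


class TestCurateNormals:
    def test_normals_toward_particle_unchanged_away_flipped(self, flat):
        _, mesh, graph = flat
        patch = build_patches([50], graph, 8.0)[0]
        above = mesh.centroids[50] + 12.0 * mesh.normals[50]
        below = mesh.centroids[50] - 12.0 * mesh.normals[50]
        cur_above = curate_normals(patch, mesh, above)
        cur_below = curate_normals(patch, mesh, below)
        assert np.all(cur_above.normal_sign == 1.0)
        assert np.all(cur_below.normal_sign == -1.0)

    def test_coincident_particle_keeps_stored_normals(self, flat):
        _, mesh, graph = flat
        patch = build_patches([50], graph, 8.0)[0]
        cur = curate_normals(patch, mesh, mesh.centroids[50])
        assert np.all(cur.normal_sign == 1.0)

    def test_curated_normals_mutually_consistent(self, flat):
        _, mesh, graph = flat
        patch = build_patches([50], graph, 8.0)[0]
        cur = curate_normals(patch, mesh,
                             mesh.centroids[50] + 9.0 * mesh.normals[50])
        normals = mesh.normals[cur.members] * cur.normal_sign[:, None]
        center_n = normals[list(cur.members).index(cur.center)]
        assert np.all(normals @ center_n >= 0)


class TestPatchProfiles:
    def test_extended_scan_has_161_samples(self, flat):
        vol, mesh, graph = flat
        patch = curate_normals(build_patches([60], graph, 8.0)[0], mesh,
                               mesh.centroids[60] + 10 * mesh.normals[60])
        prof = patch_profile(vol, mesh, patch)
        assert len(prof.offsets) == 161
        assert prof.offsets[0] == -10.0 and prof.offsets[-1] == 30.0

    def test_particle_blob_appears_near_its_offset(self, flat):
        vol, mesh, graph = flat
        vol2, ps = place_particles(vol, mesh, 1, offset_along_normal=12.0,
                                   blob_sigma=2.5, blob_amplitude=1.5,
                                   seed=4)
        centers, kept, _ = assign_patch_centers(ps, mesh)
        patch = curate_normals(build_patches(centers, graph, 12.0)[0],
                               mesh, ps.centers[0])
        prof = patch_profile(vol2, mesh, patch)
        beyond = prof.offsets > 6.0
        peak = prof.offsets[beyond][np.argmax(prof.values[beyond])]
        assert abs(peak - 12.0) <= 2.0

    def test_bare_membrane_has_no_outer_peak(self, flat):
        vol, mesh, graph = flat
        noisy = add_noise(vol, 0.1, seed=6)
        patch = curate_normals(build_patches([60], graph, 12.0)[0], mesh,
                               mesh.centroids[60] + 10 * mesh.normals[60])
        prof = patch_profile(noisy, mesh, patch)
        outer = prof.values[prof.offsets > 6.0]
        assert np.nanmax(outer) < 0.0 + 3 * 0.1

    def test_uncurated_patch_rejected(self, flat):
        vol, mesh, graph = flat
        patch = build_patches([3], graph, 6.0)[0]
        with pytest.raises(ValueError, match="curate"):
            patch_profile(vol, mesh, patch)


class TestEnsembleProfile:
    def test_single_profile_identity_zero_spread(self):
        u = np.arange(5.0)
        p = Profile(u, np.array([1.0, 2, 3, 2, 1]))
        off, mean, sd = ensemble_profile([p])
        np.testing.assert_array_equal(mean, p.values)
        assert np.all(sd == 0)

    def test_equal_profiles_mean_equals_them(self):
        u = np.arange(5.0)
        ps = [Profile(u, np.full(5, 2.0)) for _ in range(4)]
        _, mean, sd = ensemble_profile(ps)
        np.testing.assert_allclose(mean, 2.0)
        np.testing.assert_allclose(sd, 0.0)

    def test_mismatched_grids_rejected(self):
        a = Profile(np.arange(5.0), np.zeros(5))
        b = Profile(np.arange(6.0), np.zeros(6))
        with pytest.raises(ValueError, match="mismatch"):
            ensemble_profile([a, b])
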