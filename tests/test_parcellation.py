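import numpy as np
import pytest

from sulcalpits import (
    CohortSpec,
    SmoothingParams,
    Thresholds,
    VertexCorrespondence,
    build_symmetric_parcellation,
    density_map,
    depth_potential_function,
    extract_pits,
    group_watershed,
    make_cohort,
    make_sphere,
    pit_indicator_texture,
    project_texture,
    smooth_texture,
)
from sulcalpits.mesh import geodesic_distance
from sulcalpits.parcellation import DensityMap
from sulcalpits.synthetic import SYNTHETIC_THRESHOLDS, FoldSpec, pick_fold_centers

from oracles import heat_kernel_smooth


class TestSmoothTexture:
    def test_all_zero_stays_zero(self, small_sphere):
        out = smooth_texture(small_sphere, np.zeros(small_sphere.n_vertices))
        assert not np.any(out)

    def test_peak_normalized_and_nonnegative(self, brain_sphere):
        tex = np.zeros(brain_sphere.n_vertices)
        tex[10] = 1.0
        out = smooth_texture(brain_sphere, tex, SmoothingParams(5.0, 60))
        assert np.isclose(out.max(), 1.0)
        assert np.all(out >= 0)

    def test_tiny_fwhm_approximates_identity(self, brain_sphere):
        tex = np.zeros(brain_sphere.n_vertices)
        tex[10] = 1.0
        out = smooth_texture(brain_sphere, tex, SmoothingParams(0.1, 60))
        assert out[10] == 1.0
        others = np.delete(out, 10)
        assert others.max() < 0.01

    def test_matches_heat_kernel_oracle(self, small_sphere):
        # explicit Euler vs dense matrix exponential, both peak-normalized
        tex = np.zeros(small_sphere.n_vertices)
        tex[42] = 1.0
        params = SmoothingParams(fwhm=0.4, n_iter=60)  # ~ r=1 sphere scale
        ours = smooth_texture(small_sphere, tex, params)
        exact = heat_kernel_smooth(small_sphere, tex, params.total_time)
        assert np.max(np.abs(ours - exact)) < 0.05

    def test_decay_with_distance(self, brain_sphere):
        tex = np.zeros(brain_sphere.n_vertices)
        tex[7] = 1.0
        out = smooth_texture(brain_sphere, tex, SmoothingParams(5.0, 60))
        d = geodesic_distance(brain_sphere, [7])
        # bins aligned with the ~6.6 mm edge length: pit, 1-ring, 2-ring, ...
        rings = [out[(d >= lo) & (d < hi)].mean()
                 for lo, hi in ((0, 5), (5, 12), (12, 19), (19, 26))]
        assert all(a > b for a, b in zip(rings, rings[1:]))

    def test_negative_texture_rejected(self, small_sphere):
        tex = np.zeros(small_sphere.n_vertices)
        tex[0] = -1.0
        with pytest.raises(ValueError):
            smooth_texture(small_sphere, tex)

    def test_unstable_step_subdivided(self, small_sphere):
        tex = np.zeros(small_sphere.n_vertices)
        tex[0] = 1.0
        # one giant step would blow past the explicit stability bound
        with pytest.warns(UserWarning, match="stability"):
            out = smooth_texture(small_sphere, tex, SmoothingParams(1.0, 1))
        assert np.all(np.isfinite(out)) and np.isclose(out.max(), 1.0)


class TestProjection:
    def test_identity(self, small_sphere):
        rng = np.random.default_rng(0)
        tex = rng.uniform(size=small_sphere.n_vertices)
        corr = VertexCorrespondence.identity(small_sphere.n_vertices)
        assert np.array_equal(project_texture(tex, corr, small_sphere), tex)

    def test_permutation(self, small_sphere):
        rng = np.random.default_rng(1)
        n = small_sphere.n_vertices
        perm = rng.permutation(n)
        tex = rng.uniform(size=n)
        out = project_texture(tex, VertexCorrespondence(perm), small_sphere)
        assert np.array_equal(out[perm], tex)

    def test_constant_under_onto_correspondence(self, small_sphere):
        n = small_sphere.n_vertices
        perm = np.random.default_rng(2).permutation(n)
        out = project_texture(
            np.full(n, 0.7), VertexCorrespondence(perm), small_sphere
        )
        assert np.allclose(out, 0.7)

    def test_length_mismatch_rejected(self, small_sphere):
        with pytest.raises(ValueError):
            project_texture(
                np.zeros(5),
                VertexCorrespondence.identity(small_sphere.n_vertices),
                small_sphere,
            )
        with pytest.raises(ValueError):
            project_texture(
                np.zeros(small_sphere.n_vertices),
                VertexCorrespondence(
                    np.full(small_sphere.n_vertices, small_sphere.n_vertices + 3)
                ),
                small_sphere,
            )


class TestDensityMap:
    def test_single_subject_identity(self):
        tex = np.array([0.0, 0.5, 1.0])
        d = density_map([tex])
        assert np.array_equal(d.values, tex) and d.n_subjects == 1

    def test_disjoint_peaks_average(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0])
        d = density_map([a, b])
        assert np.allclose(d.values, [0.5, 0.0, 0.5])

    def test_identical_textures_unchanged(self):
        tex = np.array([0.2, 0.9, 0.0])
        d = density_map([tex] * 5)
        assert np.allclose(d.values, tex)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            density_map([np.array([0.0, 1.5])])

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError):
            density_map([np.zeros(3), np.zeros(4)])


class TestGroupWatershed:
    def test_cohort_density_recovers_folds(self):
        base = make_sphere(3, 50.0)
        centers = pick_fold_centers(base, 6)
        folds = [
            FoldSpec(center=int(c), depth=5.0, width=5.0, tier="primary")
            for c in centers
        ]
        spec = CohortSpec(n_case=5, n_control=5, folds=folds, seed=3)
        cohort = make_cohort(spec, build_meshes=True)
        textures = []
        for sid in cohort.subject_ids:
            mesh = cohort.meshes[(sid, "left")]
            res = extract_pits(
                mesh, depth_potential_function(mesh), SYNTHETIC_THRESHOLDS
            )
            tex = smooth_texture(mesh, pit_indicator_texture(res, mesh))
            textures.append(tex)
        dens = density_map(textures)
        cmap, _ = group_watershed(base, dens)
        assert cmap.n_clusters == 6
        for c in centers:
            assert cmap.cluster_labels[c] > 0
        labels = {cmap.cluster_labels[c] for c in centers}
        assert len(labels) == 6  # one cluster per fold

    def test_two_close_peaks_merge(self, brain_sphere):
        # peaks nearer than gThD with a saddle within gThR of the lower one
        d = geodesic_distance(brain_sphere, [0])
        p1 = np.exp(-(d**2) / (2 * 16.0))
        far = int(np.argmin(np.abs(d - 10.0)))
        d2 = geodesic_distance(brain_sphere, [far])
        p2 = 0.9 * np.exp(-(d2**2) / (2 * 16.0))
        dens = DensityMap(np.clip(np.maximum(p1, p2), 0, 1), n_subjects=1)
        cmap, _ = group_watershed(
            brain_sphere, dens, Thresholds(2.0, 15.0, 100.0)
        )
        assert cmap.n_clusters == 1

    def test_single_peak_single_cluster(self, brain_sphere):
        d = geodesic_distance(brain_sphere, [11])
        dens = DensityMap(np.exp(-(d**2) / (2 * 25.0)), n_subjects=1)
        cmap, _ = group_watershed(brain_sphere, dens)
        assert cmap.n_clusters == 1

    def test_all_zero_density_warns(self, brain_sphere):
        with pytest.warns(UserWarning):
            cmap, _ = group_watershed(
                brain_sphere, DensityMap(np.zeros(brain_sphere.n_vertices), 1)
            )
        assert cmap.n_clusters == 0

    def test_zero_density_vertices_unassigned(self, brain_sphere):
        d = geodesic_distance(brain_sphere, [11])
        vals = np.exp(-(d**2) / (2 * 25.0))
        vals[vals < 1e-3] = 0.0
        cmap, _ = group_watershed(brain_sphere, DensityMap(vals, 1))
        assert np.all(cmap.cluster_labels[vals == 0] == 0)
        assert np.all(cmap.cluster_labels[vals > 0] > 0)


class TestSymmetricParcellation:
    def _textures(self, base, centers, fwhm=5.0):
        tex = np.zeros(base.n_vertices)
        tex[centers] = 1.0
        return smooth_texture(base, tex, SmoothingParams(fwhm, 60))

    def test_mirrored_identity_cluster_count(self):
        base = make_sphere(3, 50.0)
        centers = pick_fold_centers(base, 4)
        sm = self._textures(base, centers)
        ident = VertexCorrespondence.identity(base.n_vertices)
        cmap, dens = build_symmetric_parcellation(
            [sm, sm], [sm, sm], [ident, ident], [ident, ident], base
        )
        assert cmap.symmetric
        assert cmap.n_clusters == 4

    def test_left_only_textures_same_clusters(self):
        base = make_sphere(3, 50.0)
        centers = pick_fold_centers(base, 4)
        sm = self._textures(base, centers)
        zero = np.zeros(base.n_vertices)
        ident = VertexCorrespondence.identity(base.n_vertices)
        full, _ = build_symmetric_parcellation(
            [sm], [sm], [ident], [ident], base
        )
        half, dens_half = build_symmetric_parcellation(
            [sm], [zero], [ident], [ident], base
        )
        assert half.n_clusters == full.n_clusters
        assert np.isclose(dens_half.values.max(), 0.5)

    def test_identical_hemispheres_density_equals_texture(self):
        base = make_sphere(2, 50.0)
        sm = self._textures(base, [0])
        ident = VertexCorrespondence.identity(base.n_vertices)
        _, dens = build_symmetric_parcellation(
            [sm], [sm], [ident], [ident], base
        )
        assert np.allclose(dens.values, sm)

    def test_missing_correspondence_rejected(self):
        base = make_sphere(2, 50.0)
        sm = self._textures(base, [0])
        ident = VertexCorrespondence.identity(base.n_vertices)
        with pytest.raises(ValueError):
            build_symmetric_parcellation([sm], [sm], [ident], [], base)
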