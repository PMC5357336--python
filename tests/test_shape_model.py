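"""Shape model: contour sampling, alignment/correspondence, PCA, generation."""

import json

import numpy as np
import pytest

import fluocell as fc
from fluocell.shape_model import Contour

from conftest import circle_mask


def shoelace(points):
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestSampleContour:
    def test_circle_points_lie_on_radius(self):
        mask = circle_mask(20.0)
        c = fc.sample_contour(mask, 64)
        r = np.linalg.norm(c.points - c.centroid(), axis=1)
        assert np.all(np.abs(r - 20.0) < 0.75)

    def test_square_equal_arclength_spacing(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        c = fc.sample_contour(mask, 4)
        closed = np.vstack([c.points, c.points[:1]])
        seps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        assert np.allclose(seps, seps.mean(), rtol=1e-6)

    def test_rectangle_polygon_area_matches_pixel_count(self):
        mask = np.zeros((30, 50), dtype=bool)
        mask[5:25, 5:45] = True          # 40 x 20 = 800 px
        c = fc.sample_contour(mask, 100)
        assert shoelace(c.points) == pytest.approx(800, rel=0.05)

    def test_orientation_and_start_convention(self):
        c = fc.sample_contour(circle_mask(15.0), 32)
        assert c.signed_area() > 0                     # counter-clockwise
        assert c.points[0, 0] == pytest.approx(c.points[:, 0].max())

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:8, 2:8] = True
        mask[12:18, 12:18] = True
        with pytest.raises(ValueError, match="invalid patch"):
            fc.sample_contour(mask, 16)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fc.sample_contour(circle_mask(10.0), 3)


@pytest.fixture(scope="module")
def blob():
    patch = fc.generate_patches(fc.FixtureSpec(n_patches=1, rng_seed=3,
                                               n_points=64))[0]
    return patch.contour


class TestNormalizeAndCorrespond:
    def test_translation_invariance(self, blob):
        shifted = Contour(blob.points + np.array([50.0, -30.0]))
        v = fc.normalize_and_correspond([blob, shifted])
        assert np.linalg.norm(v[0] - v[1]) < 1e-9

    def test_rotation_removed_by_principal_axes(self, blob):
        th = np.pi / 2
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = Contour(blob.points @ rot.T)
        v = fc.normalize_and_correspond([blob, rotated])
        assert np.sum((v[0] - v[1]) ** 2) < 1e-6 * blob.perimeter() ** 2

    def test_cyclic_shift_recovered(self, blob):
        n = blob.n_points
        shifted = Contour(np.roll(blob.points, n // 2, axis=0))
        v = fc.normalize_and_correspond([blob, shifted])
        assert np.linalg.norm(v[0] - v[1]) < 1e-9

    def test_cyclic_shift_matches_brute_force_oracle(self, blob):
        """The correspondence search equals an exhaustive shift/flip scan."""
        rng = np.random.default_rng(0)
        shifted = Contour(np.roll(blob.points, 17, axis=0) + rng.normal(0, 0.01, (64, 2)))
        v = fc.normalize_and_correspond([blob, shifted])
        a, b = v[0].reshape(-1, 2), v[1].reshape(-1, 2)
        best = min(
            min(np.sum((np.roll(cand, k, axis=0) - a) ** 2)
                for k in range(len(b)))
            for cand in (b, b[::-1], -b, -b[::-1])
        )
        assert np.sum((b - a) ** 2) <= best + 1e-12

    def test_mismatched_point_counts_rejected(self, blob):
        other = Contour(blob.points[::2])
        with pytest.raises(ValueError):
            fc.normalize_and_correspond([blob, other])

    def test_collinear_contour_rejected(self):
        t = np.linspace(0, 1, 16)
        line = Contour(np.column_stack([t, 2 * t]))
        blob = Contour(np.column_stack([np.cos(t * 2 * np.pi), np.sin(t * 2 * np.pi)]))
        with pytest.raises(ValueError, match="degenerate|collinear"):
            fc.normalize_and_correspond([blob, line])


class TestFitShapeModel:
    def test_identical_vectors_zero_eigenvalues(self):
        v = np.tile(np.arange(16, dtype=float), (5, 1))
        model = fc.fit_shape_model(list(v), n_modes=3)
        assert np.allclose(model.eigenvalues, 0.0, atol=1e-18)
        assert np.allclose(model.mean_shape, v[0])

    def test_rank_one_training_recovers_direction(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=20)
        d /= np.linalg.norm(d)
        mean = rng.normal(size=20)
        vecs = [mean + t * d for t in np.linspace(-3, 3, 10)]
        model = fc.fit_shape_model(vecs, n_modes=9)
        assert model.eigenvalues[0] > 1e-6
        assert np.allclose(model.eigenvalues[1:], 0.0, atol=1e-12)
        assert abs(model.modes[:, 0] @ d) > 1 - 1e-9

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        vecs = rng.normal(size=(20, 32))
        model = fc.fit_shape_model(list(vecs), n_modes=19)
        centered = vecs - model.mean_shape
        recon = (centered @ model.modes) @ model.modes.T
        assert np.abs(recon - centered).mean() < 1e-8

    def test_modes_orthonormal_eigenvalues_sorted(self, shape_model):
        g = shape_model.modes.T @ shape_model.modes
        assert np.allclose(g, np.eye(shape_model.n_modes), atol=1e-9)
        assert np.all(np.diff(shape_model.eigenvalues) <= 1e-9)
        assert np.all(shape_model.eigenvalues >= 0)

    def test_rigid_transform_invariant_eigenvalues(self, patch_pool):
        contours = [p.contour for p in patch_pool]
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = [Contour(c.points @ rot.T + np.array([11.0, -7.0])) for c in contours]
        m1 = fc.fit_shape_model(fc.normalize_and_correspond(contours), n_modes=5)
        m2 = fc.fit_shape_model(fc.normalize_and_correspond(moved), n_modes=5)
        assert np.allclose(m1.eigenvalues, m2.eigenvalues,
                           rtol=1e-6, atol=1e-6 * m1.eigenvalues[0])

    def test_n_modes_out_of_range(self):
        vecs = list(np.random.default_rng(0).normal(size=(5, 8)))
        with pytest.raises(ValueError):
            fc.fit_shape_model(vecs, n_modes=5)


class TestGenerateShape:
    def test_zero_coefficients_give_mean_shape(self, shape_model):
        relaxed = fc.ShapeModel(shape_model.mean_shape, shape_model.modes,
                                shape_model.eigenvalues, r_min=0.0,
                                n_points=shape_model.n_points)
        s = fc.generate_shape(relaxed, rng=0,
                              coefficients=np.zeros(shape_model.n_modes))
        assert np.allclose(s.contour.as_vector(), shape_model.mean_shape)

    def test_same_seed_reproducible(self, shape_model):
        a = fc.generate_shape(shape_model, rng=11)
        b = fc.generate_shape(shape_model, rng=11)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert np.array_equal(a.contour.points, b.contour.points)

    def test_circle_model_recovers_training_radius(self):
        """Monte-Carlo parameter recovery: samples from a model trained on
        circles of radii 15-25 have the training mean radius."""
        rng = np.random.default_rng(5)
        radii = rng.uniform(15, 25, 40)
        contours = [fc.sample_contour(circle_mask(r), 64) for r in radii]
        vecs = fc.normalize_and_correspond(contours)
        model = fc.fit_shape_model(vecs, n_modes=10, r_min=0.0)
        train_mean = np.mean([Contour.from_vector(v).mean_radius() for v in vecs])
        n = 2000
        sample_radii = np.array([
            fc.generate_shape(model, rng=rng).contour.mean_radius() for _ in range(n)
        ])
        se = sample_radii.std(ddof=1) / np.sqrt(n)
        assert abs(sample_radii.mean() - train_mean) < 3 * se

    def test_minimum_size_constraint_absolute(self, shape_model):
        rng = np.random.default_rng(3)
        for _ in range(200):
            s = fc.generate_shape(shape_model, rng=rng)
            assert s.contour.mean_radius() >= shape_model.r_min
            assert s.contour.is_simple()

    def test_incompatible_r_min_raises(self, shape_model):
        huge = fc.ShapeModel(shape_model.mean_shape, shape_model.modes,
                             shape_model.eigenvalues, r_min=1e6,
                             n_points=shape_model.n_points)
        with pytest.raises(RuntimeError, match="incompatible"):
            fc.generate_shape(huge, rng=0)

    def test_coefficient_space_constraint_mode(self, shape_model):
        model = fc.ShapeModel(shape_model.mean_shape, shape_model.modes,
                              shape_model.eigenvalues, r_min=0.0,
                              n_points=shape_model.n_points,
                              constraint="coefficient")
        s = fc.generate_shape(model, rng=1)
        ref = np.linalg.pinv(model.modes) @ model.mean_shape
        assert np.linalg.norm(s.coefficients - ref) > model.r_min

    def test_coefficient_variance_matches_eigenvalues(self, shape_model):
        """Per-mode sample variance converges to the (3-sigma truncated)
        Gaussian variance prescribed by the eigenvalues."""
        rng = np.random.default_rng(9)
        b = np.array([fc.generate_shape(shape_model, rng=rng).coefficients
                      for _ in range(3000)])
        trunc = 0.9733369     # variance factor of a +/-3 sigma truncated normal
        for j in range(3):    # leading modes carry the signal
            target = trunc * shape_model.eigenvalues[j]
            se = np.std(b[:, j] ** 2, ddof=1) / np.sqrt(len(b))
            assert abs(b[:, j].var(ddof=1) - target) < 3 * se + 1e-12


class TestPersistence:
    def test_json_roundtrip(self, shape_model, tmp_path):
        path = tmp_path / "model.json"
        fc.save_model(shape_model, path)
        back = fc.load_model(path)
        assert np.array_equal(back.mean_shape, shape_model.mean_shape)
        assert np.array_equal(back.modes, shape_model.modes)
        assert np.array_equal(back.eigenvalues, shape_model.eigenvalues)
        assert back.r_min == shape_model.r_min
        assert back.n_points == shape_model.n_points

    def test_unknown_version_rejected(self, shape_model, tmp_path):
        path = tmp_path / "model.json"
        fc.save_model(shape_model, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            fc.load_model(path)
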