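import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import special_ortho_group

from mcspace.chem_space import (
    ChemicalSpaceModel,
    compound_distance,
    fit_pca,
    hyperellipsoid,
    project,
    set_distance,
)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(42)
    return pd.DataFrame(rng.normal(50, 20, size=(60, 12)))


class TestFitPCA:
    def test_collinear_pc1_explains_everything(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        data = np.column_stack([x, 3 * x + 1])
        model = fit_pca(data)
        assert model.explained_variance[0] == pytest.approx(1.0, abs=1e-10)

    def test_training_projection_equals_scores(self, random_matrix):
        model = fit_pca(random_matrix)
        scores = project(model, random_matrix.to_numpy())
        np.testing.assert_allclose(scores, model.training_scores, atol=1e-10)

    def test_full_rank_reconstruction(self, random_matrix):
        model = fit_pca(random_matrix)
        X = random_matrix.to_numpy()
        Xc = X - model.column_means
        recon = model.training_scores @ model.coefficients.T
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_explained_variance_non_increasing_sums_to_1(self, random_matrix):
        model = fit_pca(random_matrix)
        ev = model.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() == pytest.approx(1.0)

    def test_loadings_orthonormal(self, random_matrix):
        model = fit_pca(random_matrix)
        C = model.coefficients
        np.testing.assert_allclose(C.T @ C, np.eye(C.shape[1]), atol=1e-10)

    def test_constant_columns_permitted(self):
        rng = np.random.default_rng(2)
        data = np.column_stack([rng.normal(size=30), np.zeros(30)])
        model = fit_pca(data)
        assert model.coefficients.shape[0] == 2

    def test_fewer_than_2_rows_errors(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((1, 3)))

    def test_sign_convention_reproducible(self, random_matrix):
        m1 = fit_pca(random_matrix)
        m2 = fit_pca(random_matrix.iloc[::-1].reset_index(drop=True))
        for j in range(m1.coefficients.shape[1]):
            i = int(np.argmax(np.abs(m1.coefficients[:, j])))
            assert m1.coefficients[i, j] > 0

    def test_json_roundtrip(self, random_matrix, tmp_path):
        model = fit_pca(random_matrix)
        path = tmp_path / "model.json"
        model.save(str(path))
        loaded = ChemicalSpaceModel.load(str(path))
        row = random_matrix.to_numpy()[0]
        np.testing.assert_allclose(project(model, row), project(loaded, row))


class TestProject:
    def test_row_at_column_means_scores_zero(self, random_matrix):
        model = fit_pca(random_matrix)
        np.testing.assert_allclose(
            project(model, model.column_means), 0.0, atol=1e-10)

    def test_matches_bruteforce_matrix_multiply(self, random_matrix):
        model = fit_pca(random_matrix)
        rng = np.random.default_rng(3)
        row = rng.normal(50, 20, size=random_matrix.shape[1])
        # independent oracle: explicit sum over loops
        expected = np.array([
            sum((row[p] - model.column_means[p]) * model.coefficients[p, i]
                for p in range(len(row)))
            for i in range(model.n_components)])
        np.testing.assert_allclose(project(model, row), expected, atol=1e-10)

    def test_column_mismatch_errors(self, random_matrix):
        model = fit_pca(random_matrix)
        with pytest.raises(ValueError):
            project(model, np.ones(5))


class TestHyperellipsoid:
    def test_unit_semi_axes_volume_pi5_over_120(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(50, 10))
        ell = hyperellipsoid(scores, coverage=1.0, dims=10)
        # overwrite ranges with diameter-2 axes to isolate the formula
        from mcspace.chem_space import Hyperellipsoid
        unit = Hyperellipsoid(center=np.zeros(10), ranges=np.full(10, 2.0),
                              coverage=1.0)
        assert unit.volume == pytest.approx(math.pi ** 5 / 120, rel=1e-12)
        assert unit.volume == pytest.approx(2.5502, abs=5e-5)
        assert unit.avg_radius == pytest.approx(unit.volume ** 0.1)

    def test_zero_spread_axis_gives_zero_volume(self):
        scores = np.zeros((20, 10))
        scores[:, :9] = np.random.default_rng(5).normal(size=(20, 9))
        ell = hyperellipsoid(scores, coverage=1.0, dims=10)
        assert ell.volume == 0.0

    def test_doubling_ranges_multiplies_volume_by_1024(self):
        from mcspace.chem_space import Hyperellipsoid
        rng = np.random.default_rng(6)
        ranges = rng.uniform(1, 3, size=10)
        v1 = Hyperellipsoid(np.zeros(10), ranges, 1.0).volume
        v2 = Hyperellipsoid(np.zeros(10), 2 * ranges, 1.0).volume
        assert v2 / v1 == pytest.approx(1024.0, rel=1e-10)

    def test_monte_carlo_uniform_box(self):
        """Uniform points in a known 10-D box: the coverage-0.95 volume
        must match the analytic ellipsoid from per-axis 0.95 quantile
        spans within 5% at n = 10,000."""
        rng = np.random.default_rng(7)
        lengths = rng.uniform(1.0, 4.0, size=10)
        pts = rng.uniform(0, 1, size=(10_000, 10)) * lengths
        ell = hyperellipsoid(pts, coverage=0.95, dims=10)
        semi = 0.95 * lengths / 2.0
        analytic = math.pi ** 5 / 120 * np.prod(semi)
        assert ell.volume == pytest.approx(analytic, rel=0.05)

    def test_coverage_validation(self):
        with pytest.raises(ValueError):
            hyperellipsoid(np.ones((5, 10)), coverage=0.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            hyperellipsoid(np.empty((0, 10)))

    def test_dims_exceeding_available_errors(self):
        with pytest.raises(ValueError):
            hyperellipsoid(np.ones((5, 3)), dims=10)


class TestDistances:
    def universe(self, a_pc1=1.0, dims=10):
        from mcspace.chem_space import Hyperellipsoid
        ranges = np.full(dims, 2.0 * a_pc1)
        return Hyperellipsoid(np.zeros(dims), ranges, 1.0)

    def test_self_distance_zero(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=(20, 10))
        norm, raw = set_distance(s, s, self.universe())
        assert norm == 0.0 and raw == 0.0

    def test_1pc_case(self):
        a = np.full((4, 1), 3.0)
        b = np.full((4, 1), 7.0)
        norm, raw = set_distance(a, b, self.universe(a_pc1=2.0, dims=1), dims=1)
        assert norm == pytest.approx(2.0)
        assert raw == pytest.approx(4.0)

    def test_3_4_5(self):
        a = np.zeros((3, 2))
        b = np.tile([3.0, 4.0], (3, 1))
        norm, raw = set_distance(a, b, self.universe(a_pc1=1.0, dims=2), dims=2)
        assert norm == pytest.approx(5.0)

    def test_compound_at_centroid(self):
        rng = np.random.default_rng(9)
        ref = rng.normal(size=(30, 10))
        centroid = ref.mean(axis=0)
        norm, raw = compound_distance(centroid, ref, self.universe())
        assert norm == pytest.approx(0.0, abs=1e-12)

    def test_single_pc_offset_equal_a_pc1(self):
        ref = np.zeros((5, 10))
        x = np.zeros(10)
        x[0] = 3.0
        norm, _ = compound_distance(x, ref, self.universe(a_pc1=3.0))
        assert norm == pytest.approx(1.0)

    def test_bruteforce_oracle_10d(self):
        rng = np.random.default_rng(10)
        ref = rng.normal(size=(25, 10))
        x = rng.normal(size=10)
        mu = ref.mean(axis=0)
        expected_raw = math.sqrt(sum((x[i] - mu[i]) ** 2 for i in range(10)))
        uni = self.universe(a_pc1=1.7)
        norm, raw = compound_distance(x, ref, uni)
        assert raw == pytest.approx(expected_raw, abs=1e-10)
        assert norm == pytest.approx(expected_raw / 1.7, abs=1e-10)

    def test_range_normalization_mode(self):
        ref = np.zeros((5, 10))
        x = np.zeros(10)
        x[0] = 4.0
        uni = self.universe(a_pc1=2.0)
        norm_semi, _ = compound_distance(x, ref, uni, mode="semi-axis")
        norm_range, _ = compound_distance(x, ref, uni, mode="range")
        assert norm_semi == pytest.approx(2.0)
        assert norm_range == pytest.approx(1.0)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(11)
        uni = self.universe()
        for _ in range(20):
            a, b, c = (rng.normal(size=(6, 10)) for _ in range(3))
            dab, _ = set_distance(a, b, uni)
            dba, _ = set_distance(b, a, uni)
            dac, _ = set_distance(a, c, uni)
            dcb, _ = set_distance(c, b, uni)
            assert dab == pytest.approx(dba)
            assert dab <= dac + dcb + 1e-12


def test_rotation_invariance():
    """Rotating the data changes loadings but neither total variance nor
    full-dimension centroid distances."""
    rng = np.random.default_rng(12)
    X = rng.normal(size=(40, 6))
    R = special_ortho_group.rvs(6, random_state=13)
    Xr = X @ R
    m1, m2 = fit_pca(X), fit_pca(Xr)
    var1 = (np.linalg.norm(X - X.mean(0)) ** 2)
    var2 = (np.linalg.norm(Xr - Xr.mean(0)) ** 2)
    assert var1 == pytest.approx(var2)
    s1 = m1.training_scores
    s2 = m2.training_scores
    d1 = np.linalg.norm(s1[:20].mean(0) - s1[20:].mean(0))
    d2 = np.linalg.norm(s2[:20].mean(0) - s2[20:].mean(0))
    assert d1 == pytest.approx(d2, rel=1e-9)
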