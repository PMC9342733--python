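"""PCA retention, dimensionality guard, hypervolume fitting, inclusion, intersection."""

import numpy as np
import pytest

from aquaniche.exceptions import DataError, DegenerateBoundaryError
from aquaniche.niche import (
    check_dimensionality,
    derive_seed,
    fit_hypervolume,
    fit_pca,
    intersect_n,
    load_hypervolume,
    mc_volume_se,
    save_hypervolume,
)


def mvn_compound_symmetric(n, p, rho, seed):
    rng = np.random.default_rng(seed)
    cov = np.full((p, p), rho) + (1 - rho) * np.eye(p)
    return rng.multivariate_normal(np.zeros(p), cov, size=n)


class TestFitPca:
    def test_compound_symmetric_closed_form(self):
        # correlation 0.5 among 3 variables: eigenvalues 1+(p-1)rho and 1-rho
        X = mvn_compound_symmetric(20_000, 3, 0.5, seed=42)
        model, scores = fit_pca(X)
        assert model.eigenvalues == pytest.approx([2.0, 0.5, 0.5], abs=0.1)
        assert model.retained == 1
        assert scores.shape == (20_000, 1)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 6)) @ rng.normal(size=(6, 6))
        model, _ = fit_pca(X)
        oracle = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        assert model.eigenvalues == pytest.approx(oracle, abs=1e-8)

    def test_independent_columns_near_unit_eigenvalues(self):
        X = np.random.default_rng(2).normal(size=(10_000, 5))
        model, _ = fit_pca(X)
        assert np.all(np.abs(model.eigenvalues - 1.0) < 0.1)
        assert model.retained == int(np.sum(model.eigenvalues > 1.0)) or model.retained == 1

    def test_duplicated_column_dominates(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(2000, 3))
        X = np.column_stack([base, base[:, 0]])
        model, _ = fit_pca(X)
        assert model.eigenvalues[0] == pytest.approx(2.0, abs=0.1)
        assert model.retained >= 1

    def test_invariants_orthonormal_and_trace(self):
        X = np.random.default_rng(4).normal(size=(300, 7)) ** 2
        model, _ = fit_pca(X)
        p = len(model.variable_ids)
        assert model.eigenvalues.sum() == pytest.approx(p, abs=1e-6)
        assert model.loadings.T @ model.loadings == pytest.approx(np.eye(p), abs=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.normal(size=100), np.full(100, 7.0), rng.normal(size=100)])
        model, scores = fit_pca(X, variable_ids=["a", "b", "c"])
        assert model.dropped_variables == ("b",)
        assert model.variable_ids == ("a", "c")
        # transform accepts the full-width input and subsets internally
        assert model.transform(X).shape == scores.shape

    def test_too_few_rows_raises(self):
        with pytest.raises(DataError):
            fit_pca(np.zeros((2, 3)))


class TestCheckDimensionality:
    @pytest.mark.parametrize(
        "n, d, triggered",
        [(69, 5, True), (10**6, 5, False), (3, 1, False), (10, 3, True)],
    )
    def test_ln_threshold(self, n, d, triggered):
        w = check_dimensionality(n, d)
        assert w.triggered is triggered
        assert w.threshold == pytest.approx(np.log(n))

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            check_dimensionality(0, 3)


class TestFitHypervolume:
    def test_unit_square_volume_single_seed(self):
        X = np.random.default_rng(0).uniform(0, 1, size=(2000, 2))
        hv = fit_hypervolume(X, seed=123)
        assert hv.volume == pytest.approx(1.0, rel=0.2)

    def test_determinism_bit_identical(self):
        X = np.random.default_rng(1).uniform(0, 1, size=(500, 2))
        a = fit_hypervolume(X, seed=9)
        b = fit_hypervolume(X, seed=9)
        assert a.volume == b.volume
        assert np.array_equal(a.random_points, b.random_points)

    def test_stored_points_pass_own_inclusion(self):
        X = np.random.default_rng(2).normal(size=(800, 2))
        hv = fit_hypervolume(X, seed=3)
        assert hv.includes_many(hv.random_points).all()
        assert hv.volume == pytest.approx(len(hv.random_points) / hv.point_density, abs=1e-9)

    def test_training_inclusion_rate(self):
        X = np.random.default_rng(4).normal(size=(1500, 3))
        hv = fit_hypervolume(X, seed=5)
        frac = hv.includes_many(X).mean()
        assert frac >= 1.0 - hv.nu - 0.05

    def test_centroid_inside_far_point_outside(self):
        X = np.random.default_rng(6).normal(size=(1000, 2))
        hv = fit_hypervolume(X, seed=7)
        assert hv.includes(X.mean(axis=0))
        assert not hv.includes(np.array([100.0, 100.0]))

    def test_dimension_mismatch_raises(self):
        X = np.random.default_rng(8).normal(size=(100, 2))
        hv = fit_hypervolume(X, seed=1)
        with pytest.raises(ValueError):
            hv.includes(np.array([0.0, 0.0, 0.0]))

    def test_1d_volume_against_numeric_integration(self):
        X = np.random.default_rng(10).normal(size=(2000, 1))
        hv = fit_hypervolume(X, seed=11)
        # brute-force oracle: measure of {decision >= 0} on a fine 1-D grid
        grid = np.linspace(hv.box_lo[0], hv.box_hi[0], 200_001)[:, None]
        inside = hv.includes_many(grid)
        length = inside.mean() * (hv.box_hi[0] - hv.box_lo[0])
        assert hv.volume == pytest.approx(length, rel=0.15)

    def test_degenerate_boundary_raises(self):
        X = np.random.default_rng(12).normal(size=(50, 2))
        with pytest.raises(DegenerateBoundaryError):
            fit_hypervolume(X, gamma=1e6, box_margin=50.0, n_mc_samples=200, seed=13)

    def test_too_few_points_raises(self):
        with pytest.raises(DataError):
            fit_hypervolume(np.zeros((2, 2)), seed=0)

    def test_unit_square_symmetric_difference_small(self):
        X = np.random.default_rng(14).uniform(0, 1, size=(2000, 2))
        hv = fit_hypervolume(X, seed=15)
        rng = np.random.default_rng(16)
        S = rng.uniform([-0.5, -0.5], [1.5, 1.5], size=(40_000, 2))
        in_hv = hv.includes_many(S)
        in_box = np.all((S >= 0.0) & (S <= 1.0), axis=1)
        sym_diff = np.mean(in_hv != in_box) * 4.0  # sampling box volume
        assert sym_diff < 0.3


class TestIntersectN:
    @staticmethod
    def square(lo, seed, n=2000):
        rng = np.random.default_rng(seed)
        return rng.uniform(lo, lo + 1.0, size=(n, 2))

    def test_self_intersection_recovers_volume(self):
        hv = fit_hypervolume(self.square(0.0, 1), seed=2)
        inter = intersect_n([hv, hv], seed=3)
        assert abs(inter.volume - hv.volume) <= 3 * (inter.volume_se + mc_volume_se(hv))

    def test_disjoint_supports_null(self):
        a = fit_hypervolume(self.square(0.0, 4), seed=5)
        b = fit_hypervolume(self.square(10.0, 6), seed=7)
        inter = intersect_n([a, b], seed=8)
        assert inter.volume == 0.0 and len(inter.random_points) == 0 and inter.is_null

    def test_half_overlapping_squares(self):
        a = fit_hypervolume(self.square(0.0, 9), seed=10)
        b = fit_hypervolume(self.square(0.5, 11), seed=12)
        inter = intersect_n([a, b], seed=13)
        assert inter.volume == pytest.approx(0.25, rel=0.35)

    def test_volume_bounded_by_members(self):
        rng = np.random.default_rng(20)
        for trial in range(5):
            shift = rng.uniform(0, 0.8)
            a = fit_hypervolume(self.square(0.0, 100 + trial), seed=200 + trial)
            b = fit_hypervolume(self.square(shift, 300 + trial), seed=400 + trial)
            inter = intersect_n([a, b], seed=500 + trial)
            bound = min(a.volume, b.volume) + 3 * (inter.volume_se + mc_volume_se(a) + mc_volume_se(b))
            assert inter.volume <= bound

    def test_adding_member_never_increases_volume(self):
        a = fit_hypervolume(self.square(0.0, 30), seed=31)
        b = fit_hypervolume(self.square(0.3, 32), seed=33)
        c = fit_hypervolume(self.square(0.6, 34), seed=35)
        two = intersect_n([a, b], seed=36)
        three = intersect_n([a, b, c], seed=36)
        assert three.volume <= two.volume + 3 * (two.volume_se + three.volume_se)

    def test_order_invariance_within_mc_error(self):
        a = fit_hypervolume(self.square(0.0, 40), seed=41)
        b = fit_hypervolume(self.square(0.4, 42), seed=43)
        ab = intersect_n([a, b], seed=44)
        ba = intersect_n([b, a], seed=44)
        assert abs(ab.volume - ba.volume) <= 3 * (ab.volume_se + ba.volume_se)

    def test_member_verdicts_define_inclusion(self):
        a = fit_hypervolume(self.square(0.0, 50), seed=51)
        b = fit_hypervolume(self.square(0.5, 52), seed=53)
        inter = intersect_n([a, b], seed=54)
        for pt in [np.array([0.75, 0.75]), np.array([0.1, 0.1]), np.array([5.0, 5.0])]:
            assert inter.includes(pt) == (a.includes(pt) and b.includes(pt))

    def test_mismatched_dims_rejected(self):
        a = fit_hypervolume(np.random.default_rng(60).normal(size=(100, 2)), seed=61)
        b = fit_hypervolume(np.random.default_rng(62).normal(size=(100, 3)), seed=63)
        with pytest.raises(ValueError):
            intersect_n([a, b])

    def test_fewer_than_two_rejected(self):
        a = fit_hypervolume(np.random.default_rng(64).normal(size=(100, 2)), seed=65)
        with pytest.raises(ValueError):
            intersect_n([a])


class TestSerialization:
    def test_roundtrip_bit_exact_inclusion(self, tmp_path):
        X = np.random.default_rng(70).normal(size=(500, 3))
        hv = fit_hypervolume(X, seed=71)
        save_hypervolume(hv, tmp_path, "sp")
        back = load_hypervolume(tmp_path, "sp")
        assert back.volume == hv.volume
        probes = np.random.default_rng(72).uniform(-4, 4, size=(500, 3))
        assert np.array_equal(hv.decision(probes), back.decision(probes))
        assert np.array_equal(back.random_points, hv.random_points)


class TestDeriveSeed:
    def test_stable_and_distinct(self):
        assert derive_seed(1, "a", "b") == derive_seed(1, "a", "b")
        assert derive_seed(1, "a") != derive_seed(1, "b")
        assert derive_seed(1, "a") != derive_seed(2, "a")
        assert 0 <= derive_seed(12345, "x") < 2**31
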