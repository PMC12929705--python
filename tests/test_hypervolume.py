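"""KDE hypervolumes: bandwidths, volume, FD indices, Jaccard overlap."""


import numpy as np
import pytest

from cytotraits.hypervolume import (
    estimate_bandwidth, build_hypervolume, richness, evenness, dispersion,
    jaccard, fd_per_replicate,
)


class TestBandwidth:
    def test_silverman_closed_form(self, rng):
        x = rng.standard_normal((100, 1))
        x = (x - x.mean()) / x.std(ddof=1)
        h = estimate_bandwidth(x)
        assert h[0] == pytest.approx((4.0 / 300.0) ** 0.2, rel=1e-9)

    def test_homogeneity_under_scaling(self, rng):
        X = rng.standard_normal((200, 3))
        np.testing.assert_allclose(
            estimate_bandwidth(4.5 * X), 4.5 * estimate_bandwidth(X), rtol=1e-12
        )

    def test_constant_dimension_rejected(self, rng):
        X = np.column_stack([rng.standard_normal(50), np.full(50, 2.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            estimate_bandwidth(X)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= 10"):
            estimate_bandwidth(rng.standard_normal((5, 2)))


class TestBuild:
    def test_determinism_same_seed(self, rng):
        X = rng.standard_normal((300, 2))
        a = build_hypervolume(X, seed=7)
        b = build_hypervolume(X, seed=7)
        np.testing.assert_array_equal(a.support_points, b.support_points)
        assert a.volume == b.volume

    def test_duplicated_data_same_volume(self, rng):
        X = rng.standard_normal((500, 2))
        v1 = build_hypervolume(X, n_support=2000, seed=1).volume
        v2 = build_hypervolume(np.vstack([X, X]), n_support=2000, seed=2).volume
        # doubling n shrinks the Silverman bandwidth slightly; densities are
        # otherwise identical, so volumes agree within Monte-Carlo + h error
        assert v2 == pytest.approx(v1, rel=0.10)

    def test_support_points_above_threshold(self, rng):
        hv = build_hypervolume(rng.standard_normal((300, 2)), seed=3)
        assert np.all(hv.density(hv.support_points) >= hv.threshold_density * (1 - 1e-12))

    def test_invalid_quantile(self, rng):
        with pytest.raises(ValueError, match="quantile"):
            build_hypervolume(rng.standard_normal((50, 2)), q=1.5)


class TestRichness:
    def test_equals_volume(self, rng):
        hv = build_hypervolume(rng.standard_normal((200, 2)), seed=0)
        assert richness(hv) == hv.volume

    def test_scaling_law(self, rng):
        X = rng.standard_normal((2000, 2))
        r1 = richness(build_hypervolume(X, seed=1))
        r2 = richness(build_hypervolume(3.0 * X, seed=1))
        assert r2 / r1 == pytest.approx(9.0, rel=0.10)

    def test_tight_smaller_than_dispersed(self, rng):
        X = rng.standard_normal((1000, 2))
        assert richness(build_hypervolume(0.2 * X, seed=2)) < richness(
            build_hypervolume(X, seed=2)
        )

    def test_monotone_in_quantile(self, rng):
        X = rng.standard_normal((1000, 2))
        vols = [build_hypervolume(X, q=q, seed=5).volume
                for q in (0.5, 0.75, 0.9, 0.99)]
        assert all(b > a for a, b in zip(vols, vols[1:]))


class TestEvenness:
    def test_uniform_box_near_one(self, rng):
        X = rng.uniform(0, 1, size=(8000, 2))
        assert evenness(build_hypervolume(X, seed=1)) >= 0.9

    def test_clumped_below_uniform(self, rng):
        U = rng.uniform(0, 1, size=(6000, 2))
        C = np.vstack(
            [0.05 * rng.standard_normal((3000, 2)),
             0.05 * rng.standard_normal((3000, 2)) + [5, 0]]
        )
        e_u = evenness(build_hypervolume(U, seed=2))
        e_c = evenness(build_hypervolume(C, seed=3))
        assert e_u - e_c >= 0.15

    def test_bounded_in_unit_interval(self, rng):
        for i in range(3):
            hv = build_hypervolume(rng.standard_normal((200, 2)) ** 2, seed=i)
            assert 0.0 <= evenness(hv) <= 1.0


class TestDispersion:
    def test_1d_uniform_quarter(self, rng):
        hv = build_hypervolume(rng.uniform(0, 1, size=(8000, 1)), seed=1)
        assert dispersion(hv) == pytest.approx(0.25, abs=0.03)

    def test_translation_invariance(self, rng):
        X = rng.standard_normal((500, 2))
        d1 = dispersion(build_hypervolume(X, seed=4))
        d2 = dispersion(build_hypervolume(X + [100, -50], seed=4))
        assert d2 == pytest.approx(d1, rel=1e-6)

    def test_degenerate_tight_cluster_small(self, rng):
        X = 1e-3 * rng.standard_normal((200, 2))
        assert dispersion(build_hypervolume(X, seed=5)) < 0.01


class TestJaccard:
    def test_self_same_seed_exactly_one(self, rng):
        X = rng.standard_normal((300, 2))
        assert jaccard(build_hypervolume(X, seed=9), build_hypervolume(X, seed=9)) == 1.0

    def test_self_different_seed_high(self, rng):
        X = rng.standard_normal((1500, 2))
        a = build_hypervolume(X, n_support=2000, seed=1)
        b = build_hypervolume(X, n_support=2000, seed=2)
        assert jaccard(a, b) >= 0.95

    def test_disjoint_clouds_near_zero(self, rng):
        a = build_hypervolume(rng.standard_normal((300, 2)), seed=1)
        b = build_hypervolume(rng.standard_normal((300, 2)) + 200, seed=2)
        assert jaccard(a, b) < 0.01

    def test_symmetry(self, rng):
        a = build_hypervolume(rng.standard_normal((600, 2)), n_support=2000, seed=3)
        b = build_hypervolume(rng.standard_normal((600, 2)) + 0.8,
                              n_support=2000, seed=4)
        assert jaccard(a, b) == pytest.approx(jaccard(b, a), abs=1e-12)

    def test_dimension_mismatch(self, rng):
        a = build_hypervolume(rng.standard_normal((100, 2)), seed=1)
        b = build_hypervolume(rng.standard_normal((100, 3)), seed=1)
        with pytest.raises(ValueError, match="dimensionality"):
            jaccard(a, b)


class TestFDPerReplicate:
    def test_full_design_row_count(self, rng):
        groups = {
            (t, r): rng.standard_normal((200, 2))
            for t in ("a", "b", "c", "d", "e") for r in range(4)
        }
        table, hvs = fd_per_replicate(groups, seed=0)
        assert len(table) == 20
        assert len(hvs) == 20
        assert set(table.columns) >= {"richness", "evenness", "dispersion"}

    def test_small_replicate_skipped_with_warning(self, rng):
        groups = {("a", 0): rng.standard_normal((200, 2)),
                  ("a", 1): rng.standard_normal((4, 2))}
        with pytest.warns(UserWarning, match="skipped"):
            table, _ = fd_per_replicate(groups, seed=0)
        assert len(table) == 1

    def test_identical_data_identical_indices(self, rng):
        X = rng.standard_normal((300, 2))
        t1, _ = fd_per_replicate({("a", 0): X}, seed=3)
        t2, _ = fd_per_replicate({("a", 0): X.copy()}, seed=3)
        assert t1.equals(t2)
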