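import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegtda import (PersistenceDiagram, betti1_curve, build_point_cloud,
                    compute_features, epoch_features, rips_diagram)
from eegtda.reference import rips_dims01_reference

SQRT2 = np.sqrt(2.0)


def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def diagrams_equal(a, b, atol=1e-9):
    return a.shape == b.shape and np.allclose(a, b, atol=atol)


class TestPointCloud:
    def test_epoch_transpose(self):
        epoch = np.arange(8 * 500, dtype=float).reshape(8, 500)
        epc = build_point_cloud(epoch)
        assert epc.points.shape == (500, 8)
        assert np.array_equal(epc.points, epoch.T)

    def test_constant_epoch(self):
        epc = build_point_cloud(np.ones((8, 500)))
        assert np.all(epc.points == 1.0)

    def test_channel_permutation_leaves_features_unchanged(self, rng):
        epoch = rng.normal(size=(5, 60))
        perm = rng.permutation(5)
        a = epoch_features(epoch).as_dict()
        b = epoch_features(epoch[perm]).as_dict()
        assert np.allclose(list(a.values()), list(b.values()), rtol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            build_point_cloud(np.array([[np.nan, 1.0]]))


class TestRipsDiagram:
    def test_unit_square_single_loop(self):
        dgm = rips_diagram(unit_square())
        h1 = dgm.pairs(1)
        assert h1.shape == (1, 2)
        assert np.allclose(h1[0], [1.0, SQRT2], atol=1e-12)
        h0 = dgm.pairs(0)
        assert np.isinf(h0[:, 1]).sum() == 1

    def test_single_point(self):
        dgm = rips_diagram(np.zeros((1, 3)))
        assert diagrams_equal(dgm.pairs(0), np.array([[0.0, np.inf]]))
        assert dgm.pairs(1).size == 0

    def test_three_collinear_points_have_no_cycle(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0]])
        assert rips_diagram(pts).pairs(1).size == 0

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            rips_diagram(np.empty((0, 3)))

    def test_matches_bruteforce_oracle_on_random_clouds(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 13))
            d = int(rng.integers(2, 9))
            pts = rng.normal(size=(n, d))
            dgm = rips_diagram(pts)
            h0_ref, h1_ref = rips_dims01_reference(pts)
            assert diagrams_equal(dgm.pairs(0), h0_ref)
            assert diagrams_equal(dgm.pairs(1), h1_ref)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_scale_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(12, 4))
        c = float(rng.uniform(0.1, 10.0))
        base = compute_features(rips_diagram(pts))
        scaled = compute_features(rips_diagram(c * pts))
        assert scaled.total_cycles == base.total_cycles
        assert scaled.max_cycles == base.max_cycles
        assert np.isclose(scaled.max_persistence, c * base.max_persistence)
        assert np.isclose(scaled.npe, base.npe)
        assert np.isclose(scaled.max_persistence_ratio,
                          base.max_persistence_ratio)
        assert np.isclose(scaled.median_persistence_ratio,
                          base.median_persistence_ratio)

    def test_perturbation_stability_of_max_persistence(self, rng):
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.column_stack([np.cos(t), np.sin(t)])
        base = compute_features(rips_diagram(pts)).max_persistence
        for eps in (0.01, 0.05):
            noisy = pts + rng.uniform(-eps / 2, eps / 2, pts.shape)
            pert = compute_features(rips_diagram(noisy)).max_persistence
            # bottleneck stability: diagrams move at most the point-wise
            # perturbation, so max persistence moves at most twice that
            assert abs(pert - base) <= 2 * eps + 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_circle_vs_gaussian_topology_dial(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        circle = np.column_stack([np.cos(t), np.sin(t)])
        circle += rng.normal(0, 0.05, circle.shape)
        gauss = rng.normal(size=(100, 2)) * circle.std()
        mp_circle = compute_features(rips_diagram(circle)).max_persistence
        mp_gauss = compute_features(rips_diagram(gauss)).max_persistence
        assert mp_circle > 5 * mp_gauss

    def test_dim2_unsupported(self):
        with pytest.raises(ValueError):
            rips_diagram(unit_square(), max_dimension=2)


class TestBettiCurve:
    def test_unit_square_curve(self):
        grid, counts = betti1_curve(rips_diagram(unit_square()))
        assert counts.max() == 1
        on = np.isclose(grid, 1.0)
        assert counts[on][0] == 1
        assert counts[np.isclose(grid, SQRT2)][0] == 0

    def test_empty_diagram_is_zero(self):
        grid, counts = betti1_curve(PersistenceDiagram({1: np.empty((0, 2))}))
        assert counts.max() == 0

    @pytest.mark.parametrize("pairs,expected_max", [
        ([(1.0, 2.0), (3.0, 4.0)], 1),  # disjoint
        ([(1.0, 3.0), (2.0, 4.0)], 2),  # overlapping
    ])
    def test_overlap_counting(self, pairs, expected_max):
        dgm = PersistenceDiagram({1: np.array(pairs)})
        _, counts = betti1_curve(dgm)
        assert counts.max() == expected_max


class TestFeatures:
    def test_unit_square_feature_arithmetic(self):
        feats = compute_features(rips_diagram(unit_square()))
        assert feats.total_cycles == 1
        assert feats.max_cycles == 1
        assert np.isclose(feats.max_persistence, SQRT2 - 1.0)
        assert feats.npe == 0.0
        assert np.isclose(feats.max_persistence_ratio, SQRT2)
        assert np.isclose(feats.median_persistence_ratio, SQRT2)

    def test_equal_lifetimes_saturate_entropy(self):
        dgm = PersistenceDiagram({1: np.array([[1.0, 2.0], [2.0, 3.0]])})
        assert np.isclose(compute_features(dgm).npe, 1.0)

    def test_no_cycles_all_zero(self):
        feats = compute_features(PersistenceDiagram({1: np.empty((0, 2))}))
        assert feats.as_dict() == dict.fromkeys(feats.as_dict(), 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 30))
    def test_feature_invariants_on_random_diagrams(self, seed, m):
        rng = np.random.default_rng(seed)
        births = rng.uniform(0.1, 5.0, m)
        pairs = np.column_stack([births, births + rng.uniform(0.01, 5.0, m)])
        feats = compute_features(PersistenceDiagram({1: pairs}))
        assert feats.max_cycles <= feats.total_cycles == m
        assert 0.0 <= feats.npe <= 1.0 + 1e-12
        assert feats.median_persistence_ratio <= feats.max_persistence_ratio
        assert feats.max_persistence_ratio >= 1.0
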