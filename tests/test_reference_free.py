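import math

import numpy as np
import pytest

import spatsim as ss
from spatsim.reference_free import grid_centers


class TestCovariance:
    def test_unit_diagonal(self, rng):
        pts = rng.random((8, 2))
        S = ss.build_covariance(pts, delta=0.3)
        np.testing.assert_allclose(np.diag(S), 1.0)
        np.testing.assert_allclose(S, S.T)

    def test_distance_delta_gives_exp_minus_one(self):
        pts = np.array([[0.0, 0.0], [0.7, 0.0]])
        S = ss.build_covariance(pts, delta=0.7)
        assert S[0, 1] == pytest.approx(math.exp(-1.0), abs=1e-15)

    def test_matches_double_loop_oracle(self, rng):
        pts = rng.random((6, 2))
        delta = 0.4
        S = ss.build_covariance(pts, delta)
        for i in range(6):
            for j in range(6):
                d = math.dist(pts[i], pts[j])
                assert S[i, j] == pytest.approx(
                    math.exp(-((d / delta) ** 2)), abs=1e-12
                )

    def test_positive_semidefinite_on_random_layouts(self, rng):
        for _ in range(5):
            pts = rng.random((15, 2))
            S = ss.build_covariance(pts, delta=rng.uniform(0.1, 1.0))
            assert np.linalg.eigvalsh(S).min() >= -1e-6

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            ss.build_covariance(np.zeros((2, 2)), delta=0.0)


class TestSampleField:
    def test_identity_covariance_iid_standard_normal(self):
        n = 2000
        fld = ss.sample_field(np.eye(n), seed=0)
        assert abs(fld.values.mean()) < 0.1
        assert abs(fld.values.std() - 1.0) < 0.1

    def test_seed_reproducible(self):
        S = ss.build_covariance(grid_centers(4) * 4, delta=1.0)
        a = ss.sample_field(S, seed=9)
        b = ss.sample_field(S, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestFuzziness:
    def _assignment(self, n, rng):
        return ss.SpatialAssignment(
            coordinates=rng.random((n, 2)),
            population=["p"] * n,
            cell_ids=[f"c{i}" for i in range(n)],
        )

    def test_lambda_one_identity(self, rng):
        a = self._assignment(40, rng)
        b = ss.apply_fuzziness(a, lam=1.0, seed=0)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_lambda_zero_full_permutation(self, rng):
        a = self._assignment(40, rng)
        b = ss.apply_fuzziness(a, lam=0.0, seed=0)
        # all cells participate: coordinate multiset preserved, rows moved
        assert sorted(map(tuple, a.coordinates)) == sorted(map(tuple, b.coordinates))
        assert (a.coordinates != b.coordinates).any(axis=1).sum() == 40

    def test_half_lambda_exact_participation(self, rng):
        a = self._assignment(100, rng)
        b = ss.apply_fuzziness(a, lam=0.5, seed=3)
        changed = (a.coordinates != b.coordinates).any(axis=1).sum()
        assert changed == 50
        assert sorted(map(tuple, a.coordinates)) == sorted(map(tuple, b.coordinates))
        assert b.population == a.population


class TestGeometry:
    def test_ellipse_examples(self):
        spec = ss.PatternSpec(kind="cluster", population="t",
                              center=(0.0, 0.0), axes=(2.0, 1.0), theta=0.0)
        assert ss.point_in_ellipse((1.0, 0.0), spec)
        assert not ss.point_in_ellipse((2.0, 0.0), spec)  # boundary excluded

    def test_ellipse_rotation(self):
        spec = ss.PatternSpec(kind="cluster", population="t",
                              center=(0.0, 0.0), axes=(2.0, 1.0), theta=math.pi / 2)
        # rotated frame maps (0, 1.5) onto the major axis: 1.5^2/4 < 1
        assert ss.point_in_ellipse((0.0, 1.5), spec)

    def test_stripe_examples(self):
        spec = ss.PatternSpec(kind="vessel", population="v",
                              endpoints=((0.0, 0.0), (10.0, 0.0)), width=2.0)
        assert not ss.point_in_stripe((-1.0, 1.0), spec)  # u < 0
        assert ss.point_in_stripe((5.0, 1.0), spec)       # u=5, v=0
        assert not ss.point_in_stripe((5.0, -1.0), spec)  # v = -2

    def test_symmetric_stripe_recentered(self):
        spec = ss.PatternSpec(kind="vessel", population="v", symmetric=True,
                              endpoints=((0.0, 0.0), (10.0, 0.0)), width=2.0)
        assert ss.point_in_stripe((5.0, 0.9), spec)
        assert ss.point_in_stripe((5.0, -0.9), spec)

    def test_membership_matches_canonical_frame_oracle(self, rng):
        """Rotate each point into the canonical frame and test the canonical
        inequality — must agree with the implementation everywhere."""
        for _ in range(10):
            spec = ss.PatternSpec(
                kind="cluster", population="t",
                center=tuple(rng.uniform(0.2, 0.8, 2)),
                axes=tuple(rng.uniform(0.05, 0.4, 2)),
                theta=float(rng.uniform(0, 2 * math.pi)),
            )
            pts = rng.random((1000, 2))
            c, s = math.cos(spec.theta), math.sin(spec.theta)
            for p in pts[:200]:
                xr = (p[0] - spec.center[0]) * c + (p[1] - spec.center[1]) * s
                yr = -(p[0] - spec.center[0]) * s + (p[1] - spec.center[1]) * c
                expected = (xr / spec.axes[0]) ** 2 + (yr / spec.axes[1]) ** 2 < 1
                assert ss.point_in_ellipse(tuple(p), spec) == expected


class TestBasisPatterns:
    def test_cluster_covering_canvas_labels_everything(self):
        spec = ss.PatternSpec(kind="cluster", population="big",
                              center=(0.5, 0.5), axes=(10.0, 10.0))
        a = ss.generate_basis_pattern(200, spec, background="bg", seed=0)
        assert set(a.population) == {"big"}

    def test_ring_member_count_shrinks_with_width(self):
        base = dict(kind="ring", population="r", center=(0.5, 0.5),
                    axes=(0.2, 0.2))
        counts = []
        for d in (0.15, 0.08, 0.02):
            spec = ss.PatternSpec(width=d, **base)
            a = ss.generate_basis_pattern(20000, spec, background="bg", seed=1)
            counts.append(sum(p == "r" for p in a.population))
        assert counts[0] > counts[1] > counts[2]

    def test_cluster_infiltration_fraction(self):
        spec = ss.PatternSpec(kind="cluster", population="a",
                              center=(0.5, 0.5), axes=(0.45, 0.45),
                              infiltration=[("b", 0.2)])
        a = ss.generate_basis_pattern(20000, spec, background="bg", seed=2)
        n_a = sum(p == "a" for p in a.population)
        n_b = sum(p == "b" for p in a.population)
        frac = n_b / (n_a + n_b)
        # binomial 4-sigma band around 0.2
        se = math.sqrt(0.2 * 0.8 / (n_a + n_b))
        assert abs(frac - 0.2) < 4 * se

    def test_mixed_proportions(self):
        spec = ss.PatternSpec(kind="mixed", mixed_proportions=[("a", 0.3), ("b", 0.7)])
        a = ss.generate_basis_pattern(1000, spec, background="bg", seed=3)
        assert sum(p == "a" for p in a.population) == 300
        assert sum(p == "b" for p in a.population) == 700


class TestCombine:
    def test_single_spec_equals_basis(self):
        spec = ss.PatternSpec(kind="cluster", population="c",
                              center=(0.3, 0.3), axes=(0.2, 0.1), theta=0.5)
        a = ss.generate_basis_pattern(500, spec, background="bg", seed=7)
        b = ss.combine_patterns([spec], 500, background="bg", seed=7)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        assert a.population == b.population

    def test_disjoint_clusters_additive(self):
        s1 = ss.PatternSpec(kind="cluster", population="a",
                            center=(0.2, 0.2), axes=(0.1, 0.1))
        s2 = ss.PatternSpec(kind="cluster", population="b",
                            center=(0.8, 0.8), axes=(0.1, 0.1))
        a = ss.combine_patterns([s1, s2], 5000, background="bg", seed=8)
        pops = np.asarray(a.population)
        members_a = pops == "a"
        members_b = pops == "b"
        assert not np.any(members_a & members_b)
        assert members_a.sum() > 0 and members_b.sum() > 0

    def test_painters_order_overwrite(self):
        cluster = ss.PatternSpec(kind="cluster", population="c",
                                 center=(0.5, 0.5), axes=(0.3, 0.3))
        vessel = ss.PatternSpec(kind="vessel", population="v",
                                endpoints=((0.0, 0.5), (1.0, 0.5)), width=0.1,
                                symmetric=True)
        a = ss.combine_patterns([cluster, vessel], 5000, background="bg", seed=9)
        from spatsim.reference_free import _stripe_mask, _ellipse_value

        pts = a.coordinates
        overlap = (_ellipse_value(pts, cluster) < 1) & _stripe_mask(pts, vessel)
        assert overlap.sum() > 0
        assert all(p == "v" for p in np.asarray(a.population)[overlap])


class TestAllocateRandomPatterns:
    def test_population_counts_conserved(self, nb_fixture):
        cfg = ss.RandomPatternConfig(grid_n=10, delta=1.0, lam=0.8,
                                     patterned_populations=["pop_0"], seed=0)
        a = ss.allocate_random_patterns(nb_fixture, cfg)
        assert sorted(a.population) == sorted(nb_fixture.population)
        assert a.n_cells == nb_fixture.n_cells
        assert np.all((a.coordinates >= 0) & (a.coordinates <= 1))

    def test_single_population_covers_unit_square(self):
        ds = ss.generate_fixture_scrnaseq(ss.FixtureConfig(
            n_populations=1, cells_per_population=400, n_genes=10,
            markers_per_population=1, seed=0))
        cfg = ss.RandomPatternConfig(grid_n=5, delta=1.0, lam=1.0,
                                     patterned_populations=["pop_0"], seed=0)
        a = ss.allocate_random_patterns(ds, cfg)
        # all 25 grids claimed -> occupied grid set is the full grid
        gx = np.floor(a.coordinates[:, 0] * 5).clip(0, 4)
        gy = np.floor(a.coordinates[:, 1] * 5).clip(0, 4)
        assert len(set(zip(gx, gy))) == 25

    def test_unknown_patterned_population_rejected(self, nb_fixture):
        cfg = ss.RandomPatternConfig(patterned_populations=["ghost"], seed=0)
        with pytest.raises(KeyError):
            ss.allocate_random_patterns(nb_fixture, cfg)

    def test_three_dimensional_field(self, nb_fixture):
        cfg = ss.RandomPatternConfig(grid_n=5, delta=1.0, lam=1.0, ndim=3,
                                     patterned_populations=["pop_0"], seed=0)
        a = ss.allocate_random_patterns(nb_fixture, cfg)
        assert a.ndim == 3
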