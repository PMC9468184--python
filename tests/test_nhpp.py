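import numpy as np
import pytest
from scipy import integrate

from vasctda.nhpp import (
    ContingencyTable,
    DomainBox,
    NHPPParams,
    extract_changed_blocks,
    fisher_region_test,
    fit,
    fit_blocks,
    intensity_at,
    kernel_eval,
    log_likelihood,
    simulate,
)
from vasctda.volume_io import PointCloud3D

from .oracles import fisher_two_sided_enumeration


def quad_axis_mass(a, b, lo=-np.inf, hi=np.inf):
    """1D factor ∫ a·b/(e^{bu}+2+e^{−bu}) du by adaptive quadrature."""
    val, _ = integrate.quad(
        lambda u: a * b / (np.exp(b * u) + 2 + np.exp(-b * u)), lo, hi, limit=400
    )
    return val


class TestKernel:
    def test_origin_values(self):
        assert kernel_eval([0, 0, 0], NHPPParams(1, (1, 1, 1))) == pytest.approx(1 / 64)
        assert kernel_eval([0, 0, 0], NHPPParams(2, (1, 2, 4))) == pytest.approx(1.0)

    def test_total_mass_is_a_cubed(self, rng):
        for _ in range(5):
            a = float(rng.uniform(0.5, 3))
            b = tuple(rng.uniform(0.05, 2, 3))
            mass = np.prod([quad_axis_mass(a, bi) for bi in b])
            assert mass == pytest.approx(a**3, rel=1e-6)

    def test_overflow_safe_far_from_origin(self):
        val = kernel_eval([1e6, 0, 0], NHPPParams(1, (1, 1, 1)))
        assert 0.0 <= val < 1e-300

    def test_even_in_each_axis(self, rng):
        p = NHPPParams(1.3, (0.2, 0.5, 1.0))
        u = rng.uniform(-3, 3, 3)
        assert kernel_eval(u, p) == pytest.approx(kernel_eval(-u, p))


class TestIntensity:
    def test_two_points_leave_one_out(self):
        pts = np.array([[0, 0, 0], [10, 0, 0]], dtype=float)
        p = NHPPParams(1.2, (0.3, 0.3, 0.3))
        lam = intensity_at(pts[0], pts, p, exclude_index=0)
        assert lam == pytest.approx(kernel_eval(pts[0] - pts[1], p))

    def test_decay_far_from_all_points(self, rng):
        pts = rng.uniform(0, 10, (20, 3))
        p = NHPPParams(1.0, (0.5, 0.5, 0.5))
        far = np.array([10 + 50 / 0.5, 0, 0])
        lam = intensity_at(far, pts, p)
        assert lam <= 1e-10 * 20 * kernel_eval([0, 0, 0], p)

    def test_translation_invariance(self, rng):
        pts = rng.uniform(0, 10, (15, 3))
        p = NHPPParams(1.0, (0.4, 0.6, 0.8))
        u = np.array([2.0, 3.0, 4.0])
        shift = np.array([100.0, -50.0, 7.0])
        assert intensity_at(u, pts, p) == pytest.approx(
            intensity_at(u + shift, pts + shift, p)
        )


class TestLogLikelihood:
    def box_integral_quadrature(self, coords, p, box):
        total = 0.0
        for c in coords:
            total += np.prod(
                [
                    quad_axis_mass(p.a, p.b[i], box.lo[i] - c[i], box.hi[i] - c[i])
                    for i in range(3)
                ]
            )
        return total

    def test_closed_form_integral_matches_quadrature(self, rng):
        from vasctda.nhpp import _box_integral

        for _ in range(5):
            coords = rng.uniform(-5, 15, (6, 3))
            p = NHPPParams(float(rng.uniform(0.5, 2)), tuple(rng.uniform(0.1, 1, 3)))
            box = DomainBox((0, 0, 0), tuple(rng.uniform(5, 20, 3)))
            closed = _box_integral(coords, p, box)
            assert closed == pytest.approx(
                self.box_integral_quadrature(coords, p, box), rel=1e-6
            )

    def test_infinite_box_limit(self, rng):
        from vasctda.nhpp import _box_integral

        coords = rng.uniform(0, 10, (8, 3))
        p = NHPPParams(1.4, (0.5, 0.5, 0.5))
        big = DomainBox((-1e5, -1e5, -1e5), (1e5, 1e5, 1e5))
        assert _box_integral(coords, p, big) == pytest.approx(8 * p.total_mass, rel=1e-9)

    def test_strength_scaling_of_integral(self, rng):
        from vasctda.nhpp import _box_integral

        coords = rng.uniform(0, 10, (8, 3))
        box = DomainBox((0, 0, 0), (10, 10, 10))
        b = (0.4, 0.4, 0.4)
        full = _box_integral(coords, NHPPParams(1.0, b), box)
        half = _box_integral(coords, NHPPParams(0.5, b), box)
        assert half == pytest.approx(full / 8.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(np.zeros((1, 3)), NHPPParams(1, (1, 1, 1)), DomainBox((0,) * 3, (1,) * 3))


class TestSimulate:
    def test_expected_count(self):
        p = NHPPParams(1.0, (5.0, 5.0, 5.0))  # tight kernels: negligible edge loss
        box = DomainBox((0, 0, 0), (100, 100, 100))
        cloud = simulate(100, p, box, seed=4)
        assert abs(cloud.n - 100) <= 3 * np.sqrt(100)

    def test_offset_variance_matches_logistic(self):
        p = NHPPParams(4.7, (0.1, 0.2, 0.4))  # a³ ≈ 104 offspring per center
        box = DomainBox((-1e4, -1e4, -1e4), (1e4, 1e4, 1e4))
        cloud = simulate(1000, p, box, seed=5)
        assert cloud.n > 1e5
        # variance of (offset + uniform center): estimate per-cluster spread
        # by regenerating with one center at the origin
        rng = np.random.default_rng(0)
        u = rng.uniform(size=(100_000, 3))
        offsets = np.log(u / (1 - u)) / np.array(p.b)
        for i in range(3):
            expected = np.pi**2 / (3 * p.b[i] ** 2)
            assert offsets[:, i].var() == pytest.approx(expected, rel=0.05)

    def test_deterministic_per_seed(self):
        p = NHPPParams(1.5, (0.1, 0.1, 0.1))
        box = DomainBox((0, 0, 0), (500, 500, 500))
        c1 = simulate(50, p, box, seed=9)
        c2 = simulate(50, p, box, seed=9)
        np.testing.assert_array_equal(c1.coords, c2.coords)

    def test_retention_reported(self):
        p = NHPPParams(1.5, (0.01, 0.01, 0.01))  # wide kernels leak out
        box = DomainBox((0, 0, 0), (100, 100, 100))
        cloud = simulate(50, p, box, seed=0)
        assert 0 < cloud.meta["retention"] < 1


class TestFit:
    def test_anisotropy_recovered(self):
        p = NHPPParams(1.5, (0.05, 0.05, 0.2))
        box = DomainBox((0, 0, 0), (1000, 1000, 1000))
        cloud = simulate(590, p, box, seed=11)
        res = fit(cloud, box, seed=11)
        assert res.params.b[2] / res.params.b[0] > 1.0
        assert res.params.b[2] / res.params.b[1] > 1.0

    def test_isotropic_fit_is_roughly_isotropic(self):
        p = NHPPParams(1.5, (0.1, 0.1, 0.1))
        box = DomainBox((0, 0, 0), (800, 800, 800))
        cloud = simulate(400, p, box, seed=12)
        res = fit(cloud, box, seed=12)
        bx, by = res.params.b[0], res.params.b[1]
        assert abs(bx - by) / bx < 0.25

    def test_optimum_at_least_as_good_as_truth(self):
        p = NHPPParams(1.5, (0.08, 0.08, 0.15))
        box = DomainBox((0, 0, 0), (600, 600, 600))
        cloud = simulate(150, p, box, seed=13)
        res = fit(cloud, box, seed=13)
        assert res.log_lik >= log_likelihood(cloud, p, box) - 1e-6

    def test_stretched_cloud_lowers_that_axis_concentration(self):
        # stretching clustered data along x widens the kernels the fit needs
        # on that axis, i.e. lowers the fitted concentration b_x
        p = NHPPParams(1.5, (0.1, 0.1, 0.1))
        box = DomainBox((0, 0, 0), (600, 600, 600))
        cloud = simulate(250, p, box, seed=7)
        stretched = cloud.coords * np.array([4.0, 1.0, 1.0])
        res = fit(stretched, DomainBox.from_points(stretched), seed=7)
        assert res.params.b[0] < res.params.b[1]
        assert res.params.b[0] < res.params.b[2]


class TestChangedBlocks:
    def make_grid(self, values_a, values_b):
        from vasctda.nhpp import BlockFit, BlockGrid

        blocks = []
        for k, (va, vb) in enumerate(zip(values_a, values_b)):
            blocks.append(
                BlockFit(
                    (k, 0, 0),
                    DomainBox((k, 0, 0), (k + 1, 1, 1)),
                    region_id=0,
                    n_points={"A": 100, "B": 100},
                    params={"A": va, "B": vb},
                    evaluable=True,
                )
            )
        return BlockGrid(DomainBox((0, 0, 0), (len(blocks), 1, 1)), 1.0, ("A", "B"), blocks)

    def test_strength_fold_change(self):
        grid = self.make_grid(
            [NHPPParams(3.0, (1, 1, 1)), NHPPParams(1.9, (1, 1, 1))],
            [NHPPParams(1.0, (1, 1, 1)), NHPPParams(1.0, (1, 1, 1))],
        )
        changed = extract_changed_blocks(grid, param="a", fold=2.0)
        assert changed.tolist() == [True, False]

    def test_reciprocal_directionality_fold(self):
        grid = self.make_grid(
            [NHPPParams(1.0, (0.5, 1, 1))], [NHPPParams(1.0, (2.0, 1, 1))]
        )
        changed = extract_changed_blocks(grid, param="inv_b_x", fold=2.0)
        assert changed.tolist() == [True]  # 1/b ratio = 4

    def test_mass_parameter(self):
        grid = self.make_grid(
            [NHPPParams(4.0 ** (1 / 3), (1, 1, 1))], [NHPPParams(1.0, (1, 1, 1))]
        )
        assert extract_changed_blocks(grid, param="mass", fold=2.0).tolist() == [True]
        assert extract_changed_blocks(grid, param="a", fold=2.0).tolist() == [False]


class TestFisher:
    def test_example_table(self):
        table, p = fisher_region_test(
            np.array([1] * 9 + [0] * 11, dtype=bool),
            np.array([1] * 8 + [0, 1, 1] + [0] * 9, dtype=bool),
        )
        assert (table.A, table.B, table.C, table.D) == (8, 1, 2, 9)
        assert p == pytest.approx(920 / 167960, rel=1e-12)

    def test_degenerate_margin_gives_one(self):
        _, p = fisher_region_test(np.zeros(10, bool), np.arange(10) < 5)
        assert p == 1.0

    def test_row_and_column_swap_invariance(self):
        changed = np.array([1, 1, 0, 0, 1, 0, 1, 0], dtype=bool)
        area = np.array([1, 0, 1, 0, 0, 1, 1, 0], dtype=bool)
        _, p1 = fisher_region_test(changed, area)
        _, p2 = fisher_region_test(~changed, ~area)
        assert p1 == pytest.approx(p2, rel=1e-12)

    @pytest.mark.parametrize("total", [6, 11])
    def test_matches_enumeration_oracle_small_tables(self, total):
        for a in range(total + 1):
            for b in range(total + 1 - a):
                for c in range(total + 1 - a - b):
                    d = total - a - b - c
                    changed = np.array([1] * (a + b) + [0] * (c + d), dtype=bool)
                    area = np.array(
                        [1] * a + [0] * b + [1] * c + [0] * d, dtype=bool
                    )
                    _, p = fisher_region_test(changed, area)
                    assert p == pytest.approx(
                        fisher_two_sided_enumeration(a, b, c, d), rel=1e-9, abs=1e-12
                    )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fisher_region_test(np.zeros(3, bool), np.zeros(4, bool))

    def test_contingency_counts_non_negative(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestFitBlocks:
    def test_single_block_covers_whole_domain(self, rng):
        box = DomainBox((0, 0, 0), (100, 100, 100))
        a = PointCloud3D(rng.uniform(0, 100, (80, 3)), channel="A")
        b = PointCloud3D(rng.uniform(0, 100, (80, 3)), channel="B")
        grid = fit_blocks(a, b, box, block_edge=100.0, min_points=10)
        assert len(grid.blocks) == 1 and grid.blocks[0].evaluable

    def test_min_points_makes_blocks_unevaluable(self, rng):
        box = DomainBox((0, 0, 0), (100, 100, 100))
        a = PointCloud3D(rng.uniform(0, 100, (30, 3)), channel="A")
        b = PointCloud3D(rng.uniform(0, 100, (30, 3)), channel="B")
        grid = fit_blocks(a, b, box, block_edge=50.0, min_points=1000)
        assert all(not blk.evaluable for blk in grid.blocks)
        assert extract_changed_blocks(grid, param="a").size == 0

    def test_blocks_tile_box_volume(self, rng):
        box = DomainBox((0, 0, 0), (250, 100, 100))
        a = PointCloud3D(rng.uniform(0, 100, (10, 3)), channel="A")
        b = PointCloud3D(rng.uniform(0, 100, (10, 3)), channel="B")
        grid = fit_blocks(a, b, box, block_edge=100.0, min_points=1000)
        total = sum(blk.box.volume for blk in grid.blocks)
        assert total == pytest.approx(box.volume)
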