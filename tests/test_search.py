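"""Grid scans, the U-shape rule, annealing, and the level-set probe."""

import math

import numpy as np
import pytest

from bpgrowth.data import walleye_table1
from bpgrowth.fitting import BertalanffyPutter, fit_fixed_pair
from bpgrowth.growth import ExponentPair, GrowthParameters
from bpgrowth.search import (
    AnnealConfig,
    GridSpec,
    anneal_refine,
    coarse_scan,
    detect_interior_minimum,
    global_optimum,
    parameter_level_set,
    scan_row,
)


class TestGridSpec:
    def test_round1_region_point_count(self):
        # combinatorial oracle: 11 a-values, off-diagonal rows of
        # 15, 14, ..., 5 points (sum 110), plus 11 diagonal points
        grid = GridSpec(a_min=0.0, a_max=1.0, b_max=1.5, step=0.1)
        pts = grid.points()
        off = [p for p in pts if not p.is_gompertz]
        diag = [p for p in pts if p.is_gompertz]
        assert len(off) == 110
        assert len(diag) == 11
        assert len(pts) == 121

    def test_validation(self):
        with pytest.raises(ValueError):
            GridSpec(step=0.0)
        with pytest.raises(ValueError):
            GridSpec(a_min=1.0, b_max=0.5)


class TestDetectInteriorMinimum:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([5, 3, 4], 1),
            ([5, 4, 3], None),
            ([3, 4, 5], None),
            ([math.inf, 4, 3, 5], 2),
            ([math.inf, math.inf, math.inf], None),
            ([5, 3], None),
        ],
    )
    def test_examples(self, row, expected):
        assert detect_interior_minimum(row) == expected

    def test_convex_sequence(self):
        b = np.linspace(0, 2, 21)
        row = 3.0 + (b - 0.7) ** 2
        assert detect_interior_minimum(row) == int(np.argmin(row))


class TestCoarseScan:
    def test_single_point_grid_matches_direct_fit(self, walleye):
        grid = GridSpec(a_min=0.5, a_max=0.5, b_max=0.6, step=0.1,
                        include_diagonal=False)
        surface = coarse_scan(walleye, grid, anneal_steps=200, seed=0)
        assert len(surface) == 1
        entry = surface.get(0.5, 0.6)
        direct = fit_fixed_pair(ExponentPair(0.5, 0.6), walleye,
                                method="local-simplex")
        assert entry.sse == pytest.approx(direct.sse, rel=1e-4)

    def test_surface_entries_recompute(self, walleye, model):
        grid = GridSpec(a_min=0.6, a_max=0.7, b_max=0.9, step=0.1)
        surface = coarse_scan(walleye, grid, anneal_steps=200, seed=0,
                              methods=("constrained-gradient",))
        for res in surface:
            if math.isfinite(res.sse):
                assert model.sse(res.pair, res.params) == pytest.approx(
                    res.sse, rel=1e-9
                )

    def test_diagonal_points_fitted_as_gompertz(self, walleye):
        # step larger than b_max - a_min leaves only the diagonal point
        grid = GridSpec(a_min=0.7, a_max=0.7, b_max=0.8, step=0.2)
        surface = coarse_scan(walleye, grid, anneal_steps=200, seed=0,
                              methods=("constrained-gradient",))
        entry = surface.get(0.7, 0.7)
        assert entry.pair.is_gompertz
        assert math.isfinite(entry.sse)


class TestScanRow:
    def test_row_a067_has_interior_minimum_at_b070(self, walleye):
        row, idx = scan_row(walleye, 0.67, step=0.01, b_max=0.80)
        assert idx is not None
        b_star = 0.67 + 0.01 * (idx + 1)
        assert b_star == pytest.approx(0.70, abs=0.011)
        sses = [r.sse for r in row]
        assert row[idx].sse == min(s for s in sses if math.isfinite(s))

    def test_warm_start_not_worse_than_cold(self, walleye):
        warm, _ = scan_row(walleye, 0.5, step=0.02, b_max=0.6, warm=True)
        cold, _ = scan_row(walleye, 0.5, step=0.02, b_max=0.6, warm=False)
        for w, c in zip(warm, cold):
            assert w.sse <= c.sse * (1 + 1e-6)

    def test_row_extends_until_interior(self, walleye):
        # starting right of the row minimum forces the U-shape extension
        row, idx = scan_row(walleye, 0.3, step=0.05, b_max=0.45,
                            extend_increment=0.25, b_cap=2.0)
        assert len(row) > 3  # extended past the initial b_max
        assert idx is not None


class TestAnnealRefine:
    def setup_method(self):
        self.data = walleye_table1()
        self.model = BertalanffyPutter(self.data)
        self.start = self.model.fit(
            ExponentPair(0.7, 0.7), method="constrained-gradient"
        )

    def test_single_step(self):
        cfg = AnnealConfig(steps=1, seed=0, vary_exponents=False)
        res = anneal_refine(self.data, self.start.pair, self.start.params, cfg)
        assert res.sse <= self.model.sse(self.start.pair, self.start.params)

    def test_seeded_reproducibility(self):
        cfg = AnnealConfig(steps=2000, seed=42)
        r1 = anneal_refine(self.data, self.start.pair, self.start.params, cfg)
        r2 = anneal_refine(self.data, self.start.pair, self.start.params, cfg)
        assert r1.sse == r2.sse
        assert tuple(r1.params) == tuple(r2.params)
        assert (r1.pair.a, r1.pair.b) == (r2.pair.a, r2.pair.b)

    def test_best_so_far_monotone_and_positive(self):
        cfg = AnnealConfig(steps=2000, seed=1)
        res, trace = anneal_refine(
            self.data, self.start.pair, self.start.params, cfg, return_trace=True
        )
        best = trace["best_sse"].to_numpy()
        assert np.all(np.diff(best) <= 0)
        assert res.sse == best[-1]
        assert all(v > 0 for v in res.params)
        assert res.pair.a <= res.pair.b

    def test_diagonal_family_stays_diagonal(self):
        cfg = AnnealConfig(steps=2000, seed=3)
        res = anneal_refine(self.data, self.start.pair, self.start.params, cfg)
        assert res.pair.is_gompertz

    def test_never_worse_than_start(self):
        cfg = AnnealConfig(steps=500, seed=9)
        res = anneal_refine(self.data, self.start.pair, self.start.params, cfg)
        assert res.sse <= self.start.sse

    def test_infeasible_start_rejected(self):
        with pytest.raises(ValueError):
            anneal_refine(
                self.data,
                ExponentPair(0.5, 1.0),
                GrowthParameters(5.0, 1.0, 0.1),  # m0 below the 10 g floor
                AnnealConfig(steps=10, seed=0),
            )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AnnealConfig(steps=0)
        with pytest.raises(ValueError):
            AnnealConfig(steps=10, t0=-1.0)


class TestGlobalOptimum:
    def test_single_point_surface_is_refined(self, walleye):
        from bpgrowth.search import SSESurface

        surface = SSESurface()
        surface.add(fit_fixed_pair(ExponentPair(0.7, 0.7), walleye,
                                   method="constrained-gradient"))
        best, family = global_optimum(
            walleye, surface, anneal_config=AnnealConfig(steps=2000, seed=0)
        )
        assert family == "gompertz-diagonal"
        assert best.sse <= surface.best().sse

    def test_empty_surface_rejected(self, walleye):
        from bpgrowth.search import SSESurface

        with pytest.raises(ValueError):
            global_optimum(walleye, SSESurface())


class TestParameterLevelSet:
    def test_cap_below_minimum_rejected(self, walleye):
        with pytest.raises(ValueError, match="cap"):
            parameter_level_set(ExponentPair(2 / 3, 1), walleye, 1.0)

    def test_infinite_cap_accepts_everything(self, walleye):
        ls = parameter_level_set(
            ExponentPair(2 / 3, 1), walleye, math.inf, n_samples=10, seed=0
        )
        assert len(ls.samples) == 10

    def test_tight_cap_stays_near_optimum(self, walleye, model):
        # a cap 1% above the minimum with small steps confines the walk to
        # a narrow neighbourhood of the optimum
        opt = model.fit(ExponentPair(2 / 3, 1), method="constrained-gradient")
        ls = parameter_level_set(
            ExponentPair(2 / 3, 1), walleye, opt.sse * 1.01,
            n_samples=40, seed=0, step_sigma=3e-4, start=opt,
        )
        assert len(ls.samples) == 40
        rel = np.abs(ls.samples / np.array(list(opt.params)) - 1)
        assert np.max(rel) < 0.05

    def test_thin_ridge_at_diagonal_optimum(self, walleye):
        # the SSE <= 1e7 region of (m0, p, q) at the near-optimal Gompertz
        # exponent is a thin ridge: smallest principal spread well under
        # a tenth of the largest (walk settings fixed, seed 0)
        ls = parameter_level_set(
            ExponentPair(0.686028, 0.686028), walleye, 1e7,
            n_samples=300, seed=0, step_sigma=0.1,
        )
        assert ls.thin_ridge_ratio < 0.05
        assert np.all(ls.sse_values <= 1e7)
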