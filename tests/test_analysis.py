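"""Radial bins, lineage radiality and regime comparison."""

import math

import numpy as np
import pytest

import cambiumsim as cs
from cambiumsim import analysis
from cambiumsim.mesh import TissueMesh


def square_at(t, x, y, side=1.0, cell_type="cambium"):
    ids = [t.add_vertex(x + dx, y + dy)
           for dx, dy in [(0, 0), (side, 0), (side, side), (0, side)]]
    return t.add_cell(ids, cell_type)


def scatter_tissue(centers):
    """Disconnected unit squares centred at the given points (for
    center/binning tests only; not a valid tiling)."""
    t = TissueMesh()
    for x, y in centers:
        square_at(t, x - 0.5, y - 0.5)
    return t


class TestTissueCenter:
    def test_symmetric_cells(self):
        t = scatter_tissue([(1, 1), (-1, 1), (1, -1), (-1, -1)])
        assert analysis.tissue_center(t) == pytest.approx((0.0, 0.0))

    def test_translation_equivariance(self):
        pts = [(0, 0), (3, 1), (1, 4), (-2, 2)]
        t1 = scatter_tissue(pts)
        t2 = scatter_tissue([(x + 5, y - 3) for x, y in pts])
        c1 = analysis.tissue_center(t1)
        c2 = analysis.tissue_center(t2)
        assert c2[0] - c1[0] == pytest.approx(5.0)
        assert c2[1] - c1[1] == pytest.approx(-3.0)

    def test_matches_mean_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-5, 5, size=(20, 2))
        t = scatter_tissue([tuple(p) for p in pts])
        assert analysis.tissue_center(t) == pytest.approx(
            tuple(pts.mean(axis=0)), abs=1e-9)


class TestAssignBins:
    def test_equidistant_cells_in_last_bin(self):
        t = scatter_tissue([(2, 0), (-2, 0), (0, 2), (0, -2)])
        bins = analysis.assign_bins(t, 5)
        assert set(bins.values()) == {4}

    def test_single_bin(self):
        t = scatter_tissue([(0, 0), (1, 1), (5, 2)])
        assert set(analysis.assign_bins(t, 1).values()) == {0}

    def test_matches_brute_force_sort(self):
        t = cs.make_template(cs.TemplateSpec(seed=12), "M1")
        n_bins = 7
        bins = analysis.assign_bins(t, n_bins)
        cx, cy = analysis.tissue_center(t)
        dist = {c.id: math.hypot(t.centroid(c)[0] - cx,
                                 t.centroid(c)[1] - cy)
                for c in t.cells.values()}
        dmax = max(dist.values())
        for cid, d in dist.items():
            expected = min(int(d / dmax * n_bins), n_bins - 1)
            assert bins[cid] == expected
        assert set(bins) == set(t.cells)


class TestBinProfiles:
    def test_linear_field_monotone_and_peaks_at_100(self):
        t = cs.make_template(cs.TemplateSpec(seed=2), "M1")
        cx, cy = analysis.tissue_center(t)
        for c in t.cells.values():
            x, y = t.centroid(c)
            c.chemicals = {"CLE41": math.hypot(x - cx, y - cy)}
        prof = analysis.bin_profiles([t], n_bins=5, chemicals=("CLE41",))
        sub = prof[prof.quantity == "CLE41"].sort_values("bin")
        vals = sub["mean_pct"].to_numpy()
        vals = vals[np.isfinite(vals)]  # bins without cells are missing
        assert np.all(np.diff(vals) >= -1e-9)
        assert vals[-1] == pytest.approx(100.0)

    def test_identical_simulations_have_zero_envelope(self):
        t1 = cs.make_template(cs.TemplateSpec(seed=2), "M1")
        t2 = cs.make_template(cs.TemplateSpec(seed=2), "M1")
        prof = analysis.bin_profiles([t1, t2], n_bins=4)
        assert (prof["max_pct"] - prof["min_pct"]).abs().max() < 1e-12

    def test_hand_computed_three_bin_fixture(self):
        # cells at distances 0.5, 1.5, 2.5 (bins 0, 1, 2 of 3 over [0, 2.5])
        # with chemical 2, 6, 3: normalized percentages 33.33, 100, 50
        t = scatter_tissue([(0.5, 0), (1.5, 0), (2.5, 0),
                            (-0.5, 0), (-1.5, 0), (-2.5, 0)])
        for cid, c in t.cells.items():
            d = abs(t.centroid(c)[0])
            c.chemicals = {"X": {0.5: 2.0, 1.5: 6.0, 2.5: 3.0}[round(d, 1)]}
        prof = analysis.bin_profiles([t], n_bins=3, chemicals=("X",))
        sub = prof[prof.quantity == "X"].sort_values("bin")
        assert sub["mean_pct"].to_numpy() == pytest.approx(
            [100 * 2 / 6, 100.0, 50.0])


class TestLineageRadiality:
    def test_collinear_points_give_one(self):
        pts = [(i, 2 * i + 1) for i in range(5)]
        assert analysis.lineage_radiality(np.array(pts, float)) == \
            pytest.approx(1.0)

    def test_axis_aligned_line_is_degenerate_one(self):
        pts = np.array([(i, 3.0) for i in range(5)])
        assert analysis.lineage_radiality(pts) == 1.0

    def test_square_corners_give_zero(self):
        pts = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float)
        assert analysis.lineage_radiality(pts) == pytest.approx(0.0)

    def test_matches_ols_oracle_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            pts = rng.normal(size=(n, 2)) * rng.uniform(0.5, 3, 2)
            if pts[:, 0].std() == 0 or pts[:, 1].std() == 0:
                continue
            # OLS y~x coefficient of determination
            slope, icpt = np.polyfit(pts[:, 0], pts[:, 1], 1)
            resid = pts[:, 1] - (slope * pts[:, 0] + icpt)
            ss_res = float(np.sum(resid ** 2))
            ss_tot = float(np.sum((pts[:, 1] - pts[:, 1].mean()) ** 2))
            expected = 1.0 - ss_res / ss_tot
            assert analysis.lineage_radiality(pts) == pytest.approx(
                expected, abs=1e-10)

    def test_rotation_by_right_angles_and_translation_invariant(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(8, 2)) @ np.diag([2.0, 0.5])
        base = analysis.lineage_radiality(pts)
        assert analysis.lineage_radiality(pts + [10, -4]) == \
            pytest.approx(base, abs=1e-12)
        rot90 = pts @ np.array([[0.0, 1.0], [-1.0, 0.0]])
        assert analysis.lineage_radiality(rot90) == pytest.approx(
            base, abs=1e-12)

    def test_too_few_distinct_points_rejected(self):
        with pytest.raises(ValueError):
            analysis.lineage_radiality(np.array([(0, 0), (1, 1), (0, 0)],
                                                dtype=float))


class TestRadialityDistribution:
    def test_all_high(self):
        assert analysis.radiality_distribution([1.0, 0.9, 0.8]) == \
            pytest.approx([0, 0, 0, 1])

    def test_zero_goes_to_first_interval(self):
        f = analysis.radiality_distribution([0.0, 0.25, 0.5, 0.75, 1.0])
        assert f == pytest.approx([0.4, 0.2, 0.2, 0.2])

    def test_fuzzed_sums_to_one_and_matches_histogram(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            vals = rng.uniform(0, 1, int(rng.integers(1, 60))).tolist()
            f = analysis.radiality_distribution(vals)
            assert f.sum() == pytest.approx(1.0)
            brute = np.zeros(4)
            for v in vals:
                idx = 0 if v == 0 else min(int(np.ceil(v / 0.25)) - 1, 3)
                brute[idx] += 1
            assert f == pytest.approx(brute / len(vals))


class TestCompareRegimes:
    def test_null_calibration(self):
        """Same-distribution regimes: omnibus rejects at ~nominal rate."""
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 200
        for _ in range(reps):
            a = rng.uniform(size=(10, 4))
            b = rng.uniform(size=(10, 4))
            res = analysis.compare_regimes({"a": a, "b": b}, rng)
            if res[0].kw_p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.10

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(1)
        rates = []
        for shift in (0.0, 0.3, 0.8):
            rej = 0
            for _ in range(60):
                a = rng.normal(0, 1, size=(12, 4))
                b = rng.normal(shift, 1, size=(12, 4))
                res = analysis.compare_regimes({"a": a, "b": b}, rng)
                if res[0].kw_p < 0.05:
                    rej += 1
            rates.append(rej / 60)
        assert rates[0] < rates[1] < rates[2]

    def test_identical_samples_share_letters(self):
        rng = np.random.default_rng(2)
        x = np.tile(np.array([0.2, 0.3, 0.4, 0.1]), (5, 1))
        res = analysis.compare_regimes({"a": x.copy(), "b": x.copy(),
                                        "c": x.copy()}, rng)
        for r in res:
            assert r.kw_p == 1.0
            assert len(set(r.letters.values())) == 1

    def test_subsampling_equalizes_sizes(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=(20, 4))
        b = rng.uniform(size=(7, 4))
        res = analysis.compare_regimes({"a": a, "b": b}, rng)
        assert res[0].subsample_size == 7

    def test_dunn_on_known_fixture(self):
        """Dunn z for two groups equals the normal approximation of the
        rank-sum comparison (hand-checkable fixture, no ties)."""
        groups = {"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 6.0, 7.0, 8.0]}
        df = analysis.dunn_test(groups)
        n = 8
        mean_a, mean_b = 2.5, 6.5
        se = math.sqrt((n * (n + 1) / 12.0) * (1 / 4 + 1 / 4))
        assert df.iloc[0]["z"] == pytest.approx((mean_a - mean_b) / se)


class TestMorphometrics:
    def test_rectangle_axis_ratio(self):
        t = TissueMesh()
        ids = [t.add_vertex(x, y) for x, y in
               [(0, 0), (2, 0), (2, 1), (0, 1)]]
        t.add_cell(ids, "xylem")
        df = analysis.morphometrics(t)
        row = df[df.cell_type == "xylem"].iloc[0]
        # uniform 2x1 rectangle: major axis length 2x the minor axis,
        # and 4*sqrt(lambda_max) = 4*sqrt(4/12) for the unit-height box
        assert row.mean_major_axis == pytest.approx(4 * math.sqrt(4 / 12))
        cov = cs.mesh.polygon_second_moments(t.ring_coords(0))
        evals = np.linalg.eigvalsh(cov)
        assert math.sqrt(evals[1] / evals[0]) == pytest.approx(2.0)

    def test_counts_match_template_report(self):
        from cambiumsim import template
        t = cs.make_template(cs.TemplateSpec(seed=4), "M3A")
        df = analysis.morphometrics(t).set_index("cell_type")
        rep = template.template_report(t).set_index("cell_type")
        for ct in rep.index:
            assert df.loc[ct, "count"] == rep.loc[ct, "count"]

    def test_areas_match_mesh(self):
        t = cs.make_template(cs.TemplateSpec(seed=4), "M1")
        df = analysis.morphometrics(t).set_index("cell_type")
        areas = {}
        for c in t.cells.values():
            areas.setdefault(c.cell_type, []).append(t.cell_area(c))
        for ct, vals in areas.items():
            assert df.loc[ct, "mean_area"] == pytest.approx(
                float(np.mean(vals)))


class TestPropertyBased:
    def test_radiality_fractions_partition_unit_interval(self):
        from hypothesis import given, settings, strategies as st

        @settings(deadline=None, derandomize=True, max_examples=50)
        @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                        min_size=1, max_size=40))
        def check(vals):
            f = analysis.radiality_distribution(vals)
            assert f.sum() == pytest.approx(1.0)
            assert (f >= 0).all()

        check()

    def test_lineage_r2_bounded_and_symmetric_in_axes(self):
        from hypothesis import given, settings, strategies as st

        @settings(deadline=None, derandomize=True, max_examples=50)
        @given(st.integers(min_value=0, max_value=10_000))
        def check(seed):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(6, 2))
            if pts[:, 0].std() == 0 or pts[:, 1].std() == 0:
                return
            r2 = analysis.lineage_radiality(pts)
            assert 0.0 <= r2 <= 1.0
            assert analysis.lineage_radiality(pts[:, ::-1]) == \
                pytest.approx(r2, abs=1e-12)

        check()
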