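"""The meristogram pipeline: standardization, smoothing, interpolation,
rescaling and peak extraction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meristo.core import (
    CurvePoint,
    compute_meristogram,
    derive_variables,
    interpolate_curves,
    minimum_mai,
    moving_average,
    peak_positions,
    rescale_to_collection_max,
    standardize_positions,
    standardize_row,
)
from meristo.hookio import HookCollection, HookRecord, HookRow

from conftest import brute_force_moving_average, make_collection, make_row


def random_collection(rng, n_rows=4, n_range=(3, 12)) -> HookCollection:
    rows = []
    for i in range(n_rows):
        n = int(rng.integers(*n_range))
        rows.append(
            make_row(
                rng.uniform(30, 120, n), rng.uniform(10, 40, n), specimen=f"r{i}"
            )
        )
    return make_collection(rows)


class TestStandardization:
    def test_percent_positions_follow_centring_formula(self):
        row = make_row([60] * 5, [20] * 5)
        np.testing.assert_allclose(
            standardize_positions(row),
            [100 / 6, 200 / 6, 50.0, 400 / 6, 500 / 6],
        )
        assert standardize_positions(make_row([60], [20])) == [50.0]
        assert standardize_positions(make_row([60] * 9, [20] * 9))[0] == pytest.approx(10.0)

    def test_derived_area_and_ratio(self):
        assert derive_variables(HookRecord(1, 60, 20)) == (600.0, pytest.approx(100 / 3))
        area, ratio = derive_variables(HookRecord(1, 90, 30))
        assert area == 1350.0 and ratio == pytest.approx(100 / 3)

    def test_ratio_length_identity(self):
        rec = HookRecord(1, 73.2, 21.9)
        area, ratio = derive_variables(rec)
        assert ratio * rec.length == pytest.approx(100 * rec.base)

    def test_row_standardization_divides_by_row_maxima(self):
        std = standardize_row(make_row([50, 100, 75], [20, 20, 20]))
        assert [h.l for h in std] == pytest.approx([50, 100, 75])
        # base constant -> all 100
        assert [h.b for h in std] == pytest.approx([100, 100, 100])

    def test_each_variable_attains_100_within_row(self):
        rng = np.random.default_rng(7)
        std = standardize_row(make_row(rng.uniform(30, 90, 8), rng.uniform(10, 30, 8)))
        for var in "lbar":
            assert max(getattr(h, var) for h in std) == pytest.approx(100.0)

    @given(c=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_row_scaling_is_annihilated(self, c, seed):
        """Multiplying all lengths and bases of a row by c > 0 changes no
        standardized value (allometry is removed by design)."""
        rng = np.random.default_rng(seed)
        lengths, bases = rng.uniform(30, 90, 6), rng.uniform(10, 30, 6)
        a = standardize_row(make_row(lengths, bases))
        b = standardize_row(make_row(lengths * c, bases * c))
        for ha, hb in zip(a, b):
            for var in "plbar":
                assert getattr(ha, var) == pytest.approx(getattr(hb, var), rel=1e-9)


class TestMinimumMai:
    @pytest.mark.parametrize("nmin,expected", [(5, 17), (9, 10), (99, 1), (4, 20)])
    def test_ceiling_formula_on_shortest_row(self, nmin, expected):
        rows = [
            make_row([60] * nmin, [20] * nmin, specimen="short"),
            make_row([60] * (nmin + 3), [20] * (nmin + 3), specimen="long"),
        ]
        assert minimum_mai(make_collection(rows)) == expected

    def test_window_at_mmai_covers_every_row(self):
        """With w = MMAI every window placement inside the populated span
        contains at least one hook from every row."""
        rng = np.random.default_rng(3)
        coll = random_collection(rng, n_rows=5, n_range=(4, 10))
        w = minimum_mai(coll)
        nmin = coll.min_row_length
        lo, hi = 100 / (nmin + 1), 100 * nmin / (nmin + 1)
        per_row = [standardize_row(r) for r in coll.rows]
        for s in range(0, 101 - w):
            if not (s >= lo and s + w <= hi):
                continue  # window not fully inside the populated span
            for hooks in per_row:
                assert any(s <= h.p < s + w for h in hooks)


class TestMovingAverage:
    def test_single_hook_yields_single_point(self):
        std = standardize_row(make_row([60], [20]))
        pts = moving_average(std, 20)
        assert len(pts) == 1
        assert pts[0] == CurvePoint(x=50.0, L=100.0, B=100.0, A=100.0, R=100.0)

    def test_constant_values_give_flat_curves(self):
        std = standardize_row(make_row([60] * 6, [20] * 6))
        for pt in moving_average(std, 17):
            assert pt.L == pt.B == pt.A == pt.R == pytest.approx(100.0)

    def test_two_hook_example_matches_brute_force(self):
        row = make_row([100, 50], [20, 20])
        std = standardize_row(row)
        assert moving_average(std, 17) == brute_force_moving_average(std, 17)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_on_random_collections(self, seed):
        """The vectorized smoother agrees exactly with an explicit
        double-loop enumeration of all window placements."""
        rng = np.random.default_rng(seed)
        coll = random_collection(rng, n_rows=int(rng.integers(1, 6)))
        hooks = [h for row in coll.rows for h in standardize_row(row)]
        assert coll.n_hooks <= 200
        w = int(rng.integers(minimum_mai(coll), 41))
        ours = moving_average(hooks, w)
        oracle = brute_force_moving_average(hooks, w)
        assert len(ours) == len(oracle)
        for a, b in zip(ours, oracle):
            assert a.x == pytest.approx(b.x, abs=1e-12)
            assert a.values() == pytest.approx(b.values(), abs=1e-9)

    def test_points_strictly_increasing_in_x(self):
        rng = np.random.default_rng(11)
        coll = random_collection(rng)
        hooks = [h for row in coll.rows for h in standardize_row(row)]
        xs = [pt.x for pt in moving_average(hooks, 20)]
        assert all(b > a for a, b in zip(xs, xs[1:]))

    def test_interval_below_minimum_is_rejected_with_mmai_cited(self):
        coll = make_collection([make_row([60] * 5, [20] * 5)])
        hooks = standardize_row(coll.rows[0])
        with pytest.raises(ValueError, match="17"):
            moving_average(hooks, 9, mmai=minimum_mai(coll))

    @pytest.mark.parametrize("w", [101, 17.5])
    def test_invalid_intervals_rejected(self, w):
        hooks = standardize_row(make_row([60] * 5, [20] * 5))
        with pytest.raises(ValueError):
            moving_average(hooks, w)


class TestInterpolation:
    def test_linear_values_between_two_points(self):
        pts = [
            CurvePoint(x=10.5, L=50, B=0, A=0, R=0),
            CurvePoint(x=12.5, L=60, B=0, A=0, R=0),
        ]
        out = interpolate_curves(pts)
        assert [pt.x for pt in out] == [11.0, 12.0]
        assert [pt.L for pt in out] == pytest.approx([52.5, 57.5])

    def test_integer_knots_are_reproduced_exactly(self):
        rng = np.random.default_rng(5)
        knots = np.sort(rng.choice(np.arange(10, 90), size=6, replace=False)).astype(float)
        vals = rng.uniform(20, 100, (6, 4))
        pts = [CurvePoint(x, *v) for x, v in zip(knots, vals)]
        out = {pt.x: pt for pt in interpolate_curves(pts)}
        for pt in pts:
            assert out[pt.x].values() == pytest.approx(pt.values(), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_matches_direct_piecewise_evaluation(self, seed):
        """Interpolated values equal a direct two-point linear formula at
        every integer between knots, and never leave the value range."""
        rng = np.random.default_rng(seed)
        xs = np.sort(rng.uniform(5, 95, 8))
        vals = rng.uniform(10, 100, (8, 4))
        pts = [CurvePoint(x, *v) for x, v in zip(xs, vals)]
        out = interpolate_curves(pts)
        for pt in out:
            j = np.searchsorted(xs, pt.x, side="right")
            if xs[j - 1] == pt.x:
                expected = vals[j - 1]
            else:
                t = (pt.x - xs[j - 1]) / (xs[j] - xs[j - 1])
                expected = (1 - t) * vals[j - 1] + t * vals[j]
            assert pt.values() == pytest.approx(tuple(expected), abs=1e-9)
            for k in range(4):
                assert vals[:, k].min() - 1e-12 <= pt.values()[k] <= vals[:, k].max() + 1e-12

    def test_single_distinct_position_is_rejected(self):
        pts = [CurvePoint(x=50.0, L=1, B=1, A=1, R=1)]
        with pytest.raises(ValueError, match="disable interpolation"):
            interpolate_curves(pts)


class TestRescale:
    def test_scales_each_variable_to_max_100(self):
        pts = [CurvePoint(0, 50, 10, 5, 2), CurvePoint(1, 25, 20, 10, 1)]
        out = rescale_to_collection_max(pts)
        assert [pt.L for pt in out] == pytest.approx([100, 50])
        assert [pt.B for pt in out] == pytest.approx([50, 100])

    def test_idempotent_on_already_scaled_curves(self):
        pts = [CurvePoint(0, 100, 40, 30, 100), CurvePoint(1, 50, 100, 100, 10)]
        once = rescale_to_collection_max(pts)
        assert rescale_to_collection_max(once) == pytest.approx(once)

    def test_argmax_positions_are_preserved(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(1, 90, (10, 4))
        pts = [CurvePoint(float(i), *v) for i, v in enumerate(vals)]
        out = rescale_to_collection_max(pts)
        for k, var in enumerate("LBAR"):
            assert np.argmax([getattr(p, var) for p in out]) == np.argmax(vals[:, k])


class TestComputeMeristogram:
    def test_every_curve_tops_out_at_100(self, simple_collection):
        for interp in (True, False):
            m = compute_meristogram(simple_collection, 15, interpolate=interp)
            for v in "LBAR":
                assert m.curve(v).max() == pytest.approx(100.0, rel=1e-9)

    def test_identical_hooks_give_flat_100_curves(self):
        coll = make_collection([make_row([60] * 8, [20] * 8)])
        m = compute_meristogram(coll, 17)
        for v in "LBAR":
            np.testing.assert_allclose(m.curve(v), 100.0)

    def test_row_permutation_and_relabelling_invariance(self):
        rng = np.random.default_rng(21)
        coll = random_collection(rng, n_rows=5)
        renamed = tuple(
            dataclasses.replace(r, specimen=f"z{i}") for i, r in enumerate(reversed(coll.rows))
        )
        w = max(20, minimum_mai(coll))
        m1 = compute_meristogram(coll, w)
        m2 = compute_meristogram(make_collection(renamed, label=coll.label), w)
        np.testing.assert_allclose(m1.x, m2.x)
        for v in "LBAR":
            np.testing.assert_allclose(m1.curve(v), m2.curve(v))

    @pytest.mark.parametrize("seed", range(4))
    def test_per_row_allometry_invariance(self, seed):
        """Scaling any single row's lengths and bases by c > 0 leaves the
        whole meristogram unchanged."""
        rng = np.random.default_rng(seed)
        coll = random_collection(rng, n_rows=4)
        factors = rng.uniform(0.2, 5.0, coll.n_rows)
        scaled_rows = []
        for row, c in zip(coll.rows, factors):
            recs = tuple(
                HookRecord(r.ordinal, r.length * c, r.base * c) for r in row.records
            )
            scaled_rows.append(dataclasses.replace(row, records=recs))
        w = max(20, minimum_mai(coll))
        m1 = compute_meristogram(coll, w)
        m2 = compute_meristogram(make_collection(scaled_rows, label=coll.label), w)
        np.testing.assert_allclose(m1.x, m2.x)
        for v in "LBAR":
            np.testing.assert_allclose(m1.curve(v), m2.curve(v), rtol=1e-9)

    def test_defaults_to_mmai_and_records_provenance(self, simple_collection):
        m = compute_meristogram(simple_collection)
        assert m.mai == minimum_mai(simple_collection)
        assert m.provenance == {"rows": 2, "hooks": 16}

    def test_interval_below_mmai_propagates(self, simple_collection):
        with pytest.raises(ValueError, match="below the minimum"):
            compute_meristogram(simple_collection, 5)


class TestPeaks:
    def test_peak_positions_report_argmax(self, simple_collection):
        m = compute_meristogram(simple_collection, 15)
        peaks = peak_positions(m)
        for v in "LBAR":
            assert m.curve(v)[list(m.x).index(peaks[v])] == pytest.approx(100.0)

    def test_ties_resolve_to_most_distal_position(self):
        coll = make_collection([make_row([60] * 8, [20] * 8)])
        m = compute_meristogram(coll, 17)  # flat curves: everything ties at 100
        peaks = peak_positions(m)
        assert all(p == m.x[0] for p in peaks.values())
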