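"""Correlation curves, persistence-length fits, angle and contour statistics."""

import numpy as np
import pytest

from afmwlc.errors import FitError, ParameterError
from afmwlc.tracing import TraceResult
from afmwlc.wlc_statistics import (
    CorrelationCurve,
    bending_angle_distribution,
    bootstrap_lp,
    contour_length_stats,
    fit_persistence_length,
    percent_change,
    tangent_correlation,
)


def straight_trace(n=20, step=8.0):
    pts = np.column_stack([step * np.arange(n), np.zeros(n)])
    return TraceResult(points=pts, step_nm=step, closed=False)


def square_trace(side=10.0):
    pts = np.array([[0, 0], [side, 0], [side, side], [0, side]], dtype=float)
    return TraceResult(points=pts, step_nm=side, closed=True)


def synthetic_curve(lp=56.0, step=8.0, kmax=15, offset=0.0):
    L = step * np.arange(kmax + 1)
    return CorrelationCurve(
        separations=L,
        mean_corr=np.exp(-L / (2 * lp)) + offset,
        n_pairs=np.full(kmax + 1, 100.0),
        se=np.zeros(kmax + 1),
        step_nm=step,
        n_molecules=1,
    )


def brute_force_lp(curve, lmin, lmax):
    """Independent oracle: grid search minimizing the unweighted SSE."""
    sel = (curve.separations >= lmin) & (curve.separations <= lmax)
    L, c = curve.separations[sel], curve.mean_corr[sel]
    grid = np.linspace(20.0, 150.0, 130_001)
    sse = ((c[None, :] - np.exp(-L[None, :] / (2 * grid[:, None]))) ** 2).sum(axis=1)
    best = grid[np.argmin(sse)]
    resid = c - np.exp(-L / (2 * best))
    return best, float(np.sqrt((resid**2).mean()))


class TestTangentCorrelation:
    def test_straight_traces_fully_correlated(self):
        curve = tangent_correlation([straight_trace() for _ in range(3)], 80.0)
        assert curve.mean_corr[0] == 1.0
        assert np.allclose(curve.mean_corr, 1.0)

    def test_square_perpendicular_at_one_side(self):
        curve = tangent_correlation([square_trace()], 20.0)
        assert curve.mean_corr[1] == pytest.approx(0.0, abs=1e-12)

    def test_pairs_non_increasing_for_open_trace(self):
        curve = tangent_correlation([straight_trace(30)], 120.0)
        assert np.all(np.diff(curve.n_pairs) <= 0)

    def test_wlc_ensemble_matches_decay(self, wlc_truth_traces):
        curve = tangent_correlation(wlc_truth_traces[:200], 120.0)
        expected = np.exp(-curve.separations / 112.0)
        sel = curve.separations <= 112.0
        assert np.all(
            np.abs(curve.mean_corr[sel] - expected[sel])
            < 3 * np.maximum(curve.se[sel], 1e-4)
        )

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            tangent_correlation([], 80.0)
        with pytest.raises(ParameterError):
            tangent_correlation([straight_trace(step=8.0), straight_trace(step=4.0)], 80.0)


class TestPersistenceLengthFit:
    def test_noiseless_inversion_exact(self):
        curve = synthetic_curve(lp=56.0)
        fit = fit_persistence_length(curve, (8.0, 120.0))
        assert fit.lp == pytest.approx(56.0, rel=1e-6)
        oracle, _ = brute_force_lp(curve, 8.0, 120.0)
        assert fit.lp == pytest.approx(oracle, rel=1e-3)

    def test_offset_perturbation_residual(self):
        """A +0.01 offset is left in the residuals, matching a brute-force fit."""
        curve = synthetic_curve(lp=56.0, offset=0.01)
        fit = fit_persistence_length(curve, (8.0, 120.0))
        oracle_lp, oracle_rms = brute_force_lp(curve, 8.0, 120.0)
        assert fit.lp == pytest.approx(oracle_lp, rel=1e-3)
        assert fit.residual_rms == pytest.approx(oracle_rms, rel=0.02)
        assert fit.residual_rms > 0.002

    def test_scale_consistency(self, wlc_truth_traces):
        """Scaling all coordinates by c scales the fitted Lp by c."""
        traces = wlc_truth_traces[:50]
        base = fit_persistence_length(tangent_correlation(traces, 120.0))
        c = 3.7
        scaled = [
            TraceResult(points=t.points * c, step_nm=t.step_nm * c, closed=False)
            for t in traces
        ]
        fit_scaled = fit_persistence_length(
            tangent_correlation(scaled, 120.0 * c)
        )
        assert fit_scaled.lp == pytest.approx(c * base.lp, rel=1e-3)

    def test_too_few_points_rejected(self):
        curve = synthetic_curve(kmax=3)
        with pytest.raises(ParameterError):
            fit_persistence_length(curve, (8.0, 16.0))

    def test_flat_curve_pins_at_bound(self):
        curve = synthetic_curve(lp=56.0)
        curve.mean_corr[:] = 1.0
        with pytest.raises(FitError):
            fit_persistence_length(curve, (8.0, 120.0))


class TestBendingAngles:
    def test_straight_traces_have_zero_angles(self):
        dist = bending_angle_distribution([straight_trace()], 16.0)
        assert np.allclose(dist.angles, 0.0)
        # histogram is a density over (-pi, pi]
        widths = np.diff(dist.bin_edges)
        assert (dist.densities * widths).sum() == pytest.approx(1.0)

    def test_wlc_variance_law_at_10nm(self):
        """var(theta) at 10 nm separation is 10/Lp for generator tangents."""
        from afmwlc.synthetic_data import sample_wlc_2d

        traces = []
        for i in range(300):
            poly = sample_wlc_2d(30, 10.0, 56.0, seed=40_000 + i)
            traces.append(TraceResult(points=poly.vertices, step_nm=10.0, closed=False))
        dist = bending_angle_distribution(traces, 10.0)
        var = dist.angles.var()
        se = np.sqrt(2.0 / len(dist.angles)) * var  # chi^2 s.e. of a variance
        assert abs(var - 10.0 / 56.0) < 3 * se

    def test_kink_fixture_shows_outlier_mass(self):
        """Two straight arms joined at 90 deg put mass near pi/2 that a WLC lacks."""
        step = 8.0
        arm = np.column_stack([step * np.arange(10), np.zeros(10)])
        arm2 = np.column_stack(
            [np.full(9, arm[-1, 0]), step * np.arange(1, 10)]
        )
        kinked = TraceResult(
            points=np.vstack([arm, arm2]), step_nm=step, closed=False
        )
        dist = bending_angle_distribution([kinked] * 5, 8.0)
        near_kink = np.abs(dist.angles - np.pi / 2) < 0.1
        assert near_kink.sum() == 5  # one kink per copy

    def test_separation_exceeding_trace_rejected(self):
        with pytest.raises(ParameterError):
            bending_angle_distribution([straight_trace(5)], 1000.0)


class TestContourStats:
    def test_two_trace_arithmetic(self):
        t1 = straight_trace(42, 8.0)  # 41 segments -> 328 nm
        t2_pts = np.column_stack([np.linspace(0, 332, 42), np.zeros(42)])
        t2 = TraceResult(points=t2_pts, step_nm=332 / 41, closed=False)
        stats = contour_length_stats([t1, t2])
        assert stats.mean_nm == pytest.approx(330.0)
        assert stats.sd_nm == pytest.approx(2 * np.sqrt(2), rel=1e-6)

    def test_percent_change_reported_value(self):
        change = percent_change(347.0, 328.0)
        assert change == pytest.approx(5.79, abs=0.01)
        assert round(change) == 6

    def test_needs_two_traces(self):
        with pytest.raises(ParameterError):
            contour_length_stats([straight_trace()])


class TestBootstrap:
    def test_identical_traces_zero_width(self):
        # a gently bent molecule, repeated: every resample is the same pool
        from afmwlc.synthetic_data import sample_wlc_2d

        traces = [
            TraceResult(
                points=sample_wlc_2d(40, 8.0, 56.0, seed=7).vertices,
                step_nm=8.0,
                closed=False,
            )
        ] * 8
        lp, (lo, hi) = bootstrap_lp(traces, n_boot=20, fit_range=(8.0, 120.0), seed=0)
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_parameter_guards(self, wlc_truth_traces):
        with pytest.raises(ParameterError):
            bootstrap_lp(wlc_truth_traces[:6], n_boot=1)
        with pytest.raises(ParameterError):
            bootstrap_lp(wlc_truth_traces[:3], n_boot=20)

    def test_interval_covers_truth(self, wlc_truth_traces):
        """CI from 30-molecule resampling covers Lp=56 in most repeats."""
        hits = 0
        n_meta = 13  # 13 disjoint 30-molecule pools from the 400-trace fixture
        for m in range(n_meta):
            traces = wlc_truth_traces[30 * m : 30 * (m + 1)]
            _, (lo, hi) = bootstrap_lp(
                traces, n_boot=40, fit_range=(8.0, 120.0), seed=m
            )
            hits += lo <= 56.0 <= hi
        assert hits >= 10
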