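"""Generator correctness: WLC statistics, closure, rendering closed forms."""

import numpy as np
import pytest

from afmwlc.errors import (
    DiscretizationError,
    GeometryError,
    ParameterError,
)
from afmwlc.synthetic_data import (
    ConditionSpec,
    Polymer2D,
    RenderParams,
    make_condition_ensemble,
    generate_compact,
    generate_plectoneme,
    render_afm,
    sample_closed_wlc_2d,
    sample_wlc_2d,
)


# =============================================================================
# open chains
# =============================================================================
class TestOpenChain:
    def test_invariants_and_determinism(self):
        a = sample_wlc_2d(100, 2.0, 56.0, seed=5)
        b = sample_wlc_2d(100, 2.0, 56.0, seed=5)
        a.validate()
        np.testing.assert_array_equal(a.vertices, b.vertices)
        seg = a.segment_lengths()
        assert np.allclose(seg, 2.0, rtol=1e-12)
        assert a.true_contour == pytest.approx(200.0)

    def test_stiff_limit_is_straight(self):
        p = sample_wlc_2d(50, 8.0, 1e12, seed=1)
        end_to_end = np.linalg.norm(p.vertices[-1] - p.vertices[0])
        assert end_to_end == pytest.approx(400.0, rel=1e-6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_segments=10, seg_len=-1.0, lp=56.0),
            dict(n_segments=10, seg_len=2.0, lp=0.0),
            dict(n_segments=0, seg_len=2.0, lp=56.0),
        ],
    )
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ParameterError):
            sample_wlc_2d(seed=0, **kwargs)

    def test_discretization_guard(self):
        with pytest.raises(DiscretizationError):
            sample_wlc_2d(10, seg_len=20.0, lp=56.0, seed=0)

    def test_tangent_correlation_matches_2d_wlc(self, wlc_truth_traces):
        """Ensemble <cos theta(L)> follows exp(-L/(2 Lp)) within 3 s.e."""
        heads = np.array(
            [np.arctan2(*np.diff(t.points, axis=0).T[::-1]) for t in wlc_truth_traces]
        )
        for k in (1, 3, 5, 10, 15):
            dh = heads[:, k:] - heads[:, :-k]
            cos = np.cos(dh)
            mean = cos.mean()
            se = cos.mean(axis=1).std(ddof=1) / np.sqrt(len(cos))
            expected = np.exp(-8.0 * k / (2 * 56.0))
            assert abs(mean - expected) < 3 * se + 1e-12

    def test_bend_variance_law(self):
        """Net bending angle over L = 10 nm has variance L/Lp (3 s.e.)."""
        rng_seeds = range(3000, 3400)
        var_samples = []
        for s in rng_seeds:
            p = sample_wlc_2d(100, 2.0, 56.0, seed=s)
            h = p.headings()
            dh = h[5:] - h[:-5]  # 5 segments x 2 nm = 10 nm
            dh = (dh + np.pi) % (2 * np.pi) - np.pi
            var_samples.append((dh**2).mean())
        mean_var = np.mean(var_samples)
        se = np.std(var_samples, ddof=1) / np.sqrt(len(var_samples))
        assert abs(mean_var - 10.0 / 56.0) < 3 * se


# =============================================================================
# closed chains
# =============================================================================
class TestClosedChain:
    def test_invariants(self):
        p = sample_closed_wlc_2d(107, 8.0, 56.0, seed=4)
        p.validate()
        assert p.closed
        assert p.contour_length() == pytest.approx(856.0, rel=1e-9)
        assert p.turning_angles().sum() == pytest.approx(2 * np.pi, abs=1e-6)

    def test_stiff_limit_regular_polygon(self):
        p = sample_closed_wlc_2d(16, 2.0, 1e12, seed=0)
        th = p.turning_angles()
        assert np.allclose(th, 2 * np.pi / 16, atol=1e-9)
        assert np.allclose(p.segment_lengths(), 2.0, rtol=1e-12)

    def test_contour_exact_by_construction(self):
        for s in range(5):
            p = sample_closed_wlc_2d(107, 8.0, 56.0, seed=50 + s)
            assert p.contour_length() == pytest.approx(856.0, rel=1e-9)

    def test_determinism(self):
        a = sample_closed_wlc_2d(64, 2.0, 30.0, seed=9)
        b = sample_closed_wlc_2d(64, 2.0, 30.0, seed=9)
        np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_min_segments_guard(self):
        with pytest.raises(ParameterError):
            sample_closed_wlc_2d(8, 2.0, 56.0, seed=0)

    def test_matches_closure_rejection_oracle(self):
        """Ring sampler agrees with brute-force closure-conditioned sampling.

        Independent oracle: draw open chains with angle sums bridged to
        2*pi and keep those whose ends meet within a small tolerance
        (approximate conditioning on closure); restrict both ensembles to
        simple winding +1 rings and compare turning-angle variance and
        short-range tangent correlations.
        """
        n, seg, lp = 16, 2.0, 8.0
        rng = np.random.default_rng(77)
        sig = np.sqrt(seg / lp)
        kept = []
        while len(kept) < 400:
            th = rng.normal(0, sig, (100_000, n))
            th += (2 * np.pi - th.sum(axis=1))[:, None] / n
            h = np.cumsum(th, axis=1)
            x = seg * np.cumsum(np.cos(h), axis=1)
            y = seg * np.cumsum(np.sin(h), axis=1)
            gap = np.hypot(x[:, -1], y[:, -1])
            for i in np.nonzero(gap < 0.3)[0]:
                kept.append(
                    np.column_stack(
                        [np.concatenate([[0], x[i, :-1]]), np.concatenate([[0], y[i, :-1]])]
                    )
                )
        from shapely.geometry import LineString

        def stats(rings):
            ths, hs = [], []
            for v in rings:
                d = np.diff(np.vstack([v, v[:1]]), axis=0)
                h = np.arctan2(d[:, 1], d[:, 0])
                th = np.diff(np.concatenate([h, h[:1]]))
                th = -(((-th + np.pi) % (2 * np.pi)) - np.pi)
                if abs(th.sum() - 2 * np.pi) > 1e-6:
                    continue
                if not LineString(np.vstack([v, v[:1]])).is_simple:
                    continue
                ths.append(th)
                hs.append(h)
            ths, hs = np.array(ths), np.array(hs)
            corr = [
                np.cos(np.roll(hs, -k, axis=1) - hs).mean() for k in range(1, 4)
            ]
            return ths.var(), np.array(corr), len(ths)

        var_o, corr_o, n_o = stats(kept[:400])
        mcmc = [
            sample_closed_wlc_2d(n, seg, lp, seed=500 + i, sweeps=4000).vertices[:-1]
            for i in range(300)
        ]
        var_m, corr_m, n_m = stats(mcmc)
        assert n_o > 300 and n_m > 250
        assert abs(var_m - var_o) / var_o < 0.12
        assert np.all(np.abs(corr_m - corr_o) < 0.03)


# =============================================================================
# rendering
# =============================================================================
class TestRender:
    def test_straight_ridge_transverse_profile(self, rod_setup, noiseless_params):
        """Transverse profile is the analytic two-Gaussian convolution."""
        _, image, _, _ = rod_setup
        p = noiseless_params
        sigma_eff = np.hypot(p.ridge_sigma_nm, p.tip_sigma_nm)
        col = 256  # interior column
        profile = image.heights[:, col]
        rows = np.arange(len(profile))
        y = (rows + 0.5) * image.pixel_nm
        expected = p.blurred_peak_nm * np.exp(-((y - 511.0) ** 2) / (2 * sigma_eff**2))
        sel = np.abs(y - 511.0) < 12
        assert np.allclose(profile[sel], expected[sel], atol=0.01)

    def test_peak_height_closed_form(self, rod_setup, noiseless_params):
        _, image, _, _ = rod_setup
        assert image.heights.max() == pytest.approx(
            noiseless_params.blurred_peak_nm, rel=0.01
        )

    def test_render_determinism(self, noiseless_params):
        poly = sample_wlc_2d(100, 2.0, 56.0, seed=3)
        poly.vertices += 512 - poly.vertices.mean(axis=0)
        params = RenderParams(noise_sd_nm=0.05, background_particles=3)
        a = render_afm(poly, params, seed=8)
        b = render_afm(poly, params, seed=8)
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_empty_polymer_rejected(self, noiseless_params):
        empty = Polymer2D(np.empty((0, 2)), False, 56.0, 0.0, 0)
        with pytest.raises(ParameterError):
            render_afm(empty, noiseless_params, seed=0)

    def test_out_of_bounds_rejected(self, noiseless_params):
        pts = np.column_stack([np.linspace(-5, 100, 50), np.full(50, 100.0)])
        poly = Polymer2D(pts, False, 1e12, 105.0, 0)
        with pytest.raises(GeometryError):
            render_afm(poly, noiseless_params, seed=0)


# =============================================================================
# ensembles and morphologies
# =============================================================================
class TestEnsembles:
    def test_condition_ensemble_determinism(self):
        spec = ConditionSpec(n_molecules=2, contour_nm=200.0)
        a = make_condition_ensemble(spec, seed=6)
        b = make_condition_ensemble(spec, seed=6)
        for (pa, ia), (pb, ib) in zip(a, b):
            np.testing.assert_array_equal(pa.vertices, pb.vertices)
            np.testing.assert_array_equal(ia.heights, ib.heights)

    def test_zero_molecules_rejected(self):
        with pytest.raises(ParameterError):
            make_condition_ensemble(ConditionSpec(n_molecules=0), seed=0)

    def test_plectoneme_truth_arithmetic(self):
        truth, image = generate_plectoneme(860.0, 0.42, seed=2)
        assert truth.axis_nm == pytest.approx(361.2, rel=1e-9)
        assert image.heights.max() > 0.8  # doubled-height body

    def test_plectoneme_ratio_guard(self):
        with pytest.raises(ParameterError):
            generate_plectoneme(860.0, 0.1, seed=0)

    def test_compact_fixture_height(self):
        img = generate_compact(seed=1, params=RenderParams(noise_sd_nm=0.0))
        assert img.heights.max() == pytest.approx(1.5, rel=0.05)

    def test_write_ensemble_artifacts(self, tmp_path):
        import json

        import pandas as pd

        from afmwlc.synthetic_data import write_ensemble

        spec = ConditionSpec(n_molecules=2, contour_nm=200.0, label="demo")
        pairs = make_condition_ensemble(spec, seed=1)
        write_ensemble(tmp_path, pairs, spec, seed=1)
        assert (tmp_path / "images" / "mol_000.tif").exists()
        truth = pd.read_csv(tmp_path / "ground_truth.csv")
        assert set(truth.columns) == {"molecule_id", "x_nm", "y_nm"}
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["n_molecules"] == 2
        assert manifest["seed"] == 1
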