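"""Segmentation, elastic fit, plateau averaging, pressures, aggregation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from pomoforce.config import FeatureConfig
from pomoforce.curve_io import Curve, CurveMeta
from pomoforce.errors import PlateauError, YieldNotFoundError
from pomoforce.features import (
    ProbeGeometry,
    _LineFit,
    aggregate_curve,
    detect_rupture,
    detect_yield,
    extract_features,
    extract_table,
    fit_elastic,
    mean_plateau,
    stage2_line,
    to_pressure,
)
from pomoforce.synthetic_data import (
    generate_curve,
    simulate_batch,
    worked_example_spec,
)


def piecewise(knots, step=0.005):
    """Curve through linear knots [(deformation, force), ...]; no trimming."""
    xs = np.array([k[0] for k in knots])
    ys = np.array([k[1] for k in knots])
    d = np.arange(0.0, xs[-1] + step / 2, step)
    return Curve(d, np.interp(d, xs, ys), CurveMeta(sample_id="pw")).validate()


class TestDetectRupture:
    def test_triangular_global_max(self):
        curve = piecewise([(0, 0.5), (2.2, 45.0), (5.0, 10.0)])
        idx, fb = detect_rupture(curve)
        assert fb == pytest.approx(45.0)
        assert curve.deformation[idx] == pytest.approx(2.2)

    def test_tie_goes_to_first_index(self):
        d = np.linspace(0, 5, 100)
        f = np.full(100, 1.0)
        f[[30, 60]] = 7.0
        curve = Curve(d, f, CurveMeta(sample_id="tie")).validate()
        idx, _ = detect_rupture(curve)
        assert idx == 30


class TestDetectYield:
    def test_stage1_explicit_drop(self):
        # line up to 35 N at 1.0 mm, drop to 31.5 by 1.1 mm, rise to 45 N
        curve = piecewise([(0, 0.5), (1.0, 35.0), (1.1, 31.5),
                           (2.0, 45.0), (2.4, 20.0), (5.0, 18.0)])
        idx_rupture, _ = detect_rupture(curve)
        idx, fa, stage = detect_yield(curve, idx_rupture)
        assert stage == 1
        assert curve.deformation[idx] == pytest.approx(1.0)
        assert fa == pytest.approx(35.0)

    def test_stage2_slope_break_matches_exhaustive_scan(self):
        # strictly increasing, slope break 38 -> 10 N/mm at 1.0 mm, no drop
        step = 0.01
        d = np.arange(0.0, 3.0 + step / 2, step)
        f = np.where(d <= 1.0, 0.1 + 38 * d, 38.1 + 10 * (d - 1.0))
        curve = Curve(d, f, CurveMeta(sample_id="break")).validate()
        assert len(curve) <= 500
        idx_rupture, _ = detect_rupture(curve)
        idx, fa, stage = detect_yield(curve, idx_rupture)
        assert stage == 2
        cfg = FeatureConfig()
        slope, intercept, _, e = stage2_line(curve, idx_rupture, cfg)
        # exhaustive oracle: first i whose entire persist-long stretch is short
        expected = None
        for i in range(e, idx_rupture + 1):
            js = [j for j in range(i, idx_rupture + 1)
                  if d[j] - d[i] <= cfg.resid_persist_mm + 1e-12]
            if d[js[-1]] - d[i] < cfg.resid_persist_mm - 1e-12:
                continue
            fitted = slope * d[np.array(js)] + intercept
            if np.all(fitted > 0) and np.all(f[np.array(js)] < fitted * (1 - cfg.resid_frac)):
                expected = i
                break
        assert expected is not None
        assert idx == expected
        assert fa == pytest.approx(f[expected])
        assert curve.deformation[idx] == pytest.approx(1.0, abs=0.2)

    def test_no_yield_event_raises(self):
        d = np.linspace(0, 5, 400)
        curve = Curve(d, 0.1 + 8 * d, CurveMeta(sample_id="line")).validate()
        idx_rupture, _ = detect_rupture(curve)
        with pytest.raises(YieldNotFoundError):
            detect_yield(curve, idx_rupture)

    def test_degenerate_drop_exercises_stage2(self):
        spec = replace(worked_example_spec(), yield_drop_frac=0.0)
        raw, gt = generate_curve(spec)
        curve = raw.validate()
        idx_rupture, _ = detect_rupture(curve)
        idx, fa, stage = detect_yield(curve, idx_rupture)
        assert stage == 2
        # fires shortly after the true slope break, never before it
        assert gt.delta_yield_mm <= curve.deformation[idx] <= gt.delta_yield_mm + 0.3

    @pytest.mark.parametrize("sigma,min_ok", [(0.05, 18), (0.1, 18)])
    def test_simulated_recovery_within_2pct(self, sigma, min_ok):
        ok = 0
        for seed in range(20):
            raw, gt = generate_curve(worked_example_spec(noise_sigma_n=sigma,
                                                         seed=seed))
            fs = extract_features(raw.validate())
            if (abs(fs.Fa_n - gt.Fa_n) / gt.Fa_n <= 0.02
                    and abs(fs.Fb_n - gt.Fb_n) / gt.Fb_n <= 0.02
                    and abs(fs.Fc_n - gt.Fc_n) / gt.Fc_n <= 0.02
                    and abs(fs.Ka_n_per_mm - gt.Ka_n_per_mm) / gt.Ka_n_per_mm <= 0.02):
                ok += 1
        assert ok >= min_ok


class TestFitElastic:
    def test_exact_line_full_curve(self):
        d = np.linspace(0, 3, 200)
        curve = Curve(d, 2.0 + 5.0 * d, CurveMeta(sample_id="line")).validate()
        slope, intercept, r2, start = fit_elastic(curve, len(curve) - 1)
        assert start == 0
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(5.0, abs=1e-9)
        assert intercept == pytest.approx(2.0, abs=1e-9)

    def test_three_point_identity_line(self):
        fit = _LineFit(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        slope, intercept, r2, _ = fit.fit(0, 2)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_tangent_contact_prefix_does_not_bias_fit(self, b32_s9):
        # the contact segment is slope-continuous with the elastic line, the
        # hardest case for window selection; coefficients must still be exact
        curve, gt = b32_s9
        idx_rupture, _ = detect_rupture(curve)
        idx_yield, _, _ = detect_yield(curve, idx_rupture)
        slope, intercept, r2, start = fit_elastic(curve, idx_yield)
        assert slope == pytest.approx(38.0, abs=1e-9)
        assert intercept == pytest.approx(-3.1, abs=1e-9)
        assert start > 0  # contact prefix excluded


class TestMeanPlateau:
    def test_constant_segment(self):
        curve = piecewise([(0, 0.5), (0.5, 30.0), (1.0, 20.0), (5.0, 20.0)])
        idx_rupture, _ = detect_rupture(curve)
        assert mean_plateau(curve, idx_rupture) == pytest.approx(20.0)

    def test_linear_decline_mean_is_midpoint(self):
        step = 0.01
        d = np.arange(0.0, 5.0 + step / 2, step)
        f = np.where(d <= 0.5, 0.5 + 59 * d,
                     np.where(d <= 1.5, 30 - 10 * (d - 0.5),
                              20 - (10 / 3.5) * (d - 1.5)))
        curve = Curve(d, f, CurveMeta(sample_id="decl")).validate()
        idx_rupture, _ = detect_rupture(curve)
        assert curve.deformation[idx_rupture] == pytest.approx(0.5)
        # window [1.5, 5.0]: force falls linearly 20 -> 10 on a uniform grid
        assert mean_plateau(curve, idx_rupture) == pytest.approx(15.0)

    def test_rupture_too_close_to_end(self):
        curve = piecewise([(0, 0.5), (4.5, 45.0), (5.0, 20.0)])
        idx_rupture, _ = detect_rupture(curve)
        with pytest.raises(PlateauError):
            mean_plateau(curve, idx_rupture)


class TestPressure:
    def test_probe_area_force_gives_unit_pressure(self):
        probe = ProbeGeometry(8.1)
        assert probe.area_mm2 == pytest.approx(51.5300, abs=5e-5)
        assert to_pressure(probe.area_mm2, probe) == pytest.approx(1.0)
        assert to_pressure(0.0, probe) == 0.0

    def test_pressure_scales_inverse_square_of_diameter(self):
        f = 40.0
        p1 = to_pressure(f, ProbeGeometry(8.1))
        p2 = to_pressure(f, ProbeGeometry(16.2))
        assert p2 == pytest.approx(p1 / 4.0)


class TestExtractFeatures:
    def test_worked_example_matches_ground_truth(self, b32_s9):
        curve, gt = b32_s9
        fs = extract_features(curve)
        assert fs.flags == []
        assert fs.Fa_n == pytest.approx(gt.Fa_n, rel=1e-6)
        assert fs.Fb_n == pytest.approx(gt.Fb_n, rel=1e-6)
        assert fs.Fc_n == pytest.approx(gt.Fc_n, rel=1e-6)
        assert fs.Ka_n_per_mm == pytest.approx(38.0, abs=1e-3)
        assert fs.intercept_n == pytest.approx(-3.1, abs=1e-3)
        assert fs.r2_elastic >= 0.999
        assert fs.idx_lin_start <= fs.idx_yield < fs.idx_rupture

    def test_invariants_on_simulated_batch(self):
        curves, gts, _ = simulate_batch({"B32": 10, "B217": 10}, seed=42)
        for curve in curves:
            fs = extract_features(curve)
            assert 0 < fs.Fa_n <= fs.Fb_n + 1e-12
            assert 0 < fs.Kf <= 1.0
            assert fs.Pa_mpa <= fs.Pb_mpa + 1e-12
            assert fs.Pa_mpa == pytest.approx(
                fs.Fa_n / ProbeGeometry(8.1).area_mm2, rel=1e-12)

    def test_flag_bookkeeping_never_drops_samples(self):
        curves, _, _ = simulate_batch({"HL648": 4}, seed=7)
        # inject degenerate cases: a featureless line (no yield, max at end)
        # and a late-rupture curve (empty plateau window)
        d = np.linspace(0, 5, 400)
        curves.append(Curve(d, 0.1 + 8 * d, CurveMeta(sample_id="noyield")).validate())
        curves.append(piecewise([(0, 0.5), (1.0, 35.0), (1.1, 31.5),
                                 (4.5, 45.0), (5.0, 30.0)]))
        table = extract_table(curves)
        assert len(table) == 6  # every sample appears exactly once
        flags = dict(zip(table["sample_id"], table["flags"]))
        assert "yield_not_found" in flags["noyield"]
        assert "plateau_empty" in flags["pw"]
        assert all(f == "" for sid, f in flags.items()
                   if sid not in ("noyield", "pw"))
        assert np.isnan(table.set_index("sample_id").loc["noyield", "Pa_mpa"])
        assert np.isnan(table.set_index("sample_id").loc["pw", "Pc_mpa"])


class TestAggregateCurve:
    def _line_curve(self, factor):
        d = np.linspace(0, 5, 251)
        return Curve(d, factor * d, CurveMeta(sample_id=f"l{factor}")).validate()

    def test_identical_curves_zero_sd(self):
        c = self._line_curve(2.0)
        agg = aggregate_curve([c, c, c])
        np.testing.assert_allclose(agg["sd_force_n"], 0.0, atol=1e-12)
        np.testing.assert_allclose(agg["mean_force_n"], 2.0 * agg["deformation_mm"],
                                   atol=1e-12)

    def test_two_lines_closed_form_mean_and_sd(self):
        agg = aggregate_curve([self._line_curve(1.0), self._line_curve(3.0)])
        g = agg["deformation_mm"].to_numpy()
        np.testing.assert_allclose(agg["mean_force_n"], 2.0 * g, atol=1e-12)
        np.testing.assert_allclose(agg["sd_force_n"], math.sqrt(2.0) * g, atol=1e-12)

    def test_grid_endpoint_inclusive_and_short_curves_excluded(self):
        long = self._line_curve(1.0)
        d = np.linspace(0, 3, 151)
        short = Curve(d, d, CurveMeta(sample_id="short")).validate()
        agg = aggregate_curve([long, short])
        assert agg["deformation_mm"].max() == pytest.approx(5.0)
        assert (agg.loc[agg["deformation_mm"] > 3.0, "n_curves"] == 1).all()
        assert (agg.loc[agg["deformation_mm"] <= 3.0, "n_curves"] == 2).all()
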