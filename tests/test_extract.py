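"""Isolation scheme, XIC extraction, iRT calibration, and peak detection."""

import numpy as np
import pandas as pd
import pytest

from diaforge.core import Transition
from diaforge.extract import (
    AssignmentError,
    ParameterError,
    PrecursorTraces,
    assign_window,
    build_isolation_scheme,
    detect_peak_groups,
    extract_xic,
    qc_report,
)
from diaforge.irt import CalibrationError, IrtRegressor, fit_irt, predict_rt


def _transition(mz=500.0):
    return Transition("y", 5, 1, mz, 100.0)


class TestIsolationScheme:
    def test_acquisition_scheme_has_75_windows(self):
        scheme = build_isolation_scheme(390.0, 1065.0, 10.0, 0.5)
        assert len(scheme.windows) == 75
        assert all(np.isclose(hi - lo, 10.0) for lo, hi in scheme.windows)

    def test_disjoint_windows(self):
        scheme = build_isolation_scheme(400.0, 500.0, 10.0, 0.0)
        assert len(scheme.windows) == 10
        assert scheme.windows[0] == (400.0, 410.0)
        assert scheme.windows[-1] == (490.0, 500.0)

    def test_windows_tile_without_gaps(self):
        scheme = build_isolation_scheme(390.0, 1065.0, 10.0, 0.5)
        for (lo1, hi1), (lo2, hi2) in zip(scheme.windows, scheme.windows[1:]):
            assert lo2 < hi1  # overlapping edges
        assert scheme.windows[0][0] <= 390.0 and scheme.windows[-1][1] >= 1065.0

    def test_inverted_range_rejected(self):
        with pytest.raises(ParameterError):
            build_isolation_scheme(500.0, 400.0, 10.0, 0.5)

    def test_assign_nearest_center(self):
        scheme = build_isolation_scheme(390.0, 1065.0, 10.0, 0.5)
        assert assign_window(scheme, 395.0) == 0
        # shared boundary: centers 394.5 and 403.5 -> 399.0 equidistant, lower wins
        assert assign_window(scheme, 399.0) == 0

    def test_assign_out_of_range(self):
        scheme = build_isolation_scheme(390.0, 1065.0, 10.0, 0.5)
        with pytest.raises(AssignmentError):
            assign_window(scheme, 2000.0)


class TestXic:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["rt", "mz", "intensity"])

    def test_tolerance_window(self):
        t = _transition(500.0)
        table = self._table([(1.0, 500.02, 10.0), (2.0, 500.05, 20.0)])
        chrom = extract_xic(table, t)
        assert chrom.intensities.tolist() == [10.0, 0.0]

    def test_coincident_peaks_summed(self):
        t = _transition(500.0)
        table = self._table([(1.0, 499.99, 5.0), (1.0, 500.01, 7.0), (2.0, 500.0, 1.0)])
        chrom = extract_xic(table, t)
        assert chrom.intensities.tolist() == [12.0, 1.0]

    def test_extraction_linear_in_input(self):
        t = _transition(500.0)
        a = self._table([(1.0, 500.0, 3.0), (2.0, 500.0, 4.0)])
        b = self._table([(1.0, 500.01, 5.0), (2.0, 500.0, 6.0)])
        both = pd.concat([a, b], ignore_index=True)
        assert np.allclose(
            extract_xic(both, t).intensities,
            extract_xic(a, t).intensities + extract_xic(b, t).intensities,
        )


class TestIrt:
    def test_exact_line_recovered(self):
        irts = np.linspace(0, 100, 16)
        model = fit_irt([(x, 0.8 * x + 10.0) for x in irts])
        assert model.slope_ == pytest.approx(0.8, abs=1e-12)
        assert model.intercept_ == pytest.approx(10.0, abs=1e-10)
        assert model.residual_sd_ == pytest.approx(0.0, abs=1e-10)

    def test_gross_outlier_rejected(self):
        irts = np.linspace(0, 100, 16)
        pts = [(x, 0.8 * x + 10.0) for x in irts]
        pts[7] = (pts[7][0], pts[7][1] + 30.0)
        model = fit_irt(pts)
        assert model.outliers_removed_ == 1
        assert model.slope_ == pytest.approx(0.8, abs=0.01)

    def test_too_few_points(self):
        with pytest.raises(CalibrationError):
            fit_irt([(0.0, 1.0), (1.0, 2.0)])

    def test_prediction_affine(self):
        model = IrtRegressor().fit([0, 50, 100], [10.0, 50.0, 90.0])
        a, b = 20.0, 30.0
        assert predict_rt(model, a) + predict_rt(model, b) - predict_rt(model, 0.0) == (
            pytest.approx(predict_rt(model, a + b), abs=1e-9)
        )

    def test_noisy_recovery_within_three_se(self):
        """With sigma=0.1 min RT noise, slope/intercept estimates stay calibrated."""
        rng = np.random.default_rng(42)
        irts = np.linspace(0, 100, 16)
        slope_errs, intercept_errs = [], []
        for _ in range(100):
            rts = 0.8 * irts + 10.0 + rng.normal(0, 0.1, irts.size)
            m = IrtRegressor().fit(irts, rts)
            # standard errors of the simple linear regression
            sxx = np.sum((irts - irts.mean()) ** 2)
            se_slope = 0.1 / np.sqrt(sxx)
            se_int = 0.1 * np.sqrt(1 / 16 + irts.mean() ** 2 / sxx)
            slope_errs.append(abs(m.slope_ - 0.8) <= 3 * se_slope)
            intercept_errs.append(abs(m.intercept_ - 10.0) <= 3 * se_int)
        assert np.mean(slope_errs) > 0.95
        assert np.mean(intercept_errs) > 0.95


def _gaussian_traces(apexes, heights=(1000.0,), fwhm=0.3, t0=28.0, t1=36.0, dt=0.05):
    times = np.arange(t0, t1, dt)
    sigma = fwhm / 2.3548
    mat = np.vstack(
        [
            sum(h * np.exp(-0.5 * ((times - a) / sigma) ** 2) for a in apexes)
            for h in heights
        ]
    )
    return PrecursorTraces("PEP/2", "s1", times, mat, [f"y{i+3}^1" for i in range(len(heights))])


class TestPeakDetection:
    def test_single_clean_gaussian(self):
        traces = _gaussian_traces([32.0])
        groups = detect_peak_groups(traces, predicted_rt=32.0)
        assert len(groups) >= 1
        assert abs(groups[0].rt_apex - 32.0) <= 0.05
        lo, hi = groups[0].boundaries
        assert lo < groups[0].rt_apex < hi
        assert groups[0].fwhm == pytest.approx(0.3, abs=0.1)

    def test_two_separated_gaussians(self):
        traces = _gaussian_traces([31.0, 33.0])
        groups = detect_peak_groups(traces, predicted_rt=32.0)
        apexes = sorted(g.rt_apex for g in groups[:2])
        assert abs(apexes[0] - 31.0) <= 0.1 and abs(apexes[1] - 33.0) <= 0.1

    def test_flat_baseline_no_candidates(self):
        times = np.arange(28.0, 36.0, 0.05)
        traces = PrecursorTraces("PEP/2", "s1", times, np.full((1, times.size), 5.0), ["y3^1"])
        assert detect_peak_groups(traces, predicted_rt=32.0) == []

    def test_areas_invariant_to_time_shift(self):
        a = _gaussian_traces([32.0])
        b = _gaussian_traces([32.0])
        b.times = b.times + 100.0
        ga = detect_peak_groups(a, 32.0)[0]
        gb = detect_peak_groups(b, 132.0)[0]
        assert np.allclose(ga.areas, gb.areas, rtol=1e-9)

    def test_candidate_outside_window_ignored(self):
        traces = _gaussian_traces([35.5])
        assert detect_peak_groups(traces, predicted_rt=30.0, rt_window=3.0) == []


class TestQcReport:
    def test_ppm_errors_zero_for_exact_mzs(self):
        obs = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "transition": ["a", "b"],
                "observed_mz": [500.0, 600.0],
                "theoretical_mz": [500.0, 600.0],
            }
        )
        irt_obs = pd.DataFrame({"sample_id": ["s1"] * 3, "irt": [0, 50, 100],
                                "observed_rt": [10.0, 50.0, 90.0]})
        model = IrtRegressor().fit([0, 50, 100], [10.0, 50.0, 90.0])
        rep = qc_report(obs, irt_obs, {"s1": model})
        assert np.allclose(rep.ppm_errors["ppm"], 0.0)
        assert np.allclose(rep.irt_deviations["deviation"], 0.0, atol=1e-9)

    def test_ppm_error_definition(self):
        obs = pd.DataFrame(
            {
                "sample_id": ["s1"],
                "transition": ["a"],
                "observed_mz": [500.0 * (1 + 10e-6)],
                "theoretical_mz": [500.0],
            }
        )
        irt_obs = pd.DataFrame({"sample_id": [], "irt": [], "observed_rt": []})
        rep = qc_report(obs, irt_obs, {})
        assert rep.ppm_errors["ppm"].iloc[0] == pytest.approx(10.0, abs=1e-6)
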