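"""Accuracy statistics: brute-force oracle agreement, algebraic
identities, distribution summaries and the framing-error curve."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dendrocam as dc
from dendrocam.metrics import frame_error_curve, error_distribution, write_report


def brute_force_stats(measured, reference):
    """Independent scalar-loop implementation of the six statistics."""
    n = len(measured)
    abs_re = [abs(x - r) / r * 100 for x, r in zip(measured, reference)]
    ave_re = sum(abs_re) / n
    bias = sum(x - r for x, r in zip(measured, reference)) / n
    rel_bias = sum(x / r - 1 for x, r in zip(measured, reference)) / n * 100
    rmse = math.sqrt(sum((x - r) ** 2 for x, r in zip(measured, reference)) / n)
    rel_rmse = (
        math.sqrt(sum((x / r - 1) ** 2 for x, r in zip(measured, reference)) / n)
        * 100
    )
    return ave_re, bias, rel_bias, rmse, rel_rmse


class TestAbsRelativeError:
    def test_scalar(self):
        assert dc.abs_relative_error(103.0, 100.0) == pytest.approx(3.0, abs=1e-12)
        assert dc.abs_relative_error(100.0, 100.0) == 0.0

    def test_vector_mean_equals_ave_re(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(50, 300, 40)
        r = rng.uniform(50, 300, 40)
        pm = dc.PairedMeasurements(x, r)
        assert dc.abs_relative_error(x, r).mean() == pytest.approx(
            dc.summary_metrics(pm).ave_re, abs=1e-12
        )

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            dc.abs_relative_error(10.0, 0.0)


class TestSummaryMetrics:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(40, 320, 10)
        r = rng.uniform(40, 320, 10)
        rep = dc.summary_metrics(dc.PairedMeasurements(x, r))
        ave_re, bias, rel_bias, rmse, rel_rmse = brute_force_stats(x, r)
        assert rep.ave_re == pytest.approx(ave_re, abs=1e-12)
        assert rep.bias == pytest.approx(bias, abs=1e-12)
        assert rep.rel_bias == pytest.approx(rel_bias, abs=1e-12)
        assert rep.rmse == pytest.approx(rmse, abs=1e-12)
        assert rep.rel_rmse == pytest.approx(rel_rmse, abs=1e-12)

    def test_constant_offset(self):
        r = np.array([100.0, 200.0, 300.0])
        rep = dc.summary_metrics(dc.PairedMeasurements(r + 2.0, r))
        assert rep.bias == pytest.approx(2.0, abs=1e-12)
        assert rep.rmse == pytest.approx(2.0, abs=1e-12)

    def test_perfect_agreement_degenerate_protocol(self):
        r = np.array([100.0, 200.0, 300.0])
        rep = dc.summary_metrics(dc.PairedMeasurements(r.copy(), r))
        assert rep.bias == 0.0 and rep.rmse == 0.0 and rep.ave_re == 0.0
        # identical series: correlation is well-defined (slope 1) but the
        # paired t-test is degenerate
        assert rep.slope == pytest.approx(1.0, abs=1e-12)
        assert rep.t_test_p_paired == 1.0

    def test_constant_series_reports_nan_protocol(self):
        rep = dc.summary_metrics(
            dc.PairedMeasurements(np.full(5, 101.0), np.full(5, 100.0))
        )
        assert math.isnan(rep.pearson_r)
        assert rep.bias == pytest.approx(1.0, abs=1e-12)

    def test_rmse_identity(self):
        """RMSE^2 = BIAS^2 + Var(x - x_ref), population convention."""
        rng = np.random.default_rng(3)
        x = rng.uniform(50, 300, 25)
        r = rng.uniform(50, 300, 25)
        rep = dc.summary_metrics(dc.PairedMeasurements(x, r))
        var = np.var(x - r)  # divide-by-n
        assert rep.rmse**2 == pytest.approx(rep.bias**2 + var, rel=1e-12)
        assert rep.rmse >= abs(rep.bias)

    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.01, 100.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_equivariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        x = rng.uniform(50, 300, 12)
        r = rng.uniform(50, 300, 12)
        a = dc.summary_metrics(dc.PairedMeasurements(x, r))
        b = dc.summary_metrics(dc.PairedMeasurements(scale * x, scale * r))
        assert b.ave_re == pytest.approx(a.ave_re, rel=1e-9)
        assert b.rel_bias == pytest.approx(a.rel_bias, rel=1e-9)
        assert b.rel_rmse == pytest.approx(a.rel_rmse, rel=1e-9)
        assert b.pearson_r == pytest.approx(a.pearson_r, rel=1e-9)
        assert b.bias == pytest.approx(scale * a.bias, rel=1e-9)
        assert b.rmse == pytest.approx(scale * a.rmse, rel=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            dc.PairedMeasurements(np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            dc.PairedMeasurements(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            dc.PairedMeasurements(np.array([1.0]), np.array([0.0]))

    def test_agreement_protocol_on_near_identical_series(self):
        rng = np.random.default_rng(8)
        r = rng.uniform(50, 300, 60)
        x = r + rng.normal(0, 2.0, 60)
        rep = dc.summary_metrics(dc.PairedMeasurements(x, r))
        assert rep.pearson_r > 0.99
        assert rep.t_test_p > 0.5  # no detectable mean difference
        assert rep.slope == pytest.approx(1.0, abs=0.05)

    def test_summary_table_renders(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(50, 300, 10)
        rep = dc.summary_metrics(dc.PairedMeasurements(r * 1.01, r))
        text = rep.summary()
        for token in ("aveRE", "BIAS", "relRMSE", "Pearson"):
            assert token in text


class TestErrorDistribution:
    def test_all_zero(self):
        r = np.array([100.0, 200.0])
        d = error_distribution(dc.PairedMeasurements(r.copy(), r))
        assert d["min"] == d["max"] == d["mean"] == d["median"] == 0.0

    def test_strict_threshold_convention(self):
        # absRE values exactly [1, 2, 3, 4] %: strictly-below 3 -> 0.5
        r = np.full(4, 100.0)
        x = np.array([101.0, 102.0, 103.0, 104.0])
        d = error_distribution(dc.PairedMeasurements(x, r), thresholds=(3.0,))
        assert d["fraction_below"][3.0] == 0.5

    def test_mean_equals_ave_re(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(50, 300, 30)
        r = rng.uniform(50, 300, 30)
        pm = dc.PairedMeasurements(x, r)
        assert error_distribution(pm)["mean"] == pytest.approx(
            dc.summary_metrics(pm).ave_re, abs=1e-12
        )


class TestFrameErrorCurve:
    def test_flat_curve(self):
        results = [(f, 2.0) for f in np.linspace(5, 95, 19)]
        curve = frame_error_curve(results)
        assert np.allclose(curve["mean_absRE_percent"], 2.0)

    def test_u_shape_argmin_recovered(self):
        # error lowest in the 50-60 % bin by construction
        results = [(f, abs(f - 55.0) / 10 + 0.5) for f in np.linspace(5, 95, 46)]
        curve = frame_error_curve(results)
        best = curve.loc[curve["mean_absRE_percent"].idxmin(), "bin_center_percent"]
        assert best == 55.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            frame_error_curve([])


class TestCsvReproduction:
    def test_bitwise_stats_from_user_csv(self, tmp_path):
        """Any user-supplied paired CSV reproduces hand-computed statistics
        exactly (the path used for non-deposited field campaigns)."""
        measured = [98.4, 151.2, 203.9, 247.1, 305.6, 52.0]
        reference = [100.0, 150.0, 200.0, 250.0, 300.0, 50.0]
        p = tmp_path / "field.csv"
        pd.DataFrame({"measured": measured, "reference": reference}).to_csv(
            p, index=False
        )
        pm = dc.PairedMeasurements.from_csv(p)
        rep = dc.summary_metrics(pm)
        ave_re, bias, rel_bias, rmse, rel_rmse = brute_force_stats(
            measured, reference
        )
        assert rep.ave_re == ave_re
        assert rep.bias == bias
        assert rep.rmse == rmse
        assert rep.rel_bias == pytest.approx(rel_bias, abs=1e-13)
        assert rep.rel_rmse == pytest.approx(rel_rmse, abs=1e-13)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1.0]}).to_csv(p, index=False)
        with pytest.raises(ValueError):
            dc.PairedMeasurements.from_csv(p)


def test_write_report_outputs(tmp_path):
    rng = np.random.default_rng(5)
    r = rng.uniform(50, 300, 15)
    pm = dc.PairedMeasurements(r * 1.02, r)
    rep = dc.summary_metrics(pm)
    write_report(pm, rep, tmp_path, stem="t", plots=True)
    assert (tmp_path / "t_pairs.csv").exists()
    assert (tmp_path / "t_summary.json").exists()
    assert (tmp_path / "t_plots.png").exists()
    df = pd.read_csv(tmp_path / "t_pairs.csv")
    assert len(df) == 15
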