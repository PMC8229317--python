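"""Forest-inventory measurement accuracy statistics.

For measured values :math:`x_i` against references :math:`x_{ir}`,
``i = 1..n``, the module computes the six standard printed statistics

.. math::

    absRE_i &= |x_i - x_{ir}| / x_{ir} \\times 100 \\\\
    aveRE   &= \\tfrac1n \\sum_i absRE_i \\\\
    BIAS    &= \\tfrac1n \\sum_i (x_i - x_{ir}) \\\\
    relBIAS &= \\tfrac1n \\sum_i (x_i/x_{ir} - 1) \\times 100 \\\\
    RMSE    &= \\sqrt{\\tfrac1n \\sum_i (x_i - x_{ir})^2} \\\\
    relRMSE &= \\sqrt{\\tfrac1n \\sum_i (x_i/x_{ir} - 1)^2} \\times 100

(population, divide-by-n conventions throughout, so the identity
``RMSE^2 = BIAS^2 + Var(x - x_ref)`` holds exactly), plus the agreement
protocol: two-tailed Pearson correlation, the two-sided
independent-samples t-test between the measured and reference series
(a paired variant is available but is not the default), and the
ordinary-least-squares regression of measured on reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "MetricsReport",
    "abs_relative_error",
    "summary_metrics",
    "error_distribution",
    "frame_error_curve",
    "write_report",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Measured vs reference values (mm), aligned pairwise."""

    measured: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.measured, dtype=np.float64)
        r = np.asarray(self.reference, dtype=np.float64)
        if x.ndim != 1 or r.ndim != 1 or x.size != r.size:
            raise ValueError(
                f"measured and reference must be equal-length 1-D, got "
                f"{x.shape} vs {r.shape}"
            )
        if x.size < 1:
            raise ValueError("need at least one measurement pair")
        if np.any(r <= 0):
            raise ValueError("reference values must be strictly positive")
        object.__setattr__(self, "measured", x)
        object.__setattr__(self, "reference", r)

    @property
    def n(self) -> int:
        return self.measured.size

    @classmethod
    def from_csv(
        cls,
        path: Union[str, Path],
        measured_column: str = "measured",
        reference_column: str = "reference",
    ) -> "PairedMeasurements":
        """Load pairs from a CSV with measured/reference columns."""
        df = pd.read_csv(path)
        for col in (measured_column, reference_column):
            if col not in df.columns:
                raise ValueError(f"column {col!r} not found in {path}")
        return cls(df[measured_column].to_numpy(), df[reference_column].to_numpy())


def abs_relative_error(x, x_ref):
    """Absolute relative error in percent; vectorised."""
    x = np.asarray(x, dtype=np.float64)
    x_ref = np.asarray(x_ref, dtype=np.float64)
    if np.any(x_ref <= 0):
        raise ValueError("reference values must be strictly positive")
    out = np.abs(x - x_ref) / x_ref * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MetricsReport:
    """The printed accuracy statistics plus the agreement protocol."""

    n: int
    abs_re: np.ndarray  # per-pair absRE (%)
    ave_re: float  # %
    bias: float  # mm
    rel_bias: float  # %
    rmse: float  # mm
    rel_rmse: float  # %
    pearson_r: float
    pearson_p: float
    t_statistic: float
    t_test_p: float
    t_test_p_paired: float
    slope: float
    intercept: float

    def summary(self) -> str:
        """Human-readable accuracy table."""
        rows = [
            ("n", f"{self.n}"),
            ("aveRE (%)", f"{self.ave_re:.4g}"),
            ("BIAS (mm)", f"{self.bias:.4g}"),
            ("relBIAS (%)", f"{self.rel_bias:.4g}"),
            ("RMSE (mm)", f"{self.rmse:.4g}"),
            ("relRMSE (%)", f"{self.rel_rmse:.4g}"),
            ("Pearson r", f"{self.pearson_r:.4g} (p={self.pearson_p:.3g})"),
            ("t-test p (independent)", f"{self.t_test_p:.4g}"),
            ("t-test p (paired)", f"{self.t_test_p_paired:.4g}"),
            ("regression", f"measured = {self.slope:.5g} x ref + {self.intercept:.4g}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Measurement accuracy", "=" * 42]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "aveRE_percent": self.ave_re,
            "BIAS_mm": self.bias,
            "relBIAS_percent": self.rel_bias,
            "RMSE_mm": self.rmse,
            "relRMSE_percent": self.rel_rmse,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "t_statistic": self.t_statistic,
            "t_test_p": self.t_test_p,
            "t_test_p_paired": self.t_test_p_paired,
            "slope": self.slope,
            "intercept": self.intercept,
        }


def summary_metrics(pm: PairedMeasurements) -> MetricsReport:
    """Compute the full accuracy report for one paired series.

    Degenerate inputs (zero variance in either series) yield NaN for the
    correlation/t-test/regression entries rather than an error.
    """
    x, r = pm.measured, pm.reference
    n = pm.n
    diff = x - r
    rel = x / r - 1.0
    abs_re = np.abs(diff) / r * 100.0
    ave_re = float(abs_re.mean())
    bias = float(diff.mean())
    rel_bias = float(rel.mean() * 100.0)
    rmse = float(np.sqrt(np.mean(diff**2)))
    rel_rmse = float(np.sqrt(np.mean(rel**2)) * 100.0)

    degenerate = n < 2 or np.ptp(x) == 0 or np.ptp(r) == 0
    if degenerate:
        pearson_r = pearson_p = slope = intercept = float("nan")
        t_stat = t_p = t_p_paired = float("nan")
        if n >= 2 and np.ptp(r) > 0:
            reg = stats.linregress(r, x)
            slope, intercept = float(reg.slope), float(reg.intercept)
    else:
        pr = stats.pearsonr(x, r)
        pearson_r, pearson_p = float(pr.statistic), float(pr.pvalue)
        tt = stats.ttest_ind(x, r)
        t_stat, t_p = float(tt.statistic), float(tt.pvalue)
        if np.ptp(diff) == 0:
            t_p_paired = 1.0 if np.all(diff == 0) else 0.0
        else:
            t_p_paired = float(stats.ttest_rel(x, r).pvalue)
        reg = stats.linregress(r, x)
        slope, intercept = float(reg.slope), float(reg.intercept)

    return MetricsReport(
        n=n,
        abs_re=abs_re,
        ave_re=ave_re,
        bias=bias,
        rel_bias=rel_bias,
        rmse=rmse,
        rel_rmse=rel_rmse,
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        t_statistic=t_stat,
        t_test_p=t_p,
        t_test_p_paired=t_p_paired,
        slope=slope,
        intercept=intercept,
    )


def error_distribution(
    pm: PairedMeasurements,
    thresholds: Sequence[float] = (3.0, 5.0),
    bins: int = 12,
) -> dict:
    """Distribution of per-measurement absRE: min/max/mean/median, the
    fraction strictly below each threshold (percent), and a histogram."""
    abs_re = abs_relative_error(pm.measured, pm.reference)
    abs_re = np.atleast_1d(abs_re)
    counts, edges = np.histogram(abs_re, bins=bins)
    return {
        "min": float(abs_re.min()),
        "max": float(abs_re.max()),
        "mean": float(abs_re.mean()),
        "median": float(np.median(abs_re)),
        "fraction_below": {
            float(t): float(np.mean(abs_re < t)) for t in thresholds
        },
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
    }


def frame_error_curve(
    results: Sequence[Tuple[float, float]],
    bin_width: float = 10.0,
) -> pd.DataFrame:
    """Mean absRE versus trunk/frame fraction, binned.

    ``results`` holds (trunk_fraction_percent, absRE_percent) pairs; the
    returned frame has one row per occupied bin with the bin centre,
    mean absRE and count.  Used to locate the optimal viewing frame
    (error is lowest near 50-60 % occupancy on real devices).
    """
    if len(results) == 0:
        raise ValueError("no results to bin")
    arr = np.asarray(results, dtype=np.float64)
    fractions, errors = arr[:, 0], arr[:, 1]
    idx = np.floor(fractions / bin_width).astype(int)
    rows = []
    for b in sorted(set(idx.tolist())):
        sel = idx == b
        rows.append(
            {
                "bin_center_percent": (b + 0.5) * bin_width,
                "mean_absRE_percent": float(errors[sel].mean()),
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def write_report(
    pm: PairedMeasurements,
    report: MetricsReport,
    directory: Union[str, Path],
    stem: str = "accuracy",
    plots: bool = False,
) -> None:
    """Write per-pair errors (CSV) and the summary (JSON); optionally
    an absRE histogram and measured-vs-reference scatter (PNG)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "measured_mm": pm.measured,
            "reference_mm": pm.reference,
            "error_mm": pm.measured - pm.reference,
            "absRE_percent": report.abs_re,
        }
    ).to_csv(directory / f"{stem}_pairs.csv", index=False)
    (directory / f"{stem}_summary.json").write_text(
        json.dumps(report.to_dict(), indent=2)
    )
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        axes[0].hist(report.abs_re, bins=15, color="#4a7", edgecolor="k")
        axes[0].set_xlabel("absRE (%)")
        axes[0].set_ylabel("count")
        axes[1].scatter(pm.reference, pm.measured, s=12, alpha=0.7)
        lims = [0, max(pm.reference.max(), pm.measured.max()) * 1.05]
        axes[1].plot(lims, lims, "k--", lw=1)
        if np.isfinite(report.slope):
            xs = np.linspace(*lims, 50)
            axes[1].plot(xs, report.slope * xs + report.intercept, "r-", lw=1)
        axes[1].set_xlabel("reference (mm)")
        axes[1].set_ylabel("measured (mm)")
        fig.tight_layout()
        fig.savefig(directory / f"{stem}_plots.png", dpi=120)
        plt.close(fig)
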