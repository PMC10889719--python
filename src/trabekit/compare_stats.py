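"""Method-comparison statistics for paired prism measurements.

Given matched per-prism values of a morphometric parameter measured by two
methods (microCT vs. reconstructed histology), this module computes Spearman
rank correlation with its significance, a Bland–Altman analysis (bias, 95%
limits of agreement, normality of the differences, one-sample t-test for zero
bias, regression of differences on means for zero slope), and the mountain
(folded empirical CDF) plot of the differences.

Difference orientation is ``histology − microCT`` (method B − method A) by
default and configurable.  No multiple-testing correction is applied;
p < 0.05 is flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05

#: the five parameters for which the agreement plots are typically drawn
DEFAULT_PARAMETERS = ["BV/TV", "BS/TV", "Tb.Pf", "Tb.Th", "Tb.Sp"]


@dataclass
class PairedMeasurements:
    """Matched per-prism values of one parameter from two methods."""

    parameter: str
    x: np.ndarray  # method A (microCT)
    y: np.ndarray  # method B (histology)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1D arrays of equal length")
        if self.x.size < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite values in paired measurements")

    @property
    def n(self) -> int:
        return self.x.size


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value.

    The p-value uses the t approximation ``t = rho * sqrt((n-2)/(1-rho^2))``.
    Constant input has no defined rank correlation and returns ``(nan, nan)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class BlandAltman:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    normality_stat: float
    normality_p: float
    t_stat: float
    t_p: float
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    slope_p: float
    degenerate: bool = False
    means: np.ndarray = field(default=None, repr=False)
    diffs: np.ndarray = field(default=None, repr=False)


def bland_altman(x, y, orientation: str = "b-minus-a") -> BlandAltman:
    """Bland–Altman agreement analysis of paired measurements.

    Differences ``d = y - x`` (or ``x - y`` with ``orientation="a-minus-b"``)
    are plotted against the pair means; the bias is ``mean(d)`` and the 95%
    limits of agreement are ``bias ± 1.96 sd(d)``.  Accompanying tests: the
    D'Agostino–Pearson omnibus normality test of d, a one-sample t-test of d
    against zero, and OLS of d on the means to test for zero slope.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if orientation == "b-minus-a":
        d = y - x
    elif orientation == "a-minus-b":
        d = x - y
    else:
        raise ValueError("orientation must be 'b-minus-a' or 'a-minus-b'")
    m = (x + y) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    nan = float("nan")
    if sd == 0:
        return BlandAltman(
            bias=bias, sd=0.0, loa_low=bias, loa_high=bias,
            normality_stat=nan, normality_p=nan, t_stat=nan, t_p=nan,
            slope=0.0, slope_se=nan, intercept=bias, intercept_se=nan,
            slope_p=nan, degenerate=True, means=m, diffs=d,
        )
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    try:
        nstat, np_ = stats.normaltest(d)
    except ValueError:  # n too small for the omnibus test
        nstat, np_ = nan, nan
    t_stat, t_p = stats.ttest_1samp(d, 0.0)
    if np.ptp(m) == 0:
        slope, slope_se, slope_p = 0.0, nan, nan
        intercept, intercept_se = bias, nan
    else:
        reg = stats.linregress(m, d)
        slope, slope_se, slope_p = reg.slope, reg.stderr, reg.pvalue
        intercept, intercept_se = reg.intercept, reg.intercept_stderr
    return BlandAltman(
        bias=bias, sd=sd, loa_low=float(loa_low), loa_high=float(loa_high),
        normality_stat=float(nstat), normality_p=float(np_),
        t_stat=float(t_stat), t_p=float(t_p),
        slope=float(slope), slope_se=float(slope_se),
        intercept=float(intercept), intercept_se=float(intercept_se),
        slope_p=float(slope_p), means=m, diffs=d,
    )


@dataclass
class MountainCurve:
    sorted_diffs: np.ndarray
    folded: np.ndarray
    median: float
    interval_95: tuple[float, float]


def mountain_plot(d) -> MountainCurve:
    """Folded empirical CDF ("mountain") of paired differences.

    The ECDF value p_i at each sorted difference is folded at the median:
    the plotted value is ``p_i`` where ``p_i <= 0.5`` and ``1 - p_i`` above,
    so the curve peaks at 0.5 at the median.  The central 95% interval comes
    from the 2.5th/97.5th percentiles.
    """
    d = np.sort(np.asarray(d, dtype=float))
    if d.size < 3:
        raise ValueError("need at least 3 differences")
    n = d.size
    p = np.arange(1, n + 1) / n
    folded = np.where(p <= 0.5, p, 1.0 - p)
    return MountainCurve(
        sorted_diffs=d,
        folded=folded,
        median=float(np.median(d)),
        interval_95=(float(np.percentile(d, 2.5)), float(np.percentile(d, 97.5))),
    )


@dataclass
class AgreementReport:
    """Per-parameter agreement record: correlation, Bland–Altman, mountain."""

    parameter: str
    n: int
    rho: float
    rho_p: float
    ba: BlandAltman
    mountain: MountainCurve

    @property
    def significant(self) -> bool:
        return self.rho_p < ALPHA

    def to_row(self) -> dict:
        return {
            "Parameter": self.parameter,
            "n": self.n,
            "Normality Statistic": self.ba.normality_stat,
            "Normality p": self.ba.normality_p,
            "t-Test Statistic": self.ba.t_stat,
            "t-Test p": self.ba.t_p,
            "Slope": self.ba.slope,
            "Slope SE": self.ba.slope_se,
            "Intercept": self.ba.intercept,
            "Intercept SE": self.ba.intercept_se,
            "Slope p": self.ba.slope_p,
            "Bias": self.ba.bias,
            "LoA low": self.ba.loa_low,
            "LoA high": self.ba.loa_high,
            "Spearman rho": self.rho,
            "Spearman p": self.rho_p,
        }


def compare_parameter(pm: PairedMeasurements, orientation: str = "b-minus-a") -> AgreementReport:
    rho, p = spearman(pm.x, pm.y)
    ba = bland_altman(pm.x, pm.y, orientation=orientation)
    mc = mountain_plot(ba.diffs)
    return AgreementReport(parameter=pm.parameter, n=pm.n, rho=rho, rho_p=p, ba=ba, mountain=mc)


def build_agreement_report(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    parameters: list[str] | None = None,
    orientation: str = "b-minus-a",
    key: str = "prism_id",
) -> tuple[pd.DataFrame, list[AgreementReport]]:
    """Compare two per-prism morphometry tables parameter by parameter.

    Tables must share prism IDs exactly; unmatched IDs raise with the list of
    offenders.  Returns the summary table (one row per parameter, with the
    normality / t-test / regression / Spearman columns) and the full reports.
    """
    parameters = list(parameters) if parameters is not None else list(DEFAULT_PARAMETERS)
    ids_a, ids_b = set(table_a[key]), set(table_b[key])
    if ids_a != ids_b:
        missing = sorted(ids_a.symmetric_difference(ids_b))
        raise ValueError(f"unmatched prism IDs between tables: {missing}")
    a = table_a.set_index(key).sort_index()
    b = table_b.set_index(key).sort_index()
    reports = []
    for param in parameters:
        pm = PairedMeasurements(
            parameter=param,
            x=a[param].to_numpy(),
            y=b[param].to_numpy(),
        )
        reports.append(compare_parameter(pm, orientation=orientation))
    table = pd.DataFrame([r.to_row() for r in reports])
    return table, reports


# ------------------------------------------------------------------ plotting
def plot_agreement(report: AgreementReport, out_path=None):
    """Bland–Altman (left) and mountain (right) panels for one parameter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ba = report.ba
    ax1.scatter(ba.means, ba.diffs, s=12, alpha=0.8)
    ax1.axhline(ba.bias, color="k", label=f"bias {ba.bias:.3g}")
    ax1.axhline(ba.loa_low, color="k", ls="--")
    ax1.axhline(ba.loa_high, color="k", ls="--")
    if np.isfinite(ba.slope_se):
        xs = np.linspace(ba.means.min(), ba.means.max(), 50)
        ax1.plot(xs, ba.intercept + ba.slope * xs, "k:", lw=1)
    ax1.set_xlabel("mean of methods")
    ax1.set_ylabel("difference")
    ax1.set_title(f"{report.parameter} Bland-Altman")
    mc = report.mountain
    ax2.plot(mc.sorted_diffs, mc.folded, "-o", ms=2)
    ax2.axvline(mc.median, color="k")
    for v in mc.interval_95:
        ax2.axvline(v, color="k", ls="--")
    ax2.set_xlabel("difference")
    ax2.set_ylabel("folded percentile")
    ax2.set_title(f"{report.parameter} mountain")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
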