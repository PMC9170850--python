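"""Agreement and repeatability statistics for paired uptake measurements.

The battery used to compare two quantification methods, or two observers:
Pearson correlation, intraclass correlation (two-way model, consistency
definition, single measurement — ICC(C,1)), Bland-Altman bias and 95% limits
of agreement (absolute and as pairwise percentage differences), and the
coefficient of repeatability.

ICC reliability is banded as poor (< 0.5), moderate ([0.5, 0.75)),
good ([0.75, 0.9)) and excellent (>= 0.9); the cut-points are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

Z_95 = 1.96  # normal quantile behind the 95% limits of agreement


@dataclass(frozen=True)
class PairedMeasurements:
    """Matched per-subject values from two methods (or observers)."""

    subjects: tuple
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        subjects = tuple(self.subjects)
        if not (len(subjects) == a.size == b.size):
            raise ValueError("subjects, a and b must have equal length")
        if a.size < 3:
            raise ValueError("need at least 3 paired measurements")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired measurements must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "subjects", subjects)

    @property
    def n(self) -> int:
        return self.a.size

    @property
    def differences(self) -> np.ndarray:
        return self.b - self.a

    @property
    def percent_differences(self) -> np.ndarray:
        denom = (self.a + self.b) / 2.0
        if np.any(denom == 0):
            raise ValueError("pairwise mean of zero: percentage differences undefined")
        return 100.0 * (self.b - self.a) / denom


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    band: str


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int
    percent: bool


@dataclass(frozen=True)
class AgreementReport:
    """Everything needed for a method-comparison or repeatability table."""

    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    pearson_r: float
    pearson_p: float
    icc: ICCResult
    bland_altman: BlandAltmanResult
    bland_altman_percent: BlandAltmanResult
    cr: float
    cr_percent_of_mean: float
    paired_t_p: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_a": self.mean_a,
            "sd_a": self.sd_a,
            "mean_b": self.mean_b,
            "sd_b": self.sd_b,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "icc": self.icc.estimate,
            "icc_ci95": [self.icc.ci_low, self.icc.ci_high],
            "icc_band": self.icc.band,
            "bias": self.bland_altman.bias,
            "loa": [self.bland_altman.loa_low, self.bland_altman.loa_high],
            "sd_diff": self.bland_altman.sd_diff,
            "percent_bias": self.bland_altman_percent.bias,
            "percent_loa": [
                self.bland_altman_percent.loa_low,
                self.bland_altman_percent.loa_high,
            ],
            "cr": self.cr,
            "cr_percent_of_mean": self.cr_percent_of_mean,
            "paired_t_p": self.paired_t_p,
        }


def reliability_band(icc: float) -> str:
    """Half-open reliability bands for an ICC point estimate."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def pearson_r(pairs: PairedMeasurements) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value (t, n-2 df)."""
    if np.std(pairs.a) == 0 or np.std(pairs.b) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(pairs.a, pairs.b)
    return float(res.statistic), float(res.pvalue)


def icc_consistency(matrix) -> ICCResult:
    """ICC(C,1): two-way model, consistency, single measurement, with 95% CI.

    ``matrix`` is subjects x raters, complete. The consistency estimate and
    its F-based confidence interval are identical under the two-way random
    and two-way mixed formulations.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D subjects x raters matrix with >= 2 raters")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(m)):
        raise ValueError("incomplete or non-finite rating matrix")
    n, k = m.shape
    # degenerate case: zero residual after removing subject and rater effects
    # (e.g. raters identical up to a constant shift) -> ICC(C,1) = 1 by limit
    resid = m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + m.mean()
    if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, float(np.abs(m).max()))):
        return ICCResult(1.0, 1.0, 1.0, reliability_band(1.0))
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "rating": m.ravel(),
        }
    )
    tab = pg.intraclass_corr(
        data=df, targets="subject", raters="rater", ratings="rating"
    ).set_index("Type")
    # row/column labels vary across pingouin versions
    key = "ICC(C,1)" if "ICC(C,1)" in tab.index else "ICC3"
    row = tab.loc[key]
    est = float(row["ICC"])
    ci = row["CI95"] if "CI95" in row.index else row["CI95%"]
    lo, hi = (float(v) for v in ci)
    return ICCResult(est, lo, hi, reliability_band(est))


def bland_altman(pairs: PairedMeasurements, percent: bool = False) -> BlandAltmanResult:
    """Mean bias and 95% limits of agreement of paired differences.

    Differences are b - a (or pairwise percentage differences when
    ``percent``); limits are bias +/- 1.96 * sample sd (n-1 denominator).
    """
    d = pairs.percent_differences if percent else pairs.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(bias, bias - Z_95 * sd, bias + Z_95 * sd, sd, pairs.n, percent)


def coefficient_of_repeatability(
    pairs: PairedMeasurements, form: str = "sd"
) -> tuple[float, float]:
    """Coefficient of repeatability and its value as % of the grand mean.

    ``form='sd'`` (default): CR = 1.96 * sample sd of the differences.
    ``form='anova'``: CR = 1.96 * sqrt(2) * within-subject sd from the
    paired-replicate ANOVA (sw^2 = mean(d^2) / 2), which folds a systematic
    observer offset into the repeatability rather than discounting it.
    """
    d = pairs.differences
    if form == "sd":
        cr = Z_95 * float(np.std(d, ddof=1))
    elif form == "anova":
        cr = Z_95 * float(np.sqrt(np.mean(d**2)))
    else:
        raise ValueError(f"unknown CR form {form!r}")
    grand = float(np.mean(np.concatenate([pairs.a, pairs.b])))
    if grand == 0:
        return cr, float("nan")
    return cr, 100.0 * cr / grand


def plot_bland_altman(pairs: PairedMeasurements, path, percent: bool = False) -> None:
    """Write a Bland-Altman plot: bias line and 95% limit lines over the pairs."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    res = bland_altman(pairs, percent=percent)
    mean = (pairs.a + pairs.b) / 2.0
    d = pairs.percent_differences if percent else pairs.differences
    fig = Figure(figsize=(5, 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    ax.scatter(mean, d, s=18, color="k", alpha=0.7)
    ax.axhline(res.bias, color="tab:blue", label=f"bias {res.bias:.2f}")
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="tab:red", linestyle="--")
    ax.set_xlabel("Mean of paired measurements")
    ax.set_ylabel("Percentage difference (%)" if percent else "Difference (b - a)")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def compare_methods(pairs: PairedMeasurements) -> AgreementReport:
    """Bundle the full agreement battery for one pair of measurement sets."""
    r, p = pearson_r(pairs)
    icc = icc_consistency(np.stack([pairs.a, pairs.b], axis=1))
    ba = bland_altman(pairs, percent=False)
    bap = bland_altman(pairs, percent=True)
    cr, cr_pct = coefficient_of_repeatability(pairs)
    t = stats.ttest_rel(pairs.b, pairs.a)
    return AgreementReport(
        n=pairs.n,
        mean_a=float(np.mean(pairs.a)),
        sd_a=float(np.std(pairs.a, ddof=1)),
        mean_b=float(np.mean(pairs.b)),
        sd_b=float(np.std(pairs.b, ddof=1)),
        pearson_r=r,
        pearson_p=p,
        icc=icc,
        bland_altman=ba,
        bland_altman_percent=bap,
        cr=cr,
        cr_percent_of_mean=cr_pct,
        paired_t_p=float(t.pvalue),
    )
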