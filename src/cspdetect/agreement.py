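"""Agreement statistics for method/rater comparison of CSP durations.

Implements the single-measure, absolute-agreement, two-way intraclass
correlation ICC(A,1) directly from the ANOVA mean squares, with the
McGraw-Wong F-based 95 % confidence interval, and Bland-Altman limits of
agreement (mean difference +/- 1.96 SD of the paired differences).  The
point estimate of ICC(A,1) is identical under the two-way mixed and
two-way random models; only the interpretation differs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ParameterError


@dataclass
class AgreementReport:
    """ICC with CI plus Bland-Altman limits for a two-column comparison."""

    icc: float
    ci_low: float
    ci_high: float
    model_label: str
    bland_altman: Dict[str, float]

    def to_dict(self) -> Dict:
        return dict(
            icc=self.icc,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            model_label=self.model_label,
            bland_altman=dict(self.bland_altman),
        )


def _as_matrix(values) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ParameterError("ratings must form an n_subjects x k_raters matrix")
    keep = ~np.isnan(m).any(axis=1)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} row(s) with missing cells",
            stacklevel=3,
        )
        m = m[keep]
    n, k = m.shape
    if n < 2 or k < 2:
        raise ParameterError("need at least 2 subjects and 2 raters")
    return m


def icc_a1(values, alpha: float = 0.05) -> Tuple[float, float, float]:
    """ICC(A,1): single-measure, absolute-agreement, two-way model.

    With rows = subjects and columns = raters/methods, the two-way ANOVA
    decomposition gives row, column and error mean squares (MSR, MSC,
    MSE) and::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The confidence interval follows McGraw & Wong's F-based method with a
    Satterthwaite approximation for the denominator degrees of freedom.
    Zero between-subject variance leaves the coefficient undefined and
    raises :class:`ParameterError`.
    """
    m = _as_matrix(values)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((m - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    scale = max(sst / (n * k - 1), np.finfo(float).tiny)
    if ssr / (n - 1) <= 1e-12 * scale:
        raise ParameterError(
            "zero between-subject variance: ICC is undefined for these ratings"
        )

    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    if mse == 0 and msc == 0:
        # identical raters: perfect agreement, degenerate interval
        return 1.0, 1.0, 1.0

    # McGraw & Wong (1996) CI for ICC(A,1)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return float(icc), 1.0, 1.0
    with np.errstate(all="ignore"):
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den if v_den > 0 else 1.0
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (
            n * (msr - f_l * mse)
            / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        upper = (
            n * (f_u * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        )
    lower = float(min(lower, icc)) if np.isfinite(lower) else float(icc)
    upper = float(max(upper, icc)) if np.isfinite(upper) else 1.0
    return float(icc), lower, upper


def bland_altman(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Limits of agreement between two paired measurement series.

    ``d = x - y`` elementwise; returns the mean difference, its sample SD
    (n-1 denominator) and the limits ``mean_diff +/- 1.96 sd_diff``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ParameterError("need at least 2 paired values")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return dict(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
    )


def agreement_report(
    x: Sequence[float],
    y: Sequence[float],
    labels: Tuple[str, str] = ("a", "b"),
    layout: Optional[str] = None,
) -> AgreementReport:
    """ICC(A,1) + Bland-Altman for two aligned rating series."""
    m = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    icc, lo, hi = icc_a1(m)
    label = "ICC(A,1) two-way, absolute agreement, single measure"
    if layout:
        label += f" [{layout}]"
    return AgreementReport(
        icc=icc,
        ci_low=lo,
        ci_high=hi,
        model_label=label,
        bland_altman=bland_altman(x, y),
    )
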