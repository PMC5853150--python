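"""Agreement between two per-cell quantification methods.

Validates that two ways of measuring the same black-carbon inclusions (for
example conventional 2-D light-microscopy images versus maximum-intensity
projections of 3-D femtosecond-laser z-stacks) agree: Bland-Altman limits of
agreement on natural-log areas, Spearman rank correlation with a confidence
interval, and a two-way intraclass correlation coefficient.

Per-cell BC areas span orders of magnitude and are strictly positive, so the
Bland-Altman analysis defaults to the natural-log scale, where a constant
multiplicative bias between methods appears as a constant mean difference.
Limits of agreement use mean ± 2·SD of the differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "BlandAltman",
    "AgreementReport",
    "bland_altman",
    "spearman_with_ci",
    "icc",
    "agreement_report",
]

ICC_FORM = "ICC(2,1) two-way random effects, absolute agreement, single measurement"


def _paired(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be equal-length 1-D arrays")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("pairs must be complete (no missing values)")
    return a, b


@dataclass(frozen=True)
class BlandAltman:
    n: int
    log_scale: bool
    mean_diff: float
    sd_diff: float
    limit_low: float
    limit_high: float


def bland_altman(a, b, log_scale: bool = True,
                 zero_offset: float | None = None) -> BlandAltman:
    """Bland-Altman mean difference and limits of agreement (mean ± 2·SD).

    Differences are ``log(b) - log(a)`` on the log scale (so exact
    proportionality b = c·a gives mean difference log c with zero SD).
    Zeros are only admitted on the log scale when ``zero_offset`` states the
    documented replacement value.
    """
    a, b = _paired(a, b)
    if a.size < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("areas must be non-negative")
    if log_scale:
        if ((a == 0) | (b == 0)).any():
            if zero_offset is None:
                raise ValueError(
                    "zero areas under the log scale require an explicit "
                    "zero_offset replacement value")
            a = np.where(a == 0, zero_offset, a)
            b = np.where(b == 0, zero_offset, b)
        diffs = np.log(b) - np.log(a)
    else:
        diffs = b - a
    m = float(diffs.mean())
    s = float(diffs.std(ddof=1))
    return BlandAltman(n=a.size, log_scale=log_scale, mean_diff=m, sd_diff=s,
                       limit_low=m - 2.0 * s, limit_high=m + 2.0 * s)


def spearman_with_ci(a, b, method: str = "fisher", n_boot: int = 2000,
                     seed: int | None = None) -> tuple[float, float, float]:
    """Spearman rank correlation with a 95% confidence interval.

    ``method='fisher'`` uses the z-transform approximation with variance
    1/(n-3) applied to the rank correlation (an approximation, since the
    exact variance of transformed rank correlations differs slightly);
    ``method='bootstrap'`` resamples pairs.  Ties get midranks.
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 4:
        raise ValueError("Spearman CI needs at least 4 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.spearmanr(a, b).statistic)
    if method == "fisher":
        if abs(r) >= 1.0:
            return r, r, r
        z = np.arctanh(r)
        hw = 1.959963984540054 / np.sqrt(n - 3)
        return r, float(np.tanh(z - hw)), float(np.tanh(z + hw))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        rs = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            if np.ptp(a[idx]) == 0 or np.ptp(b[idx]) == 0:
                rs[i] = np.nan
                continue
            rs[i] = stats.spearmanr(a[idx], b[idx]).statistic
        lo, hi = np.nanpercentile(rs, [2.5, 97.5])
        return r, float(lo), float(hi)
    raise ValueError("method must be 'fisher' or 'bootstrap'")


def icc(a, b, form: str = "ICC(2,1)") -> tuple[float, str]:
    """Intraclass correlation between two methods, from two-way mean squares.

    Implements ICC(2,1): two-way random effects, absolute agreement, single
    measurement —

        ICC = (MSR - MSE) / (MSR + (k-1)·MSE + k·(MSC - MSE)/n)

    with n subjects, k = 2 raters, MSR/MSC/MSE the rows/columns/error mean
    squares.  The form identifier is returned alongside the value so reports
    are auditable.
    """
    if form != "ICC(2,1)":
        raise ValueError("only ICC(2,1) is implemented")
    a, b = _paired(a, b)
    n = a.size
    if n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: zero total variance")
    return float((msr - mse) / denom), ICC_FORM


@dataclass(frozen=True)
class AgreementReport:
    """Full method-agreement report for one set of paired measurements."""

    n_pairs: int
    bland_altman: BlandAltman
    spearman_r: float
    spearman_ci: tuple[float, float]
    spearman_ci_method: str
    icc_value: float
    icc_form: str

    def to_dict(self) -> dict:
        return dict(
            n_pairs=self.n_pairs,
            bland_altman=dict(
                log_scale=self.bland_altman.log_scale,
                mean_diff=self.bland_altman.mean_diff,
                sd_diff=self.bland_altman.sd_diff,
                limits=[self.bland_altman.limit_low, self.bland_altman.limit_high],
            ),
            spearman=dict(r=self.spearman_r, ci=list(self.spearman_ci),
                          ci_method=self.spearman_ci_method),
            icc=dict(value=self.icc_value, form=self.icc_form),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def agreement_report(a, b, log_scale: bool = True,
                     spearman_method: str = "fisher",
                     zero_offset: float | None = None,
                     seed: int | None = None) -> AgreementReport:
    """Bland-Altman + Spearman + ICC in one pass over paired areas."""
    a, b = _paired(a, b)
    ba = bland_altman(a, b, log_scale=log_scale, zero_offset=zero_offset)
    r, lo, hi = spearman_with_ci(a, b, method=spearman_method, seed=seed)
    icc_val, icc_form = icc(a, b)
    return AgreementReport(
        n_pairs=a.size, bland_altman=ba, spearman_r=r, spearman_ci=(lo, hi),
        spearman_ci_method=spearman_method, icc_value=icc_val,
        icc_form=icc_form,
    )


def bland_altman_plot(a, b, log_scale: bool = True, path: str | Path | None = None,
                      zero_offset: float | None = None):
    """Bland-Altman diagram (differences vs means) with 2-SD limit lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = _paired(a, b)
    ba = bland_altman(a, b, log_scale=log_scale, zero_offset=zero_offset)
    if log_scale:
        if zero_offset is not None:
            a = np.where(a == 0, zero_offset, a)
            b = np.where(b == 0, zero_offset, b)
        xa, xb = np.log(a), np.log(b)
        xlabel = "mean of ln areas (ln μm²)"
        ylabel = "difference of ln areas"
    else:
        xa, xb = a, b
        xlabel = "mean area (μm²)"
        ylabel = "difference (μm²)"
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((xa + xb) / 2, xb - xa, s=18, alpha=0.8)
    ax.axhline(ba.mean_diff, color="green", label="mean difference")
    ax.axhline(ba.limit_low, color="black", lw=1)
    ax.axhline(ba.limit_high, color="black", lw=1, label="±2 SD")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
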