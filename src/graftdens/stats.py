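"""Agreement and comparison statistics for measurement-validation studies.

Bland–Altman limits of agreement and the intraclass correlation
coefficient are implemented from their definitions (they are the point of
the validation, and are oracle-tested); group comparison tests — paired t,
Wilcoxon signed-rank, repeated-measures ANOVA, Friedman, Spearman — are
thin wrappers around standard routines.

ICC form
--------
Intra-rater reliability of a fixed rater's repeated sessions is computed
as ICC(3,1): two-way mixed effects, consistency, single measurement,

    ICC(3,1) = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)

with MS_R the between-subject mean square and MS_E the residual mean
square of the subjects x sessions two-way model without interaction.  The
form identifier is recorded in every result.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementResult",
    "ICCResult",
    "bland_altman",
    "icc",
    "paired_compare",
    "method_compare",
    "spearman_corr",
]

LOA_MULTIPLIER = 1.96


@dataclass
class AgreementResult:
    """Bland–Altman bias and limits of agreement."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class ICCResult:
    value: float
    form: str
    n_subjects: int
    k_sessions: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def bland_altman(x, y):
    """Bland–Altman agreement of two paired measurement series.

    Differences are ``x - y``; bias is their mean, sd the sample standard
    deviation (n-1 denominator), and the limits of agreement
    ``bias +/- 1.96 sd``.  Returns ``(AgreementResult, means, diffs)``
    where the per-pair means and differences feed the usual plot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need >= 2 paired values")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    res = AgreementResult(
        bias=bias,
        sd=sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        n=x.size,
    )
    return res, (x + y) / 2.0, d


def bland_altman_csv(x, y, path):
    """Write the per-pair (mean, difference) table for external plotting."""
    import csv

    res, means, diffs = bland_altman(x, y)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mean", "diff"])
        w.writerows(zip(means, diffs))
    return res


def bland_altman_plot(x, y, ax=None):
    """Render the Bland–Altman plot (optional; needs matplotlib)."""
    import matplotlib.pyplot as plt

    res, means, diffs = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(means, diffs, s=12)
    for val, style in ((res.bias, "-"), (res.loa_lower, "--"), (res.loa_upper, "--")):
        ax.axhline(val, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    return res, ax


def icc(ratings, form: str = "ICC(3,1)") -> ICCResult:
    """Intraclass correlation of a complete subjects x sessions matrix.

    Only the two-way mixed, consistency, single-measurement form is
    offered (see module docstring).  Raises on incomplete matrices, fewer
    than two subjects or sessions, or zero total variance.
    """
    if form != "ICC(3,1)":
        raise ValueError(f"unsupported ICC form {form!r}; only ICC(3,1) is implemented")
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x sessions matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 sessions, got {n} x {k}")
    if np.isnan(m).any():
        raise ValueError("ratings matrix must be complete (no missing values)")

    grand = m.mean()
    ss_total = ((m - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("zero total variance; ICC undefined")
    ss_rows = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    value = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    return ICCResult(value=float(value), form=form, n_subjects=n, k_sessions=k)


def _as_pair(x, y, min_n):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < min_n:
        raise ValueError(f"need >= {min_n} pairs, got {x.size}")
    return x, y


def paired_compare(x, y, test: str = "paired-t"):
    """Two-sided paired comparison: ``paired-t`` or ``wilcoxon``.

    Degenerate inputs (zero-variance differences for t, all-zero
    differences for Wilcoxon) leave the statistic undefined and raise.
    """
    if test == "paired-t":
        x, y = _as_pair(x, y, 3)
        d = x - y
        if np.all(d == 0):
            return 0.0, 1.0  # identical series: no difference at all
        if d.std(ddof=1) == 0:
            raise ValueError("zero variance of paired differences; t statistic undefined")
        res = sps.ttest_rel(x, y)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon":
        x, y = _as_pair(x, y, 5)
        if np.all(x == y):
            raise ValueError("all paired differences are zero; Wilcoxon p undefined")
        res = sps.wilcoxon(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}; choose 'paired-t' or 'wilcoxon'")


def method_compare(columns, test: str = "friedman"):
    """Compare >= 3 paired samples: ``repeated-anova`` or ``friedman``.

    ``columns`` is a sequence of equal-length samples (one per method).
    The repeated-measures ANOVA F comes from the subjects x methods
    two-way mean squares (treatment MS over residual MS).
    """
    cols = [np.asarray(c, dtype=float) for c in columns]
    if len(cols) < 2:
        raise ValueError("need >= 2 columns")
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise ValueError("columns must have equal length")
    if n < 3:
        raise ValueError("need >= 3 subjects")

    if test == "friedman":
        if all(np.array_equal(cols[0], c) for c in cols[1:]):
            return 0.0, 1.0  # every row fully tied: no rank signal at all
        res = sps.friedmanchisquare(*cols)
        return float(res.statistic), float(res.pvalue)
    if test == "repeated-anova":
        m = np.column_stack(cols)
        k = m.shape[1]
        grand = m.mean()
        ss_rows = k * ((m.mean(axis=1) - grand) ** 2).sum()
        ss_cols = n * ((m.mean(axis=0) - grand) ** 2).sum()
        ss_err = ((m - grand) ** 2).sum() - ss_rows - ss_cols
        df_cols, df_err = k - 1, (n - 1) * (k - 1)
        ms_err = ss_err / df_err
        if ms_err == 0:
            raise ValueError("zero residual variance; F undefined")
        f = (ss_cols / df_cols) / ms_err
        return float(f), float(sps.f.sf(f, df_cols, df_err))
    raise ValueError(f"unknown test {test!r}; choose 'repeated-anova' or 'friedman'")


def spearman_corr(x, y):
    """Spearman rank correlation with two-sided p value."""
    x, y = _as_pair(x, y, 3)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; Spearman correlation undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
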