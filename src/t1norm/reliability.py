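"""Agreement and contrast statistics for the regional T1 measurements.

Covers the study's reliability toolkit: Bland-Altman limits of agreement
for paired measurements (left vs right homologue for intra-rater, rater
averages for inter-rater), the two-way random-effects absolute-agreement
single-measure intraclass correlation ICC(2,1), and the Wilcoxon rank-sum
contrast between structures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BRAIN_REGION_NAMES

__all__ = [
    "AgreementResult",
    "IccResult",
    "bland_altman",
    "icc_absolute",
    "wilcoxon_rank_sum",
    "structure_contrasts",
]

Z_975 = 1.959964


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman bias and 95% limits of agreement (ms)."""

    bias_ms: float
    loa_low_ms: float
    loa_high_ms: float
    n_pairs: int


@dataclass(frozen=True)
class IccResult:
    icc_value: float
    variant: str
    n_subjects: int
    n_raters: int


def bland_altman(x, y) -> AgreementResult:
    """Mean difference and bias +/- 1.96 SD limits for paired measurements."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with >= 2 pairs")
    d = x - y
    bias = float(d.mean())
    spread = Z_975 * float(d.std(ddof=1))
    return AgreementResult(bias, bias - spread, bias + spread, int(d.size))


def icc_absolute(ratings) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a complete subjects x raters table (DataFrame or 2-D
    array).  From the mean-square decomposition with n subjects, k raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("ratings table must be complete")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((m - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom != 0 else 1.0
    return IccResult(icc, "ICC(2,1) absolute agreement", n, k)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (rank-sum statistic of ``a``, p).

    The p-value comes from exact enumeration when the combined sample is
    small (m + n <= 20) and tie-free, otherwise from the normal
    approximation with midranks, tie correction and continuity correction.
    Two-sided throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    w = float(res.statistic + a.size * (a.size + 1) / 2)  # U -> rank sum
    return w, float(res.pvalue)


def structure_contrasts(per_subject: pd.DataFrame,
                        regions: tuple[str, ...] = BRAIN_REGION_NAMES) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum p-values across brain structures.

    ``per_subject`` holds one pooled mean per subject and region (columns
    subject_id, region, mean_t1_ms).  No multiplicity adjustment is applied;
    the matrix is symmetric with NaN on the diagonal.
    """
    if per_subject.subject_id.nunique() < 2:
        raise ValueError("need >= 2 subjects")
    values = {
        r: per_subject.loc[per_subject.region == r, "mean_t1_ms"].to_numpy()
        for r in regions
    }
    out = pd.DataFrame(np.nan, index=list(regions), columns=list(regions))
    for r1, r2 in itertools.combinations(regions, 2):
        _, p = wilcoxon_rank_sum(values[r1], values[r2])
        out.loc[r1, r2] = out.loc[r2, r1] = p
    return out
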