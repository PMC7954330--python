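"""Normality-gated statistical comparison protocol.

Paired samples: if the paired differences pass a Shapiro-Wilk normality
test (alpha 0.05) a paired t-test is used, otherwise the exact Wilcoxon
signed-rank test.  Unpaired samples: if both samples pass Shapiro-Wilk a
Welch two-sample t-test is used, otherwise the two-sample
Kolmogorov-Smirnov test.  Summaries are reported as mean ± SD and p < 0.05
is considered significant.

The exact Wilcoxon null distribution is computed by dynamic-programming
convolution over the (mid-)ranks — identical to enumerating all 2^n sign
assignments — for n <= 25; above that a normal approximation with
continuity and tie corrections is used.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25
DEFAULT_ALPHA = 0.05


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __str__(self):
        return f"{self.mean:.3g} ± {self.sd:.3g} (n={self.n})"


@dataclass
class ComparisonResult:
    """Two-group comparison: summaries, the gate decision and the test."""

    group_a: GroupSummary
    group_b: GroupSummary
    paired: bool
    normality_p_a: float | None
    normality_p_b: float | None
    test_used: str        # paired_t | wilcoxon_signed_rank | unpaired_t | kolmogorov_smirnov
    statistic: float
    p_value: float
    significant: bool
    alpha: float = DEFAULT_ALPHA
    n_zeros_dropped: int = 0
    degenerate: bool = False   # all paired differences were exactly zero

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _summary(x) -> GroupSummary:
    x = np.asarray(x, float)
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    return GroupSummary(mean=float(x.mean()), sd=sd, n=len(x))


def shapiro_wilk(x):
    """Shapiro-Wilk W and p (Royston approximation), 3 <= n <= 5000."""
    x = np.asarray(x, float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of the doubled signed-rank sum over all 2^n sign assignments.

    ``ranks2`` are the mid-ranks times two (integers, so ties are exact).
    Entry ``k`` of the result counts sign vectors with 2*W+ == k.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    return counts


def wilcoxon_signed_rank_exact(differences):
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Exact (full sign enumeration, mid-ranks for ties) for n <= 25 after
    dropping exact zeros; normal approximation with continuity and tie
    corrections above.  Returns ``(W, p)`` with ``W = min(W+, W-)``.
    """
    d = np.asarray(differences, float)
    nz = d != 0.0
    n_dropped = int((~nz).sum())
    if n_dropped:
        logger.info("wilcoxon: dropped %d zero difference(s)", n_dropped)
    d = d[nz]
    n = len(d)
    if n < 1:
        raise ValueError("all differences are zero: signed-rank test undefined")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w_stat = min(w_plus, w_minus)

    if n <= EXACT_WILCOXON_MAX_N:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        counts = _signed_rank_distribution(ranks2)
        total = counts.sum()   # == 2**n
        k = int(round(2.0 * w_plus))
        p_le = counts[: k + 1].sum() / total
        p_ge = counts[k:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = (n * (n + 1) * (2 * n + 1) / 24.0
               - (tie_counts ** 3 - tie_counts).sum() / 48.0)
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return w_stat, float(p)


def paired_compare(a, b, alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """Compare paired samples with the normality-gated protocol.

    The Shapiro-Wilk gate is applied to the paired differences; pass ->
    paired t-test, fail -> exact Wilcoxon signed-rank.  Identical samples
    (all differences zero) yield a flagged degenerate result with p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("paired comparison requires n >= 3")
    d = a - b
    if np.all(d == 0.0):
        return ComparisonResult(
            group_a=_summary(a), group_b=_summary(b), paired=True,
            normality_p_a=None, normality_p_b=None,
            test_used="wilcoxon_signed_rank", statistic=0.0, p_value=1.0,
            significant=False, alpha=alpha, n_zeros_dropped=len(d),
            degenerate=True)

    try:
        _, p_norm = shapiro_wilk(d)
    except ValueError:   # constant nonzero differences: clearly non-normal
        p_norm = 0.0

    if p_norm > alpha:
        res = sps.ttest_rel(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "paired_t"
        dropped = 0
    else:
        dropped = int((d == 0).sum())
        stat, p = wilcoxon_signed_rank_exact(d)
        test = "wilcoxon_signed_rank"
    return ComparisonResult(
        group_a=_summary(a), group_b=_summary(b), paired=True,
        normality_p_a=p_norm, normality_p_b=None, test_used=test,
        statistic=stat, p_value=p, significant=bool(p < alpha), alpha=alpha,
        n_zeros_dropped=dropped)


def unpaired_compare(a, b, alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """Compare unpaired samples with the normality-gated protocol.

    Both samples normal by Shapiro-Wilk -> Welch two-sample t-test,
    otherwise the two-sample Kolmogorov-Smirnov test (exact when
    ``n_a * n_b <= 10^4``).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("unpaired comparison requires n >= 3 per group")

    def _norm_p(x):
        try:
            return shapiro_wilk(x)[1]
        except ValueError:
            return 0.0

    p_a, p_b = _norm_p(a), _norm_p(b)
    if p_a > alpha and p_b > alpha:
        res = sps.ttest_ind(a, b, equal_var=False)
        stat, p, test = float(res.statistic), float(res.pvalue), "unpaired_t"
    else:
        method = "exact" if len(a) * len(b) <= 10_000 else "asymp"
        res = sps.ks_2samp(a, b, method=method)
        stat, p, test = float(res.statistic), float(res.pvalue), "kolmogorov_smirnov"
    return ComparisonResult(
        group_a=_summary(a), group_b=_summary(b), paired=False,
        normality_p_a=p_a, normality_p_b=p_b, test_used=test,
        statistic=stat, p_value=min(p, 1.0), significant=bool(p < alpha),
        alpha=alpha)


def write_comparison_table(rows, path) -> None:
    """Write a condition-comparison table CSV.

    ``rows`` is an iterable of ``(condition_label, ComparisonResult)``;
    the output schema is ``condition,cc_control,cc_application,test,p,n``.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["condition", "cc_control", "cc_application",
                         "test", "p", "n"])
        for label, res in rows:
            writer.writerow([
                label,
                f"{res.group_a.mean:.2f} ± {res.group_a.sd:.2f}",
                f"{res.group_b.mean:.2f} ± {res.group_b.sd:.2f}",
                res.test_used,
                f"{res.p_value:.3g}",
                res.group_a.n,
            ])
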