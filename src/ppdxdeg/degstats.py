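"""Statistical workflow for degradation-period comparisons.

The shoulder-area metric is measured on 64 grid spectra per degradation
period.  Period means are compared with a distribution-free workflow:

1. D'Agostino's K^2 omnibus test screens each sample for normality;
   normal samples are reported as mean +- SD, the rest as
   median (Q1, Q3).
2. Consecutive periods are compared with the Wilcoxon signed-rank test
   (paired by grid position), which does not presuppose normality.
3. The familywise error rate over the m consecutive-period comparisons
   is held at alpha by the Bonferroni correction (alpha/m per test; with
   five periods, 0.05/4 = 0.0125).

The exact signed-rank null distribution is computed in-package by
dynamic programming over (doubled, tie-midranked) ranks; the
large-sample mode delegates to scipy's normal approximation with tie
and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "dagostino_k2",
    "summarize",
    "wilcoxon_signed_rank",
    "bonferroni",
    "compare_series",
]


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics with the normality-dependent display rule."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    normality_p: float
    normal: bool
    display: str  # "mean±SD" iff normal else "median (Q1, Q3)"

    def render(self, fmt: str = "{:.2f}") -> str:
        """Human-readable cell in the journal-table style."""
        if self.normal:
            return f"{fmt.format(self.mean)} ± {fmt.format(self.sd)}"
        return (
            f"{fmt.format(self.median)} "
            f"({fmt.format(self.q1)}, {fmt.format(self.q3)})"
        )


@dataclass(frozen=True)
class ComparisonResult:
    pair: tuple[int, int]      # (week_a, week_b)
    statistic_W: float         # min of the signed-rank sums
    p_value: float
    alpha_per_test: float
    significant: bool
    direction: int             # sign of median(b - a)


def dagostino_k2(sample: Sequence[float]) -> tuple[float, float]:
    """D'Agostino's K^2 omnibus normality test.

    K^2 is the sum of squared z-transformed sample skewness and kurtosis,
    referred to a chi-square with 2 df.  Requires n >= 8 (the kurtosis
    z-transform is unreliable below that; use a Shapiro-type test for
    smaller samples) and non-degenerate data.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError(
            f"D'Agostino K^2 needs n >= 8 (got {x.size}); "
            "use e.g. Shapiro-Wilk for smaller samples"
        )
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance: normality test undefined")
    k2, p = stats.normaltest(x)
    return float(k2), float(p)


def summarize(sample: Sequence[float], alpha_normality: float = 0.05) -> GroupSummary:
    """Both summary pairs plus the normality verdict that selects the
    display.  Quartiles use linear interpolation (type 7)."""
    x = np.asarray(sample, dtype=float)
    _, p = dagostino_k2(x)
    normal = p >= alpha_normality
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # type-7 interpolation
    return GroupSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        normality_p=float(p),
        normal=bool(normal),
        display="mean±SD" if normal else "median (Q1, Q3)",
    )


def _exact_signed_rank_p(ranks: np.ndarray, w_min: float) -> float:
    """Exact two-sided p by dynamic programming.

    Ranks are midranks; doubling makes them integers, and the
    distribution of the doubled positive-rank sum is the coefficient
    array of prod_i (1 + z^{2 r_i}).  Sign-symmetry makes the
    distribution symmetric, so the two-sided p is 2 * P(W <= w_min).
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: total + 1 - r]
    counts /= 2.0 ** len(doubled)
    w2 = int(np.rint(2 * w_min))
    return float(min(1.0, 2.0 * counts[: w2 + 1].sum()))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "normal_approx"] = "auto",
    zero_method: Literal["wilcox", "pratt"] = "wilcox",
    exact_cutoff: int = 20,
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Returns (W, p) where W is the smaller of the positive/negative rank
    sums.  Zero differences are dropped before ranking under the default
    ``wilcox`` rule (Pratt's method, which ranks them and then discards
    their contribution, is available via ``zero_method="pratt"``).
    ``auto`` uses the exact null distribution up to ``exact_cutoff``
    non-zero pairs and the tie- and continuity-corrected normal
    approximation beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    d = x - y
    nonzero = d != 0
    if not np.any(nonzero):
        raise ValueError(
            "all paired differences are zero: signed-rank test undefined"
        )
    if zero_method == "wilcox":
        d_used = d[nonzero]
        ranks = stats.rankdata(np.abs(d_used))
    elif zero_method == "pratt":
        ranks_all = stats.rankdata(np.abs(d))
        d_used = d[nonzero]
        ranks = ranks_all[nonzero]
    else:
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    n = d_used.size
    if n < 6:
        raise ValueError(f"need >= 6 non-zero paired differences (got {n})")
    w_plus = float(ranks[d_used > 0].sum())
    w_minus = float(ranks[d_used < 0].sum())
    w = min(w_plus, w_minus)

    if mode == "auto":
        mode = "exact" if n <= exact_cutoff else "normal_approx"
    if mode == "exact":
        p = _exact_signed_rank_p(ranks, w)
    elif mode == "normal_approx":
        _, p = stats.wilcoxon(
            d, zero_method=zero_method, correction=True, method="approx"
        )
        p = float(p)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return w, p


def bonferroni(alpha_family: float, m: int) -> float:
    """Per-comparison significance threshold alpha_family / m."""
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    if not 0 < alpha_family < 1:
        raise ValueError("alpha_family must be in (0, 1)")
    return alpha_family / m


def compare_series(
    metrics_by_period: Mapping[int, Sequence[float]],
    pairing: Literal["by_grid_index", "independent"] = "by_grid_index",
    alpha_family: float = 0.05,
    mode: Literal["auto", "exact", "normal_approx"] = "auto",
) -> list[ComparisonResult]:
    """Consecutive-period comparisons under familywise Bonferroni control.

    Periods are sorted by week; each consecutive pair is tested with the
    signed-rank test pairing observations by grid index (the measurement
    grids share a layout, so index pairing is the natural interpretation;
    an independent-samples Mann-Whitney fallback is available).  With m
    pairs the per-test threshold is ``alpha_family / m``.
    """
    weeks = sorted(metrics_by_period)
    if len(weeks) < 2:
        return []
    samples = {w: np.asarray(metrics_by_period[w], dtype=float) for w in weeks}
    if pairing == "by_grid_index":
        sizes = {w: s.size for w, s in samples.items()}
        if len(set(sizes.values())) != 1:
            raise ValueError(
                f"paired comparison needs equal n per period, got {sizes}"
            )
    m = len(weeks) - 1
    alpha = bonferroni(alpha_family, m)
    out = []
    for a, b in zip(weeks[:-1], weeks[1:]):
        xa, xb = samples[a], samples[b]
        if pairing == "by_grid_index":
            try:
                w_stat, p = wilcoxon_signed_rank(xa, xb, mode=mode)
            except ValueError as exc:
                raise ValueError(
                    f"comparison {a} vs {b} weeks failed: {exc}"
                ) from exc
        else:
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            w_stat, p = float(res.statistic), float(res.pvalue)
        direction = int(np.sign(np.median(xb) - np.median(xa)))
        out.append(
            ComparisonResult(
                pair=(a, b),
                statistic_W=w_stat,
                p_value=p,
                alpha_per_test=alpha,
                significant=bool(p < alpha),
                direction=direction,
            )
        )
    return out
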