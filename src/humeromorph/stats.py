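"""Group allocation and the normality-gated comparison workflow.

Donors are allocated to WHO T-score bands (osteoporotic at T <= -2.5,
normal at T >= -1.0, osteopenia between).  Regional values within a group
are compared with a one-way repeated-measures analysis plus pairwise
paired contrasts when every variable passes a Shapiro-Wilk normality
gate, and with pairwise Wilcoxon signed-rank tests otherwise.  Group
comparisons use Welch's t-test on the parametric path and an
independent-samples rank-sum (Mann-Whitney) test on the nonparametric
path.  All pairwise p-values within a comparison family are
Bonferroni-adjusted.

The signed-rank null distribution is computed exactly (dynamic
programming over sign assignments, midranks for ties) for n <= 25 and by
a continuity-corrected normal approximation above.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ParameterError, ValidationError

__all__ = [
    "ComparisonTable",
    "allocate_group",
    "normality_gate",
    "signed_rank_test",
    "compare_regions_within_group",
    "compare_groups",
    "bonferroni",
]

#: maximum n for the exact signed-rank null
_EXACT_SIGNED_RANK_N = 25


@dataclass
class ComparisonTable:
    """One statistical comparison with its family-wise adjustment."""

    comparison: str
    test_used: str  # repeated_measures_parametric | wilcoxon_signed_rank | t_test | rank_sum
    raw_p: float
    adjusted_p: float
    n_comparisons: int
    significant: bool
    alpha: float = 0.05
    note: str = ""

    def __post_init__(self) -> None:
        expect = bonferroni(self.raw_p, self.n_comparisons)
        if not math.isclose(self.adjusted_p, expect, rel_tol=1e-12, abs_tol=1e-12):
            raise ValidationError(
                f"adjusted_p {self.adjusted_p} != min(1, m*raw_p) = {expect}"
            )
        if self.significant != (self.adjusted_p <= self.alpha):
            raise ValidationError("significance flag inconsistent with adjusted_p and alpha")

    @classmethod
    def build(
        cls,
        comparison: str,
        test_used: str,
        raw_p: float,
        n_comparisons: int,
        alpha: float = 0.05,
        note: str = "",
    ) -> "ComparisonTable":
        adj = bonferroni(raw_p, n_comparisons)
        return cls(
            comparison=comparison,
            test_used=test_used,
            raw_p=float(raw_p),
            adjusted_p=adj,
            n_comparisons=int(n_comparisons),
            significant=bool(adj <= alpha),
            alpha=float(alpha),
            note=note,
        )


def allocate_group(t_score: float) -> str:
    """WHO DXA band for a distal-radius T-score.

    osteoporotic if T <= -2.5, normal if T >= -1.0, osteopenia otherwise.
    Both boundaries are inclusive on the outer bands, following the WHO
    "T-score of -2.5 or less" convention.
    """
    t = float(t_score)
    if not math.isfinite(t):
        raise ValidationError(f"T-score must be finite, got {t_score}")
    if t <= -2.5:
        return "osteoporotic"
    if t >= -1.0:
        return "normal"
    return "osteopenia"


def normality_gate(samples: Sequence[float], alpha_gate: float = 0.05) -> Tuple[bool, float]:
    """Shapiro-Wilk gate: ``(treat_as_normal, W)``.

    ``treat_as_normal`` is True iff the Shapiro-Wilk p-value exceeds
    ``alpha_gate``.  A sample without variance cannot be assessed and is
    routed to the nonparametric path (gate False, W = NaN).
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"Shapiro-Wilk needs n >= 3, got n = {x.size}")
    if x.size > 5000:
        raise InsufficientDataError("Shapiro-Wilk gate limited to n <= 5000")
    if np.ptp(x) == 0.0:
        return False, float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = sps.shapiro(x)
    return bool(p > alpha_gate), float(w)


def bonferroni(raw_p: float, m: int) -> float:
    """Family-wise Bonferroni adjustment ``min(1, m * p)``."""
    p = float(raw_p)
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"p-value out of range [0, 1]: {raw_p}")
    if int(m) < 1:
        raise ParameterError(f"number of comparisons must be >= 1, got {m}")
    return min(1.0, int(m) * p)


# ---------------------------------------------------------------------------
# Wilcoxon signed rank with exact small-sample null
# ---------------------------------------------------------------------------


def _signed_rank_statistic(d: np.ndarray) -> Tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the midranks used."""
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    return w_plus, ranks


def _exact_signed_rank_cdf(ranks: np.ndarray) -> np.ndarray:
    """Null pmf of W+ on a grid of half-rank units.

    Midranks are multiples of 1/2, so 2*rank is an integer and the
    distribution of 2*W+ lives on {0, ..., sum(2*ranks)}.  Dynamic
    programming over the 2^n equiprobable sign assignments.
    """
    scaled = np.rint(2.0 * ranks).astype(int)
    total = int(scaled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in scaled:
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = 0.5 * nxt
    return pmf


def signed_rank_test(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    alternative: str = "two-sided",
) -> Tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples (or one sample vs 0).

    Returns ``(w_plus, p)``.  Zero differences are dropped (Wilcoxon
    convention); ties among |d| receive midranks.  Exact null for
    n <= 25 (conditional on the observed midranks), normal approximation
    with tie correction and continuity correction for larger n.  If every
    difference is zero the test is degenerate and p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    if y is not None:
        y = np.asarray(list(y), dtype=float)
        if y.shape != x.shape:
            raise ParameterError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    w_plus, ranks = _signed_rank_statistic(d)
    mean_w = float(ranks.sum()) / 2.0

    if n <= _EXACT_SIGNED_RANK_N:
        pmf = _exact_signed_rank_cdf(ranks)
        k = int(round(2.0 * w_plus))
        p_le = float(pmf[: k + 1].sum())
        p_ge = float(pmf[k:].sum())
    else:
        var_w = float(np.sum(ranks**2)) / 4.0
        sd = math.sqrt(var_w)
        # continuity correction of half a (half-rank) step
        p_le = float(sps.norm.cdf((w_plus - mean_w + 0.25) / sd))
        p_ge = float(sps.norm.sf((w_plus - mean_w - 0.25) / sd))

    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        raise ParameterError(f"unknown alternative {alternative!r}")
    return w_plus, float(min(1.0, p))


# ---------------------------------------------------------------------------
# Comparison workflows
# ---------------------------------------------------------------------------


def _paired_t_p(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    if np.ptp(d) == 0.0:
        return 1.0 if np.allclose(d, 0.0) else 0.0
    t, p = sps.ttest_rel(a, b)
    return float(p) if math.isfinite(p) else 1.0


def compare_regions_within_group(
    values: pd.DataFrame,
    alpha: float = 0.05,
    alpha_gate: float = 0.05,
) -> List[ComparisonTable]:
    """Pairwise region comparisons within one donor group.

    ``values``: rows = donors, columns = region labels.  Donors with any
    missing region are dropped (with a warning).  If every region column
    passes the normality gate the parametric path is taken
    (repeated-measures family, pairwise paired t contrasts); a single
    failing column routes the whole family to pairwise Wilcoxon
    signed-rank tests.  All pairwise p-values are Bonferroni-adjusted
    with m = number of region pairs.
    """
    if values.shape[1] < 2:
        raise InsufficientDataError("need at least 2 regions to compare")
    complete = values.dropna(axis=0)
    dropped = len(values) - len(complete)
    if dropped:
        warnings.warn(f"dropping {dropped} donors with missing region values")
    if len(complete) < 3:
        raise InsufficientDataError(
            f"need >= 3 complete donors, have {len(complete)}"
        )

    gates = {c: normality_gate(complete[c].to_numpy(), alpha_gate)[0] for c in complete.columns}
    parametric = all(gates.values())

    pairs = list(itertools.combinations(complete.columns, 2))
    m = len(pairs)
    tables: List[ComparisonTable] = []
    for r1, r2 in pairs:
        a = complete[r1].to_numpy(dtype=float)
        b = complete[r2].to_numpy(dtype=float)
        if parametric:
            raw_p = _paired_t_p(a, b)
            test = "repeated_measures_parametric"
        else:
            _, raw_p = signed_rank_test(a, b)
            test = "wilcoxon_signed_rank"
        tables.append(
            ComparisonTable.build(
                comparison=f"{r1} vs {r2}",
                test_used=test,
                raw_p=raw_p,
                n_comparisons=m,
                alpha=alpha,
                note="" if parametric else "normality gate failed for at least one region",
            )
        )
    return tables


def repeated_measures_anova(values: pd.DataFrame) -> float:
    """Overall one-way repeated-measures ANOVA p-value (region effect).

    Thin wrapper over statsmodels' AnovaRM; no sphericity correction is
    applied by default.
    """
    from statsmodels.stats.anova import AnovaRM

    long = values.dropna(axis=0).reset_index(names="donor").melt(
        id_vars="donor", var_name="region", value_name="value"
    )
    res = AnovaRM(long, depvar="value", subject="donor", within=["region"]).fit()
    return float(res.anova_table["Pr > F"].iloc[0])


def compare_groups(
    values_g1: Sequence[float],
    values_g2: Sequence[float],
    alpha: float = 0.05,
    alpha_gate: float = 0.05,
    n_comparisons: int = 1,
    comparison: str = "group1 vs group2",
) -> ComparisonTable:
    """Two-sided comparison of one variable between two donor groups.

    Both samples are gated with Shapiro-Wilk; if both pass, Welch's
    unequal-variance t-test is used, otherwise an independent-samples
    rank-sum (Mann-Whitney U) test.
    """
    a = np.asarray(list(values_g1), dtype=float)
    b = np.asarray(list(values_g2), dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"both groups need n >= 3 (got {a.size} and {b.size})"
        )
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        # identical constant data: no evidence of a difference
        return ComparisonTable.build(comparison, "t_test", 1.0, n_comparisons, alpha,
                                     note="degenerate: zero variance")
    ok1, _ = normality_gate(a, alpha_gate)
    ok2, _ = normality_gate(b, alpha_gate)
    if ok1 and ok2:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        test = "t_test"
        if not math.isfinite(p):
            p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "rank_sum"
        if not math.isfinite(p):
            p = 1.0
    return ComparisonTable.build(comparison, test, float(p), n_comparisons, alpha)


def tables_to_frame(tables: Sequence[ComparisonTable]) -> pd.DataFrame:
    """Flatten comparison tables into a tidy DataFrame for CSV export."""
    return pd.DataFrame(
        {
            "comparison": [t.comparison for t in tables],
            "test_used": [t.test_used for t in tables],
            "raw_p": [t.raw_p for t in tables],
            "adjusted_p": [t.adjusted_p for t in tables],
            "n_comparisons": [t.n_comparisons for t in tables],
            "significant": [t.significant for t in tables],
            "note": [t.note for t in tables],
        }
    )
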