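"""Small statistical helpers shared by the triad and repeat analyses."""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _sps

__all__ = [
    "chi_square_against_background",
    "two_proportion_ztest",
    "wilcoxon_rank_sum_one_sided",
    "TwoProportionResult",
]


@dataclass(frozen=True)
class TwoProportionResult:
    z: float
    p_value: float


def chi_square_against_background(
    observed: tuple[float, float, float],
    background: tuple[float, float, float],
) -> tuple[float, float]:
    """Chi-square (df=2) of an observed 3-way split against background shares.

    Expected counts are the background proportions scaled to the observed row
    total. Returns ``(chi2, p)`` with the two-tailed p from the df=2 upper
    tail, which has the closed form ``exp(-chi2 / 2)``.
    """
    row_total = sum(observed)
    bg_total = sum(background)
    if row_total <= 0:
        raise ValueError("observed row total must be positive")
    if bg_total <= 0:
        raise ValueError("background total must be positive")
    expected = [b / bg_total * row_total for b in background]
    if any(e <= 0 for e in expected):
        raise ValueError(
            "zero expected count; merge rows or drop the empty background state"
        )
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(_sps.chi2.sf(chi2, df=2))
    return chi2, p


def two_proportion_ztest(
    count1: int, n1: int, count2: int, n2: int, correction: bool = False
) -> TwoProportionResult:
    """Pooled two-proportion z-test (two-sided).

    With ``correction=True`` a Yates-style continuity correction of
    ``0.5 * (1/n1 + 1/n2)`` is applied to the absolute difference, matching
    R's ``prop.test`` (whose X-squared equals the corrected z squared).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = count1 / n1, count2 / n2
    pooled = (count1 + count2) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    diff = abs(p1 - p2)
    if correction:
        diff = max(0.0, diff - 0.5 * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        z = 0.0
    else:
        z = diff / se
    z_signed = math.copysign(z, p1 - p2) if p1 != p2 else 0.0
    p = float(2.0 * _sps.norm.sf(abs(z)))
    return TwoProportionResult(z=z_signed, p_value=min(1.0, p))


def wilcoxon_rank_sum_one_sided(
    x: list[float], y: list[float], alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum (Mann-Whitney U) test of x against y.

    Uses the exact null distribution for small tie-free samples (scipy's
    exact method), falling back to the normal approximation otherwise.
    Returns ``(U_statistic, p)``.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (len(x) + len(y)) <= 25 and len(set(x) | set(y)) == len(x) + len(y) else "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
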