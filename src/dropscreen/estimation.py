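"""Inference on observed screen counts.

Recovered-colony counts in these screens are small (a handful of
violacein-positive colonies out of a few hundred plated), so interval
estimates use the exact Clopper–Pearson construction rather than normal
approximations, and two-arm comparisons use Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "EnrichmentEstimate",
    "ArmComparison",
    "BackgroundEstimate",
    "estimate_enrichment",
    "compare_arms",
    "estimate_background",
]


@dataclass(frozen=True)
class EnrichmentEstimate:
    """Post-sort positive fraction and fold enrichment over the input spike.

    ``ci_low``/``ci_high`` bound the positive *fraction*; divide by
    ``input_fraction`` for the enrichment interval (exposed as
    ``enrichment_ci``).
    """

    x_positive: int
    n_total: int
    input_fraction: float
    point_fraction: float
    point_enrichment: float
    ci_low: float
    ci_high: float
    level: float
    method: str = "beta"

    @property
    def enrichment_ci(self) -> Tuple[float, float]:
        return (self.ci_low / self.input_fraction, self.ci_high / self.input_fraction)


@dataclass(frozen=True)
class ArmComparison:
    """Ratio of two arms' point enrichments with Fisher's exact p-value.

    ``enrichment_ratio`` is None when both arms observed zero positives
    (the ratio is undefined).
    """

    enrichment_ratio: Optional[float]
    p_value: float
    odds_ratio: float


@dataclass(frozen=True)
class BackgroundEstimate:
    """Per-cell background apoptosis rate with exact CI."""

    x_apoptotic: int
    n_cells: int
    rate: float
    ci_low: float
    ci_high: float
    level: float


def _check_counts(x: int, n: int) -> None:
    if n < 0 or x < 0 or x > n:
        raise ValueError(f"need 0 ≤ x ≤ n, got x={x}, n={n}")


def estimate_enrichment(
    x: int,
    n: int,
    f: float,
    level: float = 0.95,
    method: str = "beta",
) -> EnrichmentEstimate:
    """Estimate the post-sort positive fraction x/n and its enrichment over f.

    ``method`` is any statsmodels binomial-interval method; the default
    ``"beta"`` is the exact Clopper–Pearson interval, appropriate for
    the small counts these screens produce (9/300, 3/20, 0/500).
    """
    _check_counts(x, n)
    if not 0 < f <= 1:
        raise ValueError(f"input fraction must lie in (0, 1], got {f}")
    if n == 0:
        raise ValueError("cannot estimate a fraction from n = 0")
    lo, hi = proportion_confint(x, n, alpha=1 - level, method=method)
    frac = x / n
    return EnrichmentEstimate(
        x_positive=x,
        n_total=n,
        input_fraction=f,
        point_fraction=frac,
        point_enrichment=frac / f,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
        method=method,
    )


def compare_arms(
    single: EnrichmentEstimate, aggregate: EnrichmentEstimate
) -> ArmComparison:
    """Compare two screen arms sharing an input spike fraction.

    Returns the aggregate/single ratio of point enrichments (equal to
    the ratio of positive fractions since f cancels) and the two-sided
    Fisher exact p-value on the 2×2 positives table.
    """
    if not math.isclose(single.input_fraction, aggregate.input_fraction):
        raise ValueError(
            "arms must share the input fraction: "
            f"{single.input_fraction} vs {aggregate.input_fraction}"
        )
    table = [
        [aggregate.x_positive, aggregate.n_total - aggregate.x_positive],
        [single.x_positive, single.n_total - single.x_positive],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    if single.point_fraction == 0 and aggregate.point_fraction == 0:
        ratio = None
    elif single.point_fraction == 0:
        ratio = math.inf
    else:
        ratio = aggregate.point_enrichment / single.point_enrichment
    return ArmComparison(enrichment_ratio=ratio, p_value=float(p), odds_ratio=float(odds))


def estimate_background(
    x_apoptotic: int, n_cells: int, level: float = 0.95, method: str = "beta"
) -> BackgroundEstimate:
    """MLE x/n of the per-cell background apoptosis rate with exact CI."""
    _check_counts(x_apoptotic, n_cells)
    if n_cells == 0:
        raise ValueError("cannot estimate a rate from n = 0")
    lo, hi = proportion_confint(x_apoptotic, n_cells, alpha=1 - level, method=method)
    return BackgroundEstimate(
        x_apoptotic=x_apoptotic,
        n_cells=n_cells,
        rate=x_apoptotic / n_cells,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
    )
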