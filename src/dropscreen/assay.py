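"""Generative apoptosis-readout model for single cells and aggregates.

Each screening unit is either a single mammalian cell (N = 1) or an
aggregate of N cells sharing one droplet with a bacterial clone.  A cell
scores apoptotic with probability p_bg when exposed to a null clone
(background apoptosis from the invasive bacteria and handling) and with
probability p_hit ≫ p_bg when exposed to a hit clone producing a
pro-apoptotic compound.  Cells are conditionally independent given the
clone, so the apoptotic count K in an N-cell unit is Binomial(N, p); for
small p the Poisson(N·p) approximation is also provided.  A unit is
sorted positive when K reaches a threshold T — by default the mid-size
rule T = ceil(N/2), i.e. at least half the cells apoptotic.

Pooling cells into aggregates sharpens the screen: with p_bg = 0.1 an
aggregate of ten cells averages one background-apoptotic cell, far below
the mid-size threshold, while a hit-dosed aggregate has most cells
affected and passes it almost surely.  The post-sort hit fraction and
its fold enrichment over the input spike fraction f follow from Bayes'
rule on the two sort rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

__all__ = [
    "AssayParams",
    "AggregatePmf",
    "NoPositivesError",
    "midsize_threshold",
    "aggregate_count_pmf",
    "aggregate_positive_prob",
    "post_sort_positive_fraction",
    "fold_enrichment",
    "fold_improvement_vs_single",
    "expected_apoptotic_per_aggregate",
    "enrichment_curve",
]

CountModel = Literal["binomial", "poisson"]


class NoPositivesError(ValueError):
    """Raised when no unit can sort positive (both sort rates are zero)."""


class AssayParams(BaseModel):
    """Parameters of the apoptosis readout.

    ``hit_fraction`` is the spiked fraction f of true-positive clones in
    the library; ``p_background``/``p_hit`` are per-cell apoptosis
    probabilities under null and hit dosing; ``aggregate_size`` is the
    number N of cells per unit; ``threshold`` is either the string
    ``"midsize"`` (T = ceil(N/2)) or an explicit integer 1 ≤ T ≤ N.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    hit_fraction: float = Field(ge=0, le=1)
    p_background: float = Field(ge=0, le=1)
    p_hit: float = Field(ge=0, le=1)
    aggregate_size: int = Field(ge=1)
    count_model: CountModel = "binomial"
    threshold: Union[Literal["midsize"], int] = "midsize"

    @model_validator(mode="after")
    def _check(self) -> "AssayParams":
        if self.p_background > self.p_hit:
            raise ValueError("p_background must not exceed p_hit")
        if isinstance(self.threshold, int) and not (
            1 <= self.threshold <= self.aggregate_size
        ):
            raise ValueError(
                f"explicit threshold {self.threshold} outside "
                f"[1, {self.aggregate_size}]"
            )
        return self

    @property
    def threshold_value(self) -> int:
        """The sorting threshold T as an integer count."""
        if self.threshold == "midsize":
            return midsize_threshold(self.aggregate_size)
        return self.threshold


def midsize_threshold(n_cells: int) -> int:
    """Mid-size sorting threshold T = ceil(N/2).

    An aggregate is called positive when at least half its cells score
    apoptotic; for N = 1 this reduces to "the cell is apoptotic".
    """
    if n_cells < 1:
        raise ValueError(f"aggregate size must be ≥ 1, got {n_cells}")
    return -(-n_cells // 2)


def _check_np(n_cells: int, p: float) -> None:
    if n_cells < 1:
        raise ValueError(f"aggregate size must be ≥ 1, got {n_cells}")
    if not 0 <= p <= 1:
        raise ValueError(f"per-cell probability must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class AggregatePmf:
    """Distribution of the apoptotic count K over k = 0..N.

    Under the binomial model the pmf sums to 1 (``truncation_mass`` 0);
    under the Poisson(N·p) approximation mass beyond k = N is reported
    in ``truncation_mass``.
    """

    k: np.ndarray
    pmf: np.ndarray
    truncation_mass: float


def aggregate_count_pmf(
    n_cells: int, p: float, count_model: CountModel = "binomial"
) -> AggregatePmf:
    """Pmf of the apoptotic-cell count in an N-cell unit at per-cell rate p."""
    _check_np(n_cells, p)
    k = np.arange(n_cells + 1)
    if count_model == "binomial":
        return AggregatePmf(k, stats.binom.pmf(k, n_cells, p), 0.0)
    if count_model == "poisson":
        pmf = stats.poisson.pmf(k, n_cells * p)
        return AggregatePmf(k, pmf, float(stats.poisson.sf(n_cells, n_cells * p)))
    raise ValueError(f"unknown count model {count_model!r}")


def aggregate_positive_prob(
    n_cells: int, p: float, threshold: int, count_model: CountModel = "binomial"
) -> float:
    """P(K ≥ T): probability the unit is called positive at threshold T."""
    _check_np(n_cells, p)
    if not 1 <= threshold <= n_cells:
        raise ValueError(f"threshold {threshold} outside [1, {n_cells}]")
    if count_model == "binomial":
        return float(stats.binom.sf(threshold - 1, n_cells, p))
    if count_model == "poisson":
        return float(stats.poisson.sf(threshold - 1, n_cells * p))
    raise ValueError(f"unknown count model {count_model!r}")


def post_sort_positive_fraction(f: float, s_hit: float, s_null: float) -> float:
    """Fraction of sorted-positive units that are hit-dosed.

    Bayes' rule on the sort rates: f·S_hit / (f·S_hit + (1−f)·S_null).

    Raises
    ------
    NoPositivesError
        If the denominator is zero — nothing sorts positive.
    """
    for name, v in (("f", f), ("s_hit", s_hit), ("s_null", s_null)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    denom = f * s_hit + (1 - f) * s_null
    if denom == 0:
        raise NoPositivesError("no units sort positive at these rates")
    return f * s_hit / denom


def fold_enrichment(f: float, s_hit: float, s_null: float) -> float:
    """Post-sort hit fraction divided by the input spike fraction f."""
    if f <= 0:
        raise ValueError("fold enrichment requires a positive input fraction")
    return post_sort_positive_fraction(f, s_hit, s_null) / f


def fold_improvement_vs_single(
    n_cells: int,
    p_bg: float,
    p_hit: float,
    f: float,
    count_model: CountModel = "binomial",
) -> float:
    """Enrichment of an N-cell aggregate screen relative to single cells.

    The aggregate arm uses the mid-size threshold at size N; the
    single-cell comparator uses N = 1, T = 1 with the same per-cell
    probabilities.  Equals 1 at N = 1 by construction and grows with N
    whenever p_hit > p_bg: pooling suppresses the background sort rate
    much faster than the hit sort rate.
    """
    t = midsize_threshold(n_cells)
    agg = fold_enrichment(
        f,
        aggregate_positive_prob(n_cells, p_hit, t, count_model),
        aggregate_positive_prob(n_cells, p_bg, t, count_model),
    )
    single = fold_enrichment(
        f,
        aggregate_positive_prob(1, p_hit, 1, count_model),
        aggregate_positive_prob(1, p_bg, 1, count_model),
    )
    return agg / single


def expected_apoptotic_per_aggregate(n_cells: int, p_bg: float) -> float:
    """Expected background-apoptotic cells per N-cell aggregate: N·p_bg."""
    _check_np(n_cells, p_bg)
    return n_cells * p_bg


def enrichment_curve(
    sizes: Iterable[int],
    p_bg: float,
    p_hit: float,
    f: float,
    count_model: CountModel = "binomial",
) -> pd.DataFrame:
    """Aggregate-size scan of sort rates, enrichment and fold improvement.

    One row per aggregate size N with the mid-size threshold: columns
    ``n_cells, threshold, s_hit, s_null, post_sort_fraction, enrichment,
    fold_improvement``.
    """
    rows = []
    for n in sizes:
        t = midsize_threshold(n)
        s_hit = aggregate_positive_prob(n, p_hit, t, count_model)
        s_null = aggregate_positive_prob(n, p_bg, t, count_model)
        rows.append(
            {
                "n_cells": n,
                "threshold": t,
                "s_hit": s_hit,
                "s_null": s_null,
                "post_sort_fraction": post_sort_positive_fraction(f, s_hit, s_null),
                "enrichment": fold_enrichment(f, s_hit, s_null),
                "fold_improvement": fold_improvement_vs_single(
                    n, p_bg, p_hit, f, count_model
                ),
            }
        )
    return pd.DataFrame(rows)
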