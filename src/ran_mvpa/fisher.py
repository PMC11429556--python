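"""Fisher-score feature selection over atlas regions.

Each region is scored per visit with the two-class Fisher criterion

    F = (mean_1 - mean_2)**2 / (var_1 + var_2)

using unbiased class variances.  Regions whose score meets or exceeds a
threshold *at least once across the visits* survive; the threshold itself is
chosen by sweeping a grid (default 0.16-0.26 in steps of 0.02) and keeping
the value whose surviving set maximizes the mean leave-one-out SVM accuracy
across visits.

The scoring and survival rule run on the full sample at each visit — the
selection happens before, and outside, the cross-validation loop.  This
reproduces the analysis order described for the original study; a nested
(within-fold) variant is available for users who want selection kept inside
the CV loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionFeatureMatrix

__all__ = [
    "FisherScores",
    "SelectionConfig",
    "SelectionResult",
    "fisher_score",
    "score_regions",
    "select_surviving_regions",
    "sweep_thresholds",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(np.round(np.arange(0.16, 0.2601, 0.02), 10))


@dataclass(frozen=True)
class FisherScores:
    """Per-region Fisher scores for one visit."""

    visit: str
    scores: pd.Series  # index = region label
    n_group1: int
    n_group2: int


@dataclass(frozen=True)
class SelectionConfig:
    """Threshold grid and survival rule for the region-selection sweep."""

    grid: tuple[float, ...] = DEFAULT_GRID
    survival_rule: str = "at_least_once"
    weighted_variances: bool = False  # class-size-weighted Fisher variant

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0 or np.any(np.diff(g) <= 0):
            raise ValueError("threshold grid must be strictly increasing")
        if np.any(g <= 0):
            raise ValueError("threshold grid values must be positive")
        if self.survival_rule != "at_least_once":
            raise ValueError(f"unknown survival rule {self.survival_rule!r}")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the threshold sweep."""

    surviving_by_threshold: dict[float, set[int]]
    accuracy_by_threshold: dict[float, float]  # mean LOO accuracy across visits
    chosen_threshold: float
    chosen_regions: set[int]

    def summary(self) -> pd.DataFrame:
        rows = []
        for thr in sorted(self.surviving_by_threshold):
            rows.append(
                {
                    "threshold": thr,
                    "n_regions": len(self.surviving_by_threshold[thr]),
                    "mean_loo_accuracy": self.accuracy_by_threshold.get(thr, np.nan),
                    "chosen": thr == self.chosen_threshold,
                }
            )
        return pd.DataFrame(rows)


def fisher_score(
    values_group1: Sequence[float] | np.ndarray,
    values_group2: Sequence[float] | np.ndarray,
    weighted: bool = False,
) -> float:
    """Two-class Fisher criterion for one feature.

    Default: ``(m1-m2)**2 / (var1 + var2)`` with unbiased variances.
    ``weighted=True`` weights each class variance by its sample share,
    ``(m1-m2)**2 / ((n1*var1 + n2*var2)/(n1+n2))``.

    Zero pooled variance with differing means returns ``inf``; with equal
    means, 0 (no separation, no spread).
    """
    g1 = np.asarray(values_group1, dtype=float)
    g2 = np.asarray(values_group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.isnan(g1).any() or np.isnan(g2).any():
        raise ValueError("missing values in a scored feature")
    m1, m2 = g1.mean(), g2.mean()
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if weighted:
        denom = (g1.size * v1 + g2.size * v2) / (g1.size + g2.size)
    else:
        denom = v1 + v2
    num = (m1 - m2) ** 2
    if denom == 0.0:
        return float("inf") if num > 0 else 0.0
    return float(num / denom)


def score_regions(
    region_matrix: RegionFeatureMatrix,
    group_labels: Sequence[str] | None = None,
    visit: str = "",
    weighted: bool = False,
) -> FisherScores:
    """Fisher score of every region column, survivors vs controls.

    ``group_labels`` defaults to the matrix's own ``meta['group']``.  Regions
    with any missing value (empty atlas regions) carry no score (NaN).
    """
    if group_labels is None:
        group_labels = region_matrix.meta["group"].to_numpy()
    y = np.asarray(group_labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two groups, got {classes.tolist()}")
    mask1 = y == classes[0]
    mask2 = ~mask1
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    scores = {}
    for col in region_matrix.values.columns:
        vals = region_matrix.values[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            scores[col] = np.nan
            continue
        scores[col] = fisher_score(vals[mask1], vals[mask2], weighted=weighted)
    return FisherScores(
        visit=visit or (region_matrix.meta["visit"].iloc[0] if len(region_matrix.meta) else ""),
        scores=pd.Series(scores, name="fisher_score"),
        n_group1=int(mask1.sum()),
        n_group2=int(mask2.sum()),
    )


def select_surviving_regions(
    scores_by_visit: Mapping[str, FisherScores] | Iterable[FisherScores],
    threshold: float,
) -> set[int]:
    """Regions whose score meets or exceeds ``threshold`` in ANY visit."""
    if isinstance(scores_by_visit, Mapping):
        all_scores = list(scores_by_visit.values())
    else:
        all_scores = list(scores_by_visit)
    if not all_scores:
        raise ValueError("need scores for at least one visit")
    out: set[int] = set()
    for fs in all_scores:
        s = fs.scores
        out |= set(int(lab) for lab in s.index[s >= threshold])
    return out


def sweep_thresholds(
    scores_by_visit: Mapping[str, FisherScores],
    evaluate: Callable[[set[int]], Mapping[str, float]],
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Choose the threshold whose surviving regions classify best.

    ``evaluate`` maps a nonempty region set to per-visit LOO accuracies;
    the chosen threshold maximizes their mean across visits.  Thresholds
    with an empty surviving set are skipped (logged); ties resolve to the
    largest tied threshold — the most selective region set.
    """
    config = config or SelectionConfig()
    surviving: dict[float, set[int]] = {}
    acc: dict[float, float] = {}
    eval_cache: dict[frozenset, float] = {}
    for thr in config.grid:
        regions = select_surviving_regions(scores_by_visit, thr)
        surviving[float(thr)] = regions
        if not regions:
            logger.info("threshold %.3g leaves no surviving regions; skipped", thr)
            continue
        key = frozenset(regions)
        if key not in eval_cache:
            per_visit = evaluate(set(regions))
            eval_cache[key] = float(np.mean(list(per_visit.values())))
        acc[float(thr)] = eval_cache[key]
    if not acc:
        raise ValueError("every threshold in the grid yields an empty region set")
    best = max(acc.values())
    tied = [thr for thr, a in acc.items() if a == best]
    chosen = max(tied)
    if len(tied) > 1:
        logger.info(
            "thresholds %s tie at mean accuracy %.3f; keeping the largest (%.3g)",
            tied, best, chosen,
        )
    return SelectionResult(
        surviving_by_threshold=surviving,
        accuracy_by_threshold=acc,
        chosen_threshold=float(chosen),
        chosen_regions=set(surviving[float(chosen)]),
    )
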