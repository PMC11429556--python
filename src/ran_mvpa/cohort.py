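"""Cohort bookkeeping, cluster-level group statistics, and reading-score
stratification.

The cohort table has one row per subject-visit with the group label
(survivor / control) and seven age-standardized reading scores
(Woodcock-Johnson-style scale: population mean 100, SD 15).  Visit
participation is nested — every subject seen at a later visit was present
at all earlier ones; violations are hard errors at load time.

Two group-level analyses operate downstream of region selection:

* cluster-averaged contrast per subject, compared between groups per visit
  with Welch's two-sided t-test (the same code path serves the selected
  cluster and its contralateral homolog);
* high/low performer stratification of survivor visits at the standardized
  score cutoff of 100, with a leave-one-sample-out SVM per reading test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import VoxelFeatureMatrix
from .classify import (
    CVResult,
    PermutationConfig,
    SvmConfig,
    loo_cv,
    permutation_pvalue,
)

__all__ = [
    "READING_TESTS",
    "VISITS",
    "StratificationConfig",
    "GroupComparisonResult",
    "load_cohort",
    "validate_cohort",
    "cluster_mean_by_group",
    "compare_groups_by_visit",
    "group_difference_test",
    "stratify_performers",
    "performer_classification",
]

READING_TESTS = (
    "letter_word_identification",
    "reading_fluency",
    "passage_comprehension",
    "word_attack",
    "spelling_of_sounds",
    "sound_awareness",
    "reading_vocabulary",
)

VISITS = ("TP1", "TP2", "TP3")
GROUPS = ("survivor", "control")


@dataclass(frozen=True)
class StratificationConfig:
    """High/low performer split on the standardized score scale.

    ``score >= cutoff`` is "high" (the boundary score of exactly 100 is a
    high performer); samples with a missing score are dropped for that test.
    """

    cutoff: float = 100.0


@dataclass(frozen=True)
class GroupComparisonResult:
    """Per-visit group summary of cluster-averaged contrasts."""

    visit: str
    mean_survivor: float
    sd_survivor: float
    mean_control: float
    sd_control: float
    n_survivor: int
    n_control: int
    p_value: float


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check schema, group labels, and visit nestedness; returns the table."""
    required = {"subject", "group", "visit"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns {sorted(missing)}")
    bad_groups = set(cohort["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels {sorted(bad_groups)}")
    bad_visits = set(cohort["visit"].unique()) - set(VISITS)
    if bad_visits:
        raise ValueError(f"unknown visit labels {sorted(bad_visits)}")
    if cohort.duplicated(["subject", "visit"]).any():
        raise ValueError("duplicate subject-visit rows")
    by_subject = cohort.groupby("subject")["visit"].agg(set)
    for subject, seen in by_subject.items():
        ranks = sorted(VISITS.index(v) for v in seen)
        if ranks != list(range(len(ranks))):
            raise ValueError(
                f"subject {subject} violates nested participation: seen at "
                f"{sorted(seen)} but not at every earlier visit"
            )
    return cohort


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (subject, group, visit, seven scores)."""
    cohort = pd.read_csv(path, dtype={"subject": str})
    return validate_cohort(cohort)


def cluster_mean_by_group(
    maps: Mapping[tuple[str, str], np.ndarray],
    cluster_voxels: np.ndarray,
    cohort: pd.DataFrame,
    visit: str,
) -> dict[str, np.ndarray]:
    """Per-subject mean contrast over the cluster voxels, split by group.

    ``cluster_voxels`` is an (n, 3) coordinate array — a weight-map cluster's
    voxel list or the voxel union of a region set; the contralateral
    analysis runs this identical code path on the homolog set's voxels.
    """
    vox = np.asarray(cluster_voxels)
    if vox.ndim != 2 or vox.shape[1] != 3:
        raise ValueError("cluster_voxels must be an (n, 3) coordinate array")
    rows = cohort.loc[cohort["visit"] == visit, ["subject", "group"]]
    out: dict[str, list[float]] = {g: [] for g in GROUPS}
    for subject, group in rows.itertuples(index=False):
        key = (str(subject), visit)
        if key not in maps:
            raise KeyError(f"no contrast map for {key}")
        m = maps[key]
        out[group].append(float(m[vox[:, 0], vox[:, 1], vox[:, 2]].mean()))
    return {g: np.asarray(v) for g, v in out.items()}


def group_difference_test(
    values_a: Sequence[float] | np.ndarray,
    values_b: Sequence[float] | np.ndarray,
    equal_var: bool = False,
) -> float:
    """Two-sided two-sample t-test p-value (Welch by default).

    Degenerate case: zero variance in both groups with equal means has no
    evidence of a difference and returns p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return float(p)


def compare_groups_by_visit(
    maps: Mapping[tuple[str, str], np.ndarray],
    cluster_voxels: np.ndarray,
    cohort: pd.DataFrame,
    visits: Sequence[str] = VISITS,
    equal_var: bool = False,
) -> list[GroupComparisonResult]:
    """Welch comparison of cluster-averaged contrasts, one result per visit."""
    out = []
    for visit in visits:
        vals = cluster_mean_by_group(maps, cluster_voxels, cohort, visit)
        s, c = vals["survivor"], vals["control"]
        out.append(
            GroupComparisonResult(
                visit=visit,
                mean_survivor=float(s.mean()),
                sd_survivor=float(s.std(ddof=1)),
                mean_control=float(c.mean()),
                sd_control=float(c.std(ddof=1)),
                n_survivor=int(s.size),
                n_control=int(c.size),
                p_value=group_difference_test(s, c, equal_var=equal_var),
            )
        )
    return out


def stratify_performers(
    cohort: pd.DataFrame,
    test_name: str,
    config: StratificationConfig | None = None,
) -> pd.DataFrame:
    """High/low performer labels over survivor visits for one reading test.

    Pools all visits: each survivor-visit with a non-missing score becomes
    one labeled sample.  Returns a DataFrame (subject, visit, score,
    performer) where performer is "high" (score >= cutoff) or "low".
    """
    config = config or StratificationConfig()
    if test_name not in READING_TESTS:
        raise KeyError(
            f"unknown reading test {test_name!r}; expected one of {READING_TESTS}"
        )
    rows = cohort.loc[cohort["group"] == "survivor",
                      ["subject", "visit", test_name]].copy()
    rows = rows.rename(columns={test_name: "score"})
    n_missing = int(rows["score"].isna().sum())
    rows = rows.dropna(subset=["score"]).reset_index(drop=True)
    if rows.empty:
        warnings.warn(f"no non-missing {test_name} scores among survivor visits",
                      stacklevel=2)
    rows["performer"] = np.where(rows["score"] >= config.cutoff, "high", "low")
    rows.attrs["n_dropped_missing"] = n_missing
    return rows


def performer_classification(
    voxel_feats: VoxelFeatureMatrix,
    cohort: pd.DataFrame,
    test_name: str,
    strat_config: StratificationConfig | None = None,
    svm_config: SvmConfig | None = None,
    perm_config: PermutationConfig | None = None,
) -> CVResult:
    """Leave-one-sample-out SVM between high and low performers.

    Samples are pooled survivor visits (each subject-visit counts once);
    features are the voxel contrasts of ``voxel_feats`` restricted to those
    samples.  The positive class is "high".  When ``perm_config`` is given,
    the Monte-Carlo permutation p over the LOO accuracy is attached.
    """
    strat = stratify_performers(cohort, test_name, strat_config)
    key = strat.set_index(["subject", "visit"])["performer"]
    meta = voxel_feats.meta
    keep = np.array(
        [
            (s, v) in key.index
            for s, v in zip(meta["subject"], meta["visit"])
        ]
    )
    if not keep.any():
        raise ValueError(f"no feature rows match survivor visits with {test_name} scores")
    sub = voxel_feats.select_rows(keep)
    y = np.array([key.loc[(s, v)] for s, v in
                  zip(sub.meta["subject"], sub.meta["visit"])])
    if np.unique(y).size < 2:
        raise ValueError(f"all retained samples are one performer class for {test_name}")
    svm_config = svm_config or SvmConfig()
    result = loo_cv(sub.values, y, svm_config, positive_class="high")
    if perm_config is not None:
        result = permutation_pvalue(sub.values, y, svm_config, perm_config,
                                    observed=result)
    return result
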