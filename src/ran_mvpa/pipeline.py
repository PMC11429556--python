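"""End-to-end analysis: region features -> Fisher sweep -> per-visit SVM
with permutation inference -> weight-map clusters -> cluster group
statistics (including the contralateral homolog) -> performer
classification on the seven reading tests.

The library entry point is :func:`run_full_analysis`, which operates on
in-memory objects and returns a :class:`ReportBundle` of tidy DataFrames;
the command-line layer handles file I/O around it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import (
    Parcellation,
    contralateral_homolog,
    stack_region_features,
    voxel_features,
)
from .classify import PermutationConfig, SvmConfig, loo_cv, permutation_pvalue
from .cohort import (
    READING_TESTS,
    VISITS,
    StratificationConfig,
    compare_groups_by_visit,
    performer_classification,
    validate_cohort,
)
from .effect_maps import ClusterThresholdConfig, fit_weight_map, threshold_clusters
from .fisher import SelectionConfig, score_regions, sweep_thresholds

__all__ = ["AnalysisConfig", "ReportBundle", "run_full_analysis"]

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "survivor"  # the stated positive label throughout


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis-stage settings in one place.

    Defaults are the study constants: linear SVM with C = 1, 1000 label
    shuffles, Fisher threshold grid 0.16-0.26 in steps of 0.02, performer
    cutoff at a standardized score of 100, and weight-map clusters of at
    least 50 voxels with |w| >= 0.02.
    """

    svm: SvmConfig = field(default_factory=SvmConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    cluster: ClusterThresholdConfig = field(default_factory=ClusterThresholdConfig)
    stratification: StratificationConfig = field(default_factory=StratificationConfig)
    run_permutations: bool = True
    run_performer_permutations: bool = True
    seed: int = 0


@dataclass
class ReportBundle:
    """Tidy outputs of the full analysis."""

    fisher_scores: pd.DataFrame        # visit, region label, name, score
    sweep_summary: pd.DataFrame        # threshold, n_regions, mean accuracy, chosen
    selected_regions: pd.DataFrame     # label, name, hemisphere, best score/visit
    survivor_control: pd.DataFrame     # one row per visit (Table-2 shape)
    cluster_table: pd.DataFrame        # per visit: surviving weight clusters
    group_stats: pd.DataFrame          # cluster means by group (+ homolog side)
    performer: pd.DataFrame            # one row per reading test (Table-3 shape)
    weight_maps: dict[str, np.ndarray]
    chosen_threshold: float
    chosen_regions: set[int]
    seed: int

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "fisher_scores": self.fisher_scores,
            "sweep_summary": self.sweep_summary,
            "selected_regions": self.selected_regions,
            "survivor_control": self.survivor_control,
            "cluster_table": self.cluster_table,
            "group_stats": self.group_stats,
            "performer": self.performer,
        }


def _pct(x: float) -> float:
    return round(100.0 * x, 1)


def run_full_analysis(
    maps: dict[tuple[str, str], np.ndarray],
    parcellation: Parcellation,
    cohort: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> ReportBundle:
    """Run the full survivor-vs-control and performer analysis.

    ``maps`` holds one Letter>Color contrast map per (subject, visit);
    visits present in the cohort but configured without both groups fail
    at the relevant stage with the stage named.
    """
    config = config or AnalysisConfig()
    cohort = validate_cohort(cohort)
    t0 = time.perf_counter()

    def stage(name: str) -> None:
        logger.info("[%6.1fs] stage: %s", time.perf_counter() - t0, name)

    visits = [v for v in VISITS if (cohort["visit"] == v).any()]

    # -- region-mean features and Fisher scores per visit ------------------
    stage("region features")
    rfm = stack_region_features(maps, parcellation, cohort)
    stage("fisher scores")
    scores_by_visit = {
        v: score_regions(rfm.for_visit(v), visit=v) for v in visits
    }
    fisher_rows = []
    name_of = dict(zip(parcellation.table["label"], parcellation.table["name"]))
    for v, fs in scores_by_visit.items():
        for lab, s in fs.scores.items():
            fisher_rows.append(
                {"visit": v, "label": int(lab), "name": name_of[int(lab)],
                 "fisher_score": s}
            )
    fisher_df = pd.DataFrame(fisher_rows)

    # -- threshold sweep ---------------------------------------------------
    stage("threshold sweep")

    def evaluate(region_set: set[int]) -> dict[str, float]:
        vf = voxel_features(maps, parcellation, region_set, cohort)
        out = {}
        for v in visits:
            sub = vf.for_visit(v)
            res = loo_cv(sub.values, sub.meta["group"].to_numpy(), config.svm,
                         positive_class=POSITIVE_CLASS)
            out[v] = res.accuracy
        return out

    selection = sweep_thresholds(scores_by_visit, evaluate, config.selection)
    chosen = selection.chosen_regions
    sel_rows = []
    for lab in sorted(chosen):
        per_visit = {v: scores_by_visit[v].scores.get(lab, np.nan) for v in visits}
        best_visit = max(per_visit, key=lambda v: per_visit[v])
        row = parcellation.table.loc[parcellation.table["label"] == lab].iloc[0]
        sel_rows.append(
            {"label": lab, "name": row["name"], "hemisphere": row["hemisphere"],
             "best_visit": best_visit, "best_score": per_visit[best_visit]}
        )
    selected_df = pd.DataFrame(sel_rows)

    # -- per-visit survivor/control classification -------------------------
    stage("survivor/control LOO classification")
    vf_sel = voxel_features(maps, parcellation, chosen, cohort)
    sc_rows = []
    for i, v in enumerate(visits):
        sub = vf_sel.for_visit(v)
        y = sub.meta["group"].to_numpy()
        res = loo_cv(sub.values, y, config.svm, positive_class=POSITIVE_CLASS)
        if config.run_permutations:
            perm = PermutationConfig(
                n_shuffles=config.permutation.n_shuffles,
                seed=config.permutation.seed + i,
            )
            res = permutation_pvalue(sub.values, y, config.svm, perm, observed=res)
        sc_rows.append({"visit": v, **res.as_row()})
    survivor_control = pd.DataFrame(sc_rows)

    # -- weight maps and clusters ------------------------------------------
    stage("weight maps")
    weight_maps: dict[str, np.ndarray] = {}
    cl_rows = []
    for v in visits:
        sub = vf_sel.for_visit(v)
        wmap = fit_weight_map(sub, sub.meta["group"].to_numpy(), config.svm,
                              grid_shape=parcellation.grid_shape,
                              positive_class=POSITIVE_CLASS)
        weight_maps[v] = wmap
        for ci, cl in enumerate(threshold_clusters(wmap, config.cluster)):
            cl_rows.append(
                {"visit": v, "cluster": ci, "size": cl.size,
                 "peak_abs_weight": cl.peak_abs_weight,
                 "peak_voxel": cl.peak_voxel,
                 "mean_weight": cl.mean_weight,
                 "dominant_sign": cl.dominant_sign}
            )
    cluster_df = pd.DataFrame(
        cl_rows, columns=["visit", "cluster", "size", "peak_abs_weight",
                          "peak_voxel", "mean_weight", "dominant_sign"]
    )

    # -- cluster-averaged group statistics, both hemispheres ---------------
    stage("cluster group statistics")
    gs_rows = []
    sides = {"selected": chosen}
    try:
        sides["contralateral"] = contralateral_homolog(chosen, parcellation)
    except ValueError:
        logger.warning("selected set has midline regions; homolog analysis skipped")
    for side, regions in sides.items():
        vox = parcellation.voxels_of(regions)
        for r in compare_groups_by_visit(maps, vox, cohort, visits):
            gs_rows.append({"side": side, **r.__dict__})
    group_stats = pd.DataFrame(gs_rows)

    # -- performer classification per reading test -------------------------
    stage("performer classification")
    perf_rows = []
    score_cols = [t for t in READING_TESTS if t in cohort.columns]
    for j, test in enumerate(score_cols):
        perm = None
        if config.run_permutations and config.run_performer_permutations:
            perm = PermutationConfig(
                n_shuffles=config.permutation.n_shuffles,
                seed=config.permutation.seed + 100 + j,
            )
        res = performer_classification(
            vf_sel, cohort, test, config.stratification, config.svm, perm
        )
        perf_rows.append({"test": test, **res.as_row()})
    performer = pd.DataFrame(perf_rows)

    stage("done")
    return ReportBundle(
        fisher_scores=fisher_df,
        sweep_summary=selection.summary(),
        selected_regions=selected_df,
        survivor_control=survivor_control,
        cluster_table=cluster_df,
        group_stats=group_stats,
        performer=performer,
        weight_maps=weight_maps,
        chosen_threshold=selection.chosen_threshold,
        chosen_regions=chosen,
        seed=config.seed,
    )
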