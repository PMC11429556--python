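"""Synthetic longitudinal fMRI cohort with a planted lateralized effect.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without access to any scan archive:

* a rectangular-box parcellation of 15 mirror-symmetric left/right region
  pairs on a 32x32x32 grid (a stand-in geometry for an anatomical atlas;
  region names follow occipitotemporal anatomy for readability);
* two groups with nested attrition 50/50 -> 36/36 -> 21/21 across three
  annual visits, each subject-visit yielding one contrast map: a
  per-subject random offset plus i.i.d. voxel noise, with a group effect
  added inside four designated right-hemisphere regions for survivors only;
* the planted effect grows across visits (0, 0.4, 0.8 voxel-noise SDs by
  default) so the groups are indistinguishable at the first visit and
  separate by the third;
* seven standardized reading scores (mean 100, SD 15) in which three tests
  (sound awareness, reading fluency, word attack) are correlated with the
  planted regional signal and four are pure noise.

All randomness flows from one master seed through a single generator, so a
full dataset is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .atlas import Parcellation
from .cohort import READING_TESTS, VISITS, validate_cohort
from .paradigm import ParadigmTimeline, build_timeline, condition_volume_indices

__all__ = [
    "SyntheticConfig",
    "REGION_BASENAMES",
    "generate_parcellation",
    "generate_cohort",
    "generate_scores",
    "generate_dataset",
    "generate_series",
]

# 15 homolog pairs; the first four right-hemisphere regions are the default
# planted set, mirroring the lateralized occipital role in the analysis.
REGION_BASENAMES = (
    "superior occipital gyrus",
    "middle occipital gyrus",
    "inferior occipital gyrus",
    "occipital pole",
    "lingual gyrus",
    "fusiform gyrus",
    "cuneus",
    "calcarine cortex",
    "precuneus",
    "angular gyrus",
    "supramarginal gyrus",
    "superior temporal gyrus",
    "middle temporal gyrus",
    "inferior temporal gyrus",
    "parahippocampal gyrus",
)

DEFAULT_RHO = {
    "sound_awareness": 0.5,
    "reading_fluency": 0.5,
    "word_attack": 0.5,
    "letter_word_identification": 0.0,
    "passage_comprehension": 0.0,
    "spelling_of_sounds": 0.0,
    "reading_vocabulary": 0.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort.

    Effect sizes are in units of the voxel noise SD and apply inside the
    planted regions only; ``subject_sd`` is the SD of the per-subject
    global offset (shared across all voxels and visits of a subject).
    ``score_rho`` maps each reading test to its correlation with the
    standardized planted-region signal.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_region_pairs: int = 15
    planted_regions: tuple[int, ...] = ()  # default: first 4 right regions
    effect_sizes: tuple[float, float, float] = (0.0, 0.4, 0.8)
    noise_sd: float = 1.0
    subject_sd: float = 0.4
    group_sizes: tuple[tuple[int, int], ...] = ((50, 50), (36, 36), (21, 21))
    score_rho: tuple[tuple[str, float], ...] = tuple(DEFAULT_RHO.items())
    score_missing_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.effect_sizes) != len(VISITS):
            raise ValueError("need one effect size per visit")
        if any(d < 0 for d in self.effect_sizes):
            raise ValueError("effect sizes must be >= 0")
        sizes = np.asarray(self.group_sizes)
        if sizes.shape != (len(VISITS), 2):
            raise ValueError("group_sizes must give (survivors, controls) per visit")
        if np.any(np.diff(sizes, axis=0) > 0):
            raise ValueError("group sizes must be non-increasing across visits (nested)")
        for test, rho in self.score_rho:
            if test not in READING_TESTS:
                raise ValueError(f"unknown reading test {test!r}")
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"rho for {test} must lie in [-1, 1]")
        if not 0.0 <= self.score_missing_frac < 1.0:
            raise ValueError("score_missing_frac must lie in [0, 1)")

    @property
    def rho(self) -> dict[str, float]:
        out = dict(DEFAULT_RHO)
        out.update(dict(self.score_rho))
        return out

    def planted(self, parcellation: Parcellation) -> tuple[int, ...]:
        if self.planted_regions:
            return self.planted_regions
        right = parcellation.table.loc[
            parcellation.table["hemisphere"] == "R", "label"
        ]
        return tuple(int(x) for x in right.iloc[:4])


def generate_parcellation(config: SyntheticConfig | None = None) -> Parcellation:
    """Rectangular-box parcellation with mirrored left/right homolog pairs.

    Left-hemisphere boxes occupy x in [4, 10); right boxes are their exact
    mirror under x -> (nx-1) - x.  Pairs tile a 3x5 grid in (y, z), each box
    6 x 8 x 5 = 240 voxels, separated by background gutters so no two
    regions touch.  Labels: left regions 1..15, right regions 16..30,
    homolog(i) = i +/- 15.
    """
    config = config or SyntheticConfig()
    nx, ny, nz = config.grid_shape
    n_pairs = config.n_region_pairs
    if n_pairs < 1 or n_pairs > 15:
        raise ValueError("the box layout supports 1..15 homolog pairs")
    n_ybands = -(-n_pairs // 5)
    n_zbands = min(n_pairs, 5)
    if (nx < 20 or ny < 2 + 10 * (n_ybands - 1) + 8
            or nz < 1 + 6 * (n_zbands - 1) + 5):
        raise ValueError(
            f"grid {config.grid_shape} too small for {n_pairs} region pairs"
        )
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    rows = []
    for r in range(n_pairs):
        yband, zband = divmod(r, 5)
        ys = slice(2 + 10 * yband, 2 + 10 * yband + 8)
        zs = slice(1 + 6 * zband, 1 + 6 * zband + 5)
        left_label, right_label = r + 1, r + 1 + n_pairs
        labels[4:10, ys, zs] = left_label
        labels[nx - 10:nx - 4, ys, zs] = right_label
        name = REGION_BASENAMES[r % len(REGION_BASENAMES)]
        rows.append({"label": left_label, "name": f"left {name}",
                     "hemisphere": "L", "homolog_label": right_label})
        rows.append({"label": right_label, "name": f"right {name}",
                     "hemisphere": "R", "homolog_label": left_label})
    table = pd.DataFrame(rows).sort_values("label").reset_index(drop=True)
    table["homolog_label"] = table["homolog_label"].astype("Int64")
    return Parcellation(labels=labels, table=table)


def _roster(config: SyntheticConfig) -> pd.DataFrame:
    """Subject-visit roster with nested attrition by enrollment order."""
    rows = []
    for v, visit in enumerate(VISITS):
        n_surv, n_ctrl = config.group_sizes[v]
        for i in range(n_surv):
            rows.append({"subject": f"surv{i:03d}", "group": "survivor",
                         "visit": visit})
        for i in range(n_ctrl):
            rows.append({"subject": f"ctrl{i:03d}", "group": "control",
                         "visit": visit})
    return pd.DataFrame(rows)


def generate_cohort(
    config: SyntheticConfig | None = None,
    parcellation: Parcellation | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Cohort table (without scores) and one contrast map per subject-visit.

    Voxel model:  ``value = subject_offset + is_survivor * delta_visit *
    [voxel in planted regions] + N(0, noise_sd)``.  Attrition keeps the
    first-enrolled subjects, so later visits are strict subsets.
    """
    config = config or SyntheticConfig()
    parcellation = parcellation or generate_parcellation(config)
    rng = rng or np.random.default_rng(config.seed)
    planted = config.planted(parcellation)
    planted_mask = np.isin(parcellation.labels, planted)
    cohort = _roster(config)
    subjects = sorted(cohort["subject"].unique())
    offsets = {s: rng.normal(0.0, config.subject_sd) for s in subjects}
    maps: dict[tuple[str, str], np.ndarray] = {}
    for row in cohort.itertuples(index=False):
        delta = config.effect_sizes[VISITS.index(row.visit)] * config.noise_sd
        m = rng.normal(0.0, config.noise_sd, size=config.grid_shape)
        m += offsets[row.subject]
        if row.group == "survivor" and delta > 0:
            m[planted_mask] += delta
        maps[(row.subject, row.visit)] = m
    return validate_cohort(cohort), maps


def _planted_signal(
    maps: dict[tuple[str, str], np.ndarray],
    cohort: pd.DataFrame,
    parcellation: Parcellation,
    planted: Iterable[int],
) -> pd.Series:
    coords = parcellation.voxels_of(planted)
    ii, jj, kk = coords[:, 0], coords[:, 1], coords[:, 2]
    vals = {}
    for row in cohort.itertuples(index=False):
        key = (row.subject, row.visit)
        vals[key] = float(maps[key][ii, jj, kk].mean())
    return pd.Series(vals)


def generate_scores(
    cohort: pd.DataFrame,
    maps: dict[tuple[str, str], np.ndarray],
    config: SyntheticConfig,
    parcellation: Parcellation,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill the seven reading scores into the cohort table.

    Score model per test:  ``100 + 15 * (rho * z + sqrt(1-rho^2) * eps)``
    with ``z`` the subject-visit planted-region signal standardized across
    the cohort and ``eps ~ N(0, 1)``; a small fraction of scores is then
    removed at random (missing completely at random).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    cohort = cohort.copy()
    latent = _planted_signal(maps, cohort, parcellation,
                             config.planted(parcellation))
    z = (latent - latent.mean()) / latent.std(ddof=0)
    keys = list(zip(cohort["subject"], cohort["visit"]))
    zv = z.loc[keys].to_numpy()
    rho = config.rho
    for test in READING_TESTS:
        r = rho[test]
        eps = rng.normal(0.0, 1.0, size=len(cohort))
        score = 100.0 + 15.0 * (r * zv + np.sqrt(1.0 - r * r) * eps)
        if config.score_missing_frac > 0:
            drop = rng.random(len(cohort)) < config.score_missing_frac
            score = np.where(drop, np.nan, score)
        cohort[test] = score
    return cohort


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[Parcellation, pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Full synthetic dataset: parcellation, scored cohort, contrast maps."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    parcellation = generate_parcellation(config)
    cohort, maps = generate_cohort(config, parcellation, rng)
    cohort = generate_scores(cohort, maps, config, parcellation, rng)
    return parcellation, cohort, maps


def generate_series(
    contrast_map: np.ndarray,
    timeline: ParadigmTimeline | None = None,
    noise_sd: float | None = None,
    baseline: float = 100.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """4D block-design series whose Letter>Color contrast recovers a map.

    Letter-naming volumes carry the map as an added amplitude; all other
    volumes sit at baseline.  The per-volume noise SD defaults to
    ``sqrt(n_letter*n_color/(n_letter+n_color))`` times 1, so the temporal-
    average contrast has unit-variance noise when the map itself is
    noise-free — matching the direct map generator's scale.
    """
    timeline = timeline or build_timeline()
    rng = rng or np.random.default_rng(0)
    shift = timeline.hrf_shift_volumes
    letter_idx = condition_volume_indices(timeline, "LETTER", shift)
    color_idx = condition_volume_indices(timeline, "COLOR", shift)
    if noise_sd is None:
        nl, nc = len(letter_idx), len(color_idx)
        noise_sd = float(np.sqrt(nl * nc / (nl + nc)))
    shape = contrast_map.shape + (timeline.n_volumes,)
    series = rng.normal(baseline, noise_sd, size=shape)
    series[..., letter_idx] += contrast_map[..., None]
    return series
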