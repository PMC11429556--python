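"""Parcellation handling and feature extraction from contrast maps.

Two feature granularities feed the analysis, mirroring its two stages:

* **region means** — each contrast map is spatially averaged within every
  atlas region; these region-wise values are what the Fisher-score filter
  ranks;
* **voxel features** — the raw voxel values inside a chosen region set;
  these are the multivariate features handed to the SVM.

The parcellation is an integer label volume (0 = background) plus a region
table carrying name, hemisphere, and the contralateral-homolog link used to
mirror a region set into the opposite hemisphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .paradigm import ContrastMap

__all__ = [
    "Parcellation",
    "RegionFeatureMatrix",
    "VoxelFeatureMatrix",
    "region_means",
    "stack_region_features",
    "voxel_features",
    "contralateral_homolog",
]

TABLE_COLUMNS = ("label", "name", "hemisphere", "homolog_label")


@dataclass(frozen=True)
class Parcellation:
    """Labeled volume plus region table.

    ``table`` columns: ``label`` (int, > 0), ``name``, ``hemisphere``
    (one of L/R/midline), ``homolog_label`` (int label of the mirror region,
    or <NA> for midline regions).
    """

    labels: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        tbl = self.table
        missing = set(TABLE_COLUMNS) - set(tbl.columns)
        if missing:
            raise ValueError(f"region table is missing columns {sorted(missing)}")
        if tbl["label"].duplicated().any():
            raise ValueError("region table has duplicate labels")
        if (tbl["label"] <= 0).any():
            raise ValueError("region labels must be positive (0 is background)")
        bad_hemi = set(tbl["hemisphere"]) - {"L", "R", "midline"}
        if bad_hemi:
            raise ValueError(f"unknown hemisphere values {sorted(bad_hemi)}")
        present = set(np.unique(self.labels)) - {0}
        known = set(tbl["label"].tolist())
        orphans = present - known
        if orphans:
            raise ValueError(
                f"labels present in the volume but absent from the table: {sorted(orphans)}"
            )
        # homolog links must be symmetric and cross-hemispheric
        by_label = tbl.set_index("label")
        for lab, row in by_label.iterrows():
            hom = row["homolog_label"]
            if pd.isna(hom):
                continue
            hom = int(hom)
            if hom not in by_label.index:
                raise ValueError(f"region {lab}: homolog {hom} not in table")
            back = by_label.loc[hom, "homolog_label"]
            if pd.isna(back) or int(back) != lab:
                raise ValueError(f"homolog link {lab}<->{hom} is not symmetric")
            if by_label.loc[hom, "hemisphere"] == row["hemisphere"]:
                raise ValueError(
                    f"homolog pair {lab}<->{hom} lies in the same hemisphere"
                )

    @property
    def region_labels(self) -> list[int]:
        """All region labels, in table order (the canonical column order)."""
        return [int(x) for x in self.table["label"]]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region_name(self, label: int) -> str:
        row = self.table.loc[self.table["label"] == label]
        if row.empty:
            raise KeyError(f"no region with label {label}")
        return str(row["name"].iloc[0])

    def voxels_of(self, region_set: Iterable[int]) -> np.ndarray:
        """Coordinates (n, 3) of all voxels in the union of the regions,
        in lexicographic (i, j, k) order — the fixed voxel-column ordering."""
        region_set = sorted(set(int(r) for r in region_set))
        unknown = set(region_set) - set(self.region_labels)
        if unknown:
            raise KeyError(f"labels not in the parcellation table: {sorted(unknown)}")
        mask = np.isin(self.labels, region_set)
        coords = np.argwhere(mask)  # argwhere is already lexicographic
        return coords

    # -- I/O ---------------------------------------------------------------

    def to_files(self, label_path: str | Path, table_path: str | Path,
                 affine: np.ndarray | None = None) -> None:
        import nibabel as nib

        if affine is None:
            affine = np.eye(4)
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine),
                 str(label_path))
        self.table.to_csv(table_path, index=False)

    @classmethod
    def from_files(cls, label_path: str | Path, table_path: str | Path) -> "Parcellation":
        import nibabel as nib

        img = nib.load(str(label_path))
        labels = np.asarray(img.dataobj).astype(np.int64)
        table = pd.read_csv(table_path)
        if "homolog_label" in table.columns:
            table["homolog_label"] = table["homolog_label"].astype("Int64")
        return cls(labels=labels, table=table)


def _sample_meta(cohort: pd.DataFrame, keys: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Row metadata (subject, visit, group) for the given sample keys."""
    lut = cohort.set_index(["subject", "visit"])
    rows = []
    for subject, visit in keys:
        if (subject, visit) not in lut.index:
            raise KeyError(f"({subject}, {visit}) not found in the cohort table")
        rows.append(
            {"subject": subject, "visit": visit,
             "group": lut.loc[(subject, visit), "group"]}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegionFeatureMatrix:
    """Samples x regions matrix of region-mean contrasts.

    ``values``: DataFrame, one row per (subject, visit), columns = region
    labels in table order; ``meta``: aligned DataFrame with subject, visit,
    group.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.values) != len(self.meta):
            raise ValueError("values and meta row counts differ")

    def for_visit(self, visit: str) -> "RegionFeatureMatrix":
        keep = (self.meta["visit"] == visit).to_numpy()
        return RegionFeatureMatrix(
            values=self.values.loc[keep].reset_index(drop=True),
            meta=self.meta.loc[keep].reset_index(drop=True),
        )

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta.reset_index(drop=True),
                         self.values.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class VoxelFeatureMatrix:
    """Samples x voxels matrix restricted to a stated region set.

    ``values``: (n_samples, n_voxels) array; ``coords``: (n_voxels, 3) voxel
    coordinates in fixed lexicographic (i, j, k) order; ``meta`` as in
    :class:`RegionFeatureMatrix`; ``region_set``: the labels the columns
    were drawn from.
    """

    values: np.ndarray
    coords: np.ndarray
    meta: pd.DataFrame
    region_set: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.meta):
            raise ValueError("values and meta row counts differ")
        if self.values.shape[1] != self.coords.shape[0]:
            raise ValueError("column count does not match coordinate count")

    def for_visit(self, visit: str) -> "VoxelFeatureMatrix":
        keep = (self.meta["visit"] == visit).to_numpy()
        return VoxelFeatureMatrix(
            values=self.values[keep],
            coords=self.coords,
            meta=self.meta.loc[keep].reset_index(drop=True),
            region_set=self.region_set,
        )

    def select_rows(self, keep: np.ndarray) -> "VoxelFeatureMatrix":
        return VoxelFeatureMatrix(
            values=self.values[keep],
            coords=self.coords,
            meta=self.meta.loc[keep].reset_index(drop=True),
            region_set=self.region_set,
        )

    def to_csv(self, path: str | Path) -> None:
        cols = ["v_" + "_".join(map(str, c)) for c in self.coords]
        out = pd.concat(
            [self.meta.reset_index(drop=True),
             pd.DataFrame(self.values, columns=cols)], axis=1)
        with open(path, "w") as fh:
            fh.write(f"# region_set: {','.join(map(str, self.region_set))}\n")
            out.to_csv(fh, index=False)


def _as_map_dict(
    maps: Mapping[tuple[str, str], np.ndarray] | Iterable[ContrastMap],
) -> dict[tuple[str, str], np.ndarray]:
    if isinstance(maps, Mapping):
        return {k: np.asarray(v) for k, v in maps.items()}
    out: dict[tuple[str, str], np.ndarray] = {}
    for m in maps:
        key = (m.subject, m.visit)
        if key in out:
            raise ValueError(f"duplicate contrast map for {key}")
        out[key] = m.data
    return out


def region_means(
    contrast: np.ndarray | ContrastMap,
    parcellation: Parcellation,
) -> pd.Series:
    """Mean contrast per atlas region.

    Returns a Series indexed by region label (table order).  Regions with no
    voxels in the label volume are flagged with a warning and set to NaN —
    never silently zero.
    """
    data = contrast.data if isinstance(contrast, ContrastMap) else np.asarray(contrast)
    if data.shape != parcellation.grid_shape:
        raise ValueError(
            f"map grid {data.shape} does not match parcellation grid "
            f"{parcellation.grid_shape}"
        )
    labels = parcellation.labels.ravel()
    flat = data.ravel().astype(float)
    region_ids = parcellation.region_labels
    maxlab = int(labels.max(initial=0))
    sums = np.bincount(labels, weights=flat, minlength=maxlab + 1)
    counts = np.bincount(labels, minlength=maxlab + 1)
    out = pd.Series(index=region_ids, dtype=float, name="region_mean")
    empty = []
    for lab in region_ids:
        if lab <= maxlab and counts[lab] > 0:
            out[lab] = sums[lab] / counts[lab]
        else:
            out[lab] = np.nan
            empty.append(lab)
    if empty:
        warnings.warn(
            f"regions with zero voxels set to missing: {empty}", stacklevel=2
        )
    return out


def stack_region_features(
    maps: Mapping[tuple[str, str], np.ndarray] | Iterable[ContrastMap],
    parcellation: Parcellation,
    cohort: pd.DataFrame,
) -> RegionFeatureMatrix:
    """Region-mean feature matrix over all subject-visits in the cohort.

    Rows are sorted by (subject, visit) so the result is independent of the
    input map ordering; a roster entry without a map is an error.
    """
    map_dict = _as_map_dict(maps)
    roster = cohort[["subject", "visit"]].drop_duplicates()
    keys = sorted((str(s), str(v)) for s, v in roster.itertuples(index=False))
    missing = [k for k in keys if k not in map_dict]
    if missing:
        raise KeyError(f"no contrast map for roster entries: {missing[:5]}")
    rows = [region_means(map_dict[k], parcellation) for k in keys]
    values = pd.DataFrame(rows).reset_index(drop=True)
    values.columns = parcellation.region_labels
    meta = _sample_meta(cohort, keys)
    return RegionFeatureMatrix(values=values, meta=meta)


def voxel_features(
    maps: Mapping[tuple[str, str], np.ndarray] | Iterable[ContrastMap],
    parcellation: Parcellation,
    region_set: Iterable[int],
    cohort: pd.DataFrame,
) -> VoxelFeatureMatrix:
    """Voxel-level feature matrix restricted to the union of ``region_set``.

    Column order is the fixed lexicographic (i, j, k) ordering so that SVM
    weight maps are reproducible run to run; requesting a region twice does
    not duplicate its voxels.
    """
    region_set = tuple(sorted(set(int(r) for r in region_set)))
    if not region_set:
        raise ValueError("region_set must be nonempty")
    coords = parcellation.voxels_of(region_set)
    if coords.shape[0] == 0:
        raise ValueError(f"regions {region_set} contain no voxels")
    map_dict = _as_map_dict(maps)
    roster = cohort[["subject", "visit"]].drop_duplicates()
    keys = sorted((str(s), str(v)) for s, v in roster.itertuples(index=False))
    missing = [k for k in keys if k not in map_dict]
    if missing:
        raise KeyError(f"no contrast map for roster entries: {missing[:5]}")
    ii, jj, kk = coords[:, 0], coords[:, 1], coords[:, 2]
    values = np.empty((len(keys), coords.shape[0]), dtype=float)
    for r, k in enumerate(keys):
        m = map_dict[k]
        if m.shape != parcellation.grid_shape:
            raise ValueError(f"map for {k} has grid {m.shape}")
        values[r] = m[ii, jj, kk]
    meta = _sample_meta(cohort, keys)
    return VoxelFeatureMatrix(values=values, coords=coords, meta=meta,
                              region_set=region_set)


def contralateral_homolog(
    region_set: Iterable[int], parcellation: Parcellation
) -> set[int]:
    """Mirror a region set into the opposite hemisphere via homolog links.

    Midline regions (no homolog) are an error; by symmetry of the links,
    applying this twice returns the input set.
    """
    by_label = parcellation.table.set_index("label")
    out: set[int] = set()
    missing: list[int] = []
    for lab in sorted(set(int(r) for r in region_set)):
        if lab not in by_label.index:
            raise KeyError(f"label {lab} not in the parcellation table")
        hom = by_label.loc[lab, "homolog_label"]
        if pd.isna(hom):
            missing.append(lab)
        else:
            out.add(int(hom))
    if missing:
        raise ValueError(f"regions without a contralateral homolog: {missing}")
    return out
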