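"""File-level I/O: NIfTI volumes, dataset directories, and result tables.

A *dataset directory* is the on-disk interchange format between pipeline
stages::

    dataset/
      parcellation.nii.gz   integer label volume
      regions.csv           label,name,hemisphere,homolog_label
      cohort.csv            subject,group,visit,<seven reading scores>
      maps/<subject>_<visit>.nii.gz   one Letter>Color contrast map each
      manifest.yaml         generator / provenance metadata

The affine of an input series is propagated unchanged to maps derived from
it; synthetic volumes use an identity affine.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .atlas import Parcellation
from .cohort import load_cohort

__all__ = [
    "load_volume",
    "save_volume",
    "save_dataset",
    "load_dataset",
]


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, nib.Nifti1Header]:
    """Read a NIfTI volume; returns (data, affine, header)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine, img.header


def save_volume(
    data: np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
    header: nib.Nifti1Header | None = None,
) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine, header), str(path))


def save_dataset(
    out_dir: str | Path,
    parcellation: Parcellation,
    cohort: pd.DataFrame,
    maps: dict[tuple[str, str], np.ndarray],
    manifest: dict | None = None,
) -> Path:
    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    parcellation.to_files(out / "parcellation.nii.gz", out / "regions.csv")
    cohort.to_csv(out / "cohort.csv", index=False)
    for (subject, visit), m in maps.items():
        save_volume(m.astype(np.float32), out / "maps" / f"{subject}_{visit}.nii.gz")
    if manifest is not None:
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return out


def load_dataset(
    data_dir: str | Path,
) -> tuple[Parcellation, pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    data_dir = Path(data_dir)
    parcellation = Parcellation.from_files(
        data_dir / "parcellation.nii.gz", data_dir / "regions.csv"
    )
    cohort = load_cohort(data_dir / "cohort.csv")
    maps: dict[tuple[str, str], np.ndarray] = {}
    for row in cohort.itertuples(index=False):
        path = data_dir / "maps" / f"{row.subject}_{row.visit}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing contrast map {path}")
        maps[(row.subject, row.visit)] = np.asarray(
            nib.load(str(path)).dataobj, dtype=float
        )
    return parcellation, cohort, maps
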