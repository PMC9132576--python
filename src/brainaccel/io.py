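"""Readers and writers for the delimited-text and NIfTI formats used throughout.

All tabular artifacts (cohorts, regional volumes, cognitive scores, effect
maps, matched pairs, study summaries, meta-analysis results) are plain
comma-separated text with a header row.  Volumetric data (4D BOLD series,
masks, region label volumes, ALFF and z maps) are NIfTI-1 files handled by
nibabel, with the repetition time stored in the header.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a comma-separated table with a header row."""
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, index=index)


def write_nifti(
    data: np.ndarray,
    path: str | os.PathLike,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tr: float | None = None,
) -> None:
    """Write a 3D or 4D array as NIfTI-1 with isotropic-or-not voxel sizes in mm.

    For 4D data ``tr`` (seconds) is stored as the fourth zoom, the convention
    functional time series use.
    """
    affine = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = list(voxel_size)
    if data.ndim == 4:
        if tr is None:
            raise ValueError("tr is required when writing 4D time-series data")
        zooms.append(tr)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(tuple(zooms))
    nib.save(img, str(path))


def read_nifti(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a NIfTI file; returns (data array, header zooms).

    For 4D images the fourth zoom is the repetition time in seconds.
    """
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), tuple(float(z) for z in img.header.get_zooms())
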