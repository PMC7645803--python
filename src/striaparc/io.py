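"""On-disk formats: NIfTI volumes, atlas label tables, subject and results tables.

Coordinate conventions: voxel indices are 0-based; world space is whatever the
NIfTI affine defines (no silent reorientation). PET and fMRI inputs must share
a grid — shape equality plus affine agreement within 1e-4 mm — since
registration is upstream preprocessing, out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AFFINE_ATOL_MM = 1e-4


@dataclass
class BrainVolume:
    """A 3-D scalar image (e.g. a voxelwise Ki parametric map) with its affine.

    ``mask``, when present, marks the voxels whose values are meaningful;
    values outside the mask may be NaN.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got {self.data.ndim}-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data shape")
            if not np.all(np.isfinite(self.data[self.mask])):
                raise ValueError("non-finite values inside mask")
        elif not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in unmasked volume")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def in_mask_values(self) -> np.ndarray:
        """Values at in-mask voxels, in sorted flat-index order."""
        if self.mask is None:
            return self.data.ravel()
        return self.data[self.mask]


@dataclass
class TimeSeries4D:
    """A 4-D BOLD run (x, y, z, t) with its affine and repetition time."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got {self.data.ndim}-D")
        if self.data.shape[3] < 2:
            raise ValueError("time series needs at least 2 timepoints")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class AtlasLabels:
    """Integer label volume plus its node table.

    Label 0 is background.  ``table`` is indexed by label id and carries a
    ``name`` column and, optionally, a ``network`` column with reference
    resting-state-network names used for community naming.
    """

    labels: np.ndarray
    table: pd.DataFrame
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3-D label volume, got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        present = np.unique(self.labels)
        present = present[present != 0]
        missing = sorted(set(present.tolist()) - set(self.table.index.tolist()))
        if missing:
            raise ValueError(f"label ids present in volume but absent from table: {missing}")
        if self.n_nodes == 0:
            logger.warning("atlas has no labelled voxels / empty node table")

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def node_ids(self) -> np.ndarray:
        return np.asarray(self.table.index, dtype=int)

    @property
    def reference_networks(self) -> pd.Series | None:
        if "network" in self.table.columns:
            return self.table["network"]
        return None


@dataclass
class SubjectTable:
    """Cohort bookkeeping: one row per subject with group labels and file paths."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.rows) and not self.rows.index.is_unique:
            raise ValueError("subject ids must be unique")

    @property
    def subject_ids(self) -> list:
        return list(self.rows.index)

    def groups(self) -> pd.Series:
        if "group" not in self.rows.columns:
            raise ValueError("subject table has no 'group' column")
        bad = set(self.rows["group"].unique()) - {"patient", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        return self.rows["group"]


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, nib.Nifti1Header]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), np.asarray(img.affine, dtype=float), img.header


def read_volume(path: str | Path, mask: np.ndarray | None = None) -> BrainVolume:
    """Read a 3-D NIfTI volume. The affine comes from the header (sform/qform)."""
    data, affine, _ = _load_nifti(path)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D image at {path}, got {data.ndim}-D")
    return BrainVolume(data=data.astype(np.float64, copy=False), affine=affine, mask=mask)


def read_timeseries(path: str | Path, tr_seconds: float | None = None) -> TimeSeries4D:
    """Read a 4-D NIfTI run. TR is taken from the header unless overridden."""
    data, affine, header = _load_nifti(path)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D image at {path}, got {data.ndim}-D")
    if tr_seconds is None:
        zooms = header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return TimeSeries4D(
        data=data.astype(np.float64, copy=False), affine=affine, tr_seconds=tr_seconds
    )


def write_volume(vol: BrainVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine).to_filename(str(path))
    return path


def write_timeseries(ts: TimeSeries4D, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(ts.data, dtype=np.float64), ts.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = ts.tr_seconds
    img.header.set_zooms(zooms)
    img.to_filename(str(path))
    return path


def read_atlas(label_path: str | Path, table_path: str | Path) -> AtlasLabels:
    """Read a cortical atlas: integer label NIfTI plus TSV node table.

    The table must contain ``label`` and ``name`` columns; an optional
    ``network`` column carries reference network names per node.
    """
    data, affine, _ = _load_nifti(label_path)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D label image at {label_path}, got {data.ndim}-D")
    labels = np.rint(data).astype(np.int64)
    table = pd.read_csv(table_path, sep="\t")
    if "label" not in table.columns or "name" not in table.columns:
        raise ValueError("atlas table needs 'label' and 'name' columns")
    table = table.set_index("label")
    return AtlasLabels(labels=labels, table=table, affine=affine)


def read_subject_table(path: str | Path) -> SubjectTable:
    rows = pd.read_csv(path, sep="\t").set_index("subject")
    return SubjectTable(rows=rows)


def write_results_table(records: list[dict], path: str | Path) -> Path:
    """Write a list of records as TSV with deterministic row and column order.

    Columns are ordered by first appearance then alphabetically for extras;
    rows are sorted lexicographically over their stringified values so two
    runs with the same results produce byte-identical files.
    """
    path = Path(path)
    df = pd.DataFrame.from_records(records)
    if len(df):
        df = df.sort_values(by=list(df.columns), key=lambda c: c.astype(str), kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def check_shared_grid(*objs) -> None:
    """Require identical shapes (spatial) and affines within 1e-4 mm."""
    ref_shape, ref_affine = None, None
    for obj in objs:
        shape = obj.data.shape[:3] if hasattr(obj, "data") else obj.labels.shape
        affine = obj.affine
        if ref_shape is None:
            ref_shape, ref_affine = shape, affine
            continue
        if shape != ref_shape:
            raise ValueError(f"grid mismatch: shapes {ref_shape} vs {shape}")
        if affine is not None and ref_affine is not None:
            if not np.allclose(affine, ref_affine, atol=AFFINE_ATOL_MM):
                raise ValueError("grid mismatch: affines differ by more than 1e-4 mm")
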