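"""Reading and writing uptake tables, networks, and ROI extraction from volumes.

The tabular format is plain delimited text (comma by default, tab via
``delimiter``): one header row of ROI labels, one row per subject with the
subject identifier in the first column, and an optional ``group`` column
holding the diagnostic label.  Networks are stored either as a labelled
square matrix or as a three-column edge list; both round-trip losslessly.

ROI mean uptake can also be extracted directly from a 3-D intensity volume
paired with an integer-label atlas (NIfTI-1 via nibabel).  Inputs are
assumed spatially preprocessed (aligned to the atlas space); no intensity
normalization is applied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import WeightedNetwork

__all__ = [
    "ImageVolume",
    "LabelAtlas",
    "SUVTable",
    "roi_mean_suv",
    "read_suv_table",
    "write_suv_table",
    "read_network",
    "write_network",
    "load_volume",
    "load_atlas",
]

GROUP_COLUMN = "group"


@dataclass
class ImageVolume:
    """3-D array of uptake intensities (arbitrary units)."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"volume must be 3-D with positive dims, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite voxels")
        self.voxels = v


@dataclass
class LabelAtlas:
    """Integer ROI labels on the same grid as a paired volume; 0 = background."""

    labels: np.ndarray
    roi_codes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("atlas must be 3-D")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise ValueError("atlas labels must be integers")
            lab = lab.astype(np.int64)
        if lab.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        self.labels = lab
        if not self.roi_codes:
            self.roi_codes = [int(c) for c in np.unique(lab) if c != 0]
        if 0 in self.roi_codes:
            raise ValueError("background label 0 cannot be an ROI")


@dataclass
class SUVTable:
    """Subject x ROI matrix of mean uptake values for one diagnostic group."""

    values: np.ndarray
    subject_ids: list[str]
    roi_labels: list[str]
    group: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (subjects x ROIs)")
        k, n = v.shape
        if k < 2:
            raise ValueError(f"need at least 2 subjects, got {k}")
        if n < 3:
            raise ValueError(f"need at least 3 ROIs, got {n}")
        if not np.all(np.isfinite(v)):
            bad = np.argwhere(~np.isfinite(v))[0]
            raise ValueError(
                f"non-finite value at subject row {bad[0]}, ROI column {bad[1]}"
            )
        if len(self.subject_ids) != k:
            raise ValueError("subject_ids length does not match values")
        if len(self.roi_labels) != n:
            raise ValueError("roi_labels length does not match values")
        if len(set(self.roi_labels)) != n:
            raise ValueError("roi_labels must be unique")
        self.values = v
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.roi_labels = [str(r) for r in self.roi_labels]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_roi(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray, group: str | None = None) -> "SUVTable":
        """New table restricted to the given subject row indices."""
        rows = np.asarray(rows)
        return SUVTable(
            values=self.values[rows],
            subject_ids=[self.subject_ids[i] for i in rows],
            roi_labels=list(self.roi_labels),
            group=self.group if group is None else group,
        )


def roi_mean_suv(volume: ImageVolume, atlas: LabelAtlas) -> np.ndarray:
    """Mean uptake per ROI: the arithmetic mean of voxel values within each label.

    Returns one vector of N means ordered as ``atlas.roi_codes`` — a single
    subject's row of an :class:`SUVTable`.
    """
    if volume.voxels.shape != atlas.labels.shape:
        raise ValueError(
            f"volume shape {volume.voxels.shape} does not match atlas "
            f"shape {atlas.labels.shape}"
        )
    flat_v = volume.voxels.ravel()
    flat_l = atlas.labels.ravel()
    means = np.empty(len(atlas.roi_codes), dtype=float)
    for idx, code in enumerate(atlas.roi_codes):
        sel = flat_l == code
        count = int(sel.sum())
        if count == 0:
            raise ValueError(f"ROI code {code} has no voxels in the atlas")
        means[idx] = flat_v[sel].sum() / count
    return means


def load_volume(path: str | Path) -> ImageVolume:
    import nibabel as nib

    img = nib.load(str(path))
    return ImageVolume(voxels=np.asarray(img.get_fdata(), dtype=float))


def load_atlas(path: str | Path, roi_codes: list[int] | None = None) -> LabelAtlas:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    return LabelAtlas(labels=np.round(data).astype(np.int64), roi_codes=roi_codes or [])


def _fmt(x: float) -> str:
    return repr(float(x))


def write_suv_table(table: SUVTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a table as delimited text; floats use shortest round-trip form."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        header = ["subject_id", *table.roi_labels]
        if table.group:
            header.append(GROUP_COLUMN)
        writer.writerow(header)
        for i, sid in enumerate(table.subject_ids):
            row = [sid, *(_fmt(x) for x in table.values[i])]
            if table.group:
                row.append(table.group)
            writer.writerow(row)


def read_suv_table(path: str | Path, delimiter: str = ",") -> SUVTable:
    """Read a subject x ROI table; inverse of :func:`write_suv_table`."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(delimiter)[1:]
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise ValueError(f"duplicate ROI label: {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    group = ""
    if GROUP_COLUMN in df.columns:
        groups = df[GROUP_COLUMN].unique()
        if len(groups) != 1:
            raise ValueError(f"multiple group labels in one table: {sorted(groups)}")
        group = str(groups[0])
        df = df.drop(columns=[GROUP_COLUMN])
    roi_labels = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = df.iat[i, j]
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"missing or non-numeric cell at subject {df.index[i]!r}, "
                    f"ROI {roi_labels[j]!r}"
                ) from None
    return SUVTable(
        values=values,
        subject_ids=[str(s) for s in df.index],
        roi_labels=roi_labels,
        group=group,
    )


def write_network(
    network: WeightedNetwork,
    path: str | Path,
    delimiter: str = ",",
    fmt: str = "matrix",
) -> None:
    """Write a network as a labelled square matrix or a 3-column edge list.

    Absent edges (after filtering) are written as empty cells in matrix
    form and simply omitted from an edge list.
    """
    mask = network.edge_mask()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        if fmt == "matrix":
            writer.writerow(["roi", *network.roi_labels])
            for i, lab in enumerate(network.roi_labels):
                row: list[str] = [lab]
                for j in range(network.n_roi):
                    if i == j:
                        row.append(_fmt(0.0))
                    elif mask[i, j]:
                        row.append(_fmt(network.weights[i, j]))
                    else:
                        row.append("")
                writer.writerow(row)
        elif fmt == "edgelist":
            writer.writerow(["roi_a", "roi_b", "weight"])
            for i in range(network.n_roi):
                for j in range(i + 1, network.n_roi):
                    if mask[i, j]:
                        writer.writerow(
                            [network.roi_labels[i], network.roi_labels[j],
                             _fmt(network.weights[i, j])]
                        )
        else:
            raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, delimiter: str = ",") -> WeightedNetwork:
    """Read a network written by :func:`write_network` (either format).

    A three-column header (``roi_a, roi_b, weight``) is parsed as an edge
    list; anything else must be a labelled square matrix.  Asymmetry beyond
    1e-8 and negative weights are rejected.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if list(df.columns) == ["roi_b", "weight"]:
        return _network_from_edgelist(pd.read_csv(path, sep=delimiter))
    labels = [str(c) for c in df.columns]
    row_labels = [str(r) for r in df.index]
    if labels != row_labels:
        raise ValueError("row labels do not match column labels")
    raw = df.to_numpy(dtype=float)
    present = ~np.isnan(raw)
    if not np.array_equal(present, present.T):
        raise ValueError("edge presence pattern is not symmetric")
    w = np.where(present, raw, 0.0)
    if not np.allclose(w, w.T, atol=1e-8, rtol=0.0):
        ij = np.argwhere(np.abs(w - w.T) > 1e-8)[0]
        raise ValueError(
            f"asymmetric weights at ({labels[ij[0]]}, {labels[ij[1]]})"
        )
    if w.min() < 0:
        raise ValueError("negative edge weights are not allowed")
    mask = present.copy()
    np.fill_diagonal(mask, False)
    complete = bool(np.all(mask == ~np.eye(len(labels), dtype=bool)))
    return WeightedNetwork(
        weights=w, roi_labels=labels, mask=None if complete else mask
    )


def _network_from_edgelist(df: pd.DataFrame) -> WeightedNetwork:
    labels = sorted(set(df["roi_a"].astype(str)) | set(df["roi_b"].astype(str)))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    w = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for a, b, wt in df.itertuples(index=False):
        wt = float(wt)
        if wt < 0:
            raise ValueError(f"negative weight on edge ({a}, {b})")
        i, j = index[str(a)], index[str(b)]
        if i == j:
            raise ValueError(f"self-loop on {a}")
        if mask[i, j] and abs(w[i, j] - wt) > 1e-8:
            raise ValueError(f"conflicting duplicate edge ({a}, {b})")
        w[i, j] = w[j, i] = wt
        mask[i, j] = mask[j, i] = True
    complete = bool(np.all(mask == ~np.eye(n, dtype=bool)))
    return WeightedNetwork(weights=w, roi_labels=labels, mask=None if complete else mask)
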