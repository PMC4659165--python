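"""Voxel stacks, label volumes and detection tables.

Conventions shared by every module:

* Voxel grids are indexed ``(x, y, z)``, 0-based, half-open ranges.
* Physical coordinates are in micrometres, ``um = index * spacing``
  (voxel-centre convention), with ``spacing = (sx, sy, sz)`` in μm/voxel.
* TIFF files store pages along z with rows = y and columns = x, so arrays
  are transposed on load/save; a label TIFF stores the cell index as the
  pixel value (0 = background).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelStack",
    "DetectionSet",
    "load_stack",
    "save_stack",
    "load_labels",
    "save_labels",
    "load_detections",
    "save_detections",
]


@dataclass
class VoxelStack:
    """A single-channel 3-D intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    data
        3-D array indexed ``(x, y, z)``; finite and non-negative.
    spacing
        ``(sx, sy, sz)`` voxel spacing in μm.
    name
        Channel name, e.g. ``"dna"`` or ``"membrane"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def to_um(self, indices: np.ndarray) -> np.ndarray:
        """Voxel indices ``(n, 3)`` -> physical μm coordinates."""
        return np.asarray(indices, dtype=float) * np.asarray(self.spacing)

    def to_voxel(self, coords_um: np.ndarray) -> np.ndarray:
        """Physical μm coordinates ``(n, 3)`` -> nearest voxel indices."""
        idx = np.rint(np.asarray(coords_um, dtype=float) / np.asarray(self.spacing))
        return idx.astype(int)

    def bounds_um(self) -> np.ndarray:
        """Upper physical bound per axis (half-open)."""
        return np.asarray(self.shape) * np.asarray(self.spacing)


@dataclass
class DetectionSet:
    """Candidate cell centres in physical coordinates.

    ``coords_um`` is ``(n, 3)``; ``scores`` ``(n,)``; ``scales`` holds the
    detector scale factor per detection (NaN when absent); ``labels`` is a
    list of string sets, e.g. ``{"M-phase"}``.
    """

    coords_um: np.ndarray
    scores: np.ndarray
    scales: np.ndarray | None = None
    labels: list[set] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords_um = np.atleast_2d(np.asarray(self.coords_um, dtype=float))
        if self.coords_um.size == 0:
            self.coords_um = self.coords_um.reshape(0, 3)
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        if self.coords_um.shape[0] != self.scores.shape[0]:
            raise ValueError("coords and scores length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("detection scores must be finite")
        if self.scales is not None:
            self.scales = np.asarray(self.scales, dtype=float).reshape(-1)
        if not self.labels:
            self.labels = [set() for _ in range(len(self))]

    def __len__(self) -> int:
        return self.coords_um.shape[0]

    def order_by_score(self) -> "DetectionSet":
        """Descending score, stable for ties (insertion order)."""
        order = np.argsort(-self.scores, kind="stable")
        return DetectionSet(
            self.coords_um[order],
            self.scores[order],
            None if self.scales is None else self.scales[order],
            [self.labels[i] for i in order],
        )


def load_stack(path, spacing, name: str = "") -> VoxelStack | list[VoxelStack]:
    """Load a single- or multi-channel TIFF stack.

    Multi-page TIFFs are read as z-stacks; a 4-D (z, c, y, x) file is split
    into one :class:`VoxelStack` per channel (named ``name_0``, ``name_1``,
    ...). Returns a single stack for single-channel input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"non-numeric pixel type {arr.dtype}")
    if arr.ndim == 2:  # single plane -> (x, y, 1)
        arr = arr[None, ...]
    if arr.ndim == 3:
        data = np.ascontiguousarray(arr.transpose(2, 1, 0))
        return VoxelStack(data, spacing, name)
    if arr.ndim == 4:  # (z, c, y, x)
        stacks = []
        for c in range(arr.shape[1]):
            data = np.ascontiguousarray(arr[:, c].transpose(2, 1, 0))
            stacks.append(VoxelStack(data, spacing, f"{name}_{c}" if name else str(c)))
        return stacks
    raise ValueError(f"unsupported TIFF dimensionality {arr.ndim}")


def save_stack(stack: VoxelStack, path) -> None:
    """Write a stack as a multi-page TIFF (pages = z, rows = y, cols = x)."""
    tifffile.imwrite(
        Path(path),
        np.ascontiguousarray(stack.data.transpose(2, 1, 0)),
        photometric="minisblack",
    )


def save_labels(labels: np.ndarray, path) -> None:
    """Write a label volume (pixel value = cell index) as uint16 TIFF."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 65535:
        raise ValueError("label values must fit uint16 (0..65535)")
    tifffile.imwrite(
        Path(path),
        np.ascontiguousarray(labels.transpose(2, 1, 0).astype(np.uint16)),
        photometric="minisblack",
    )


def load_labels(path) -> np.ndarray:
    """Read a label volume written by :func:`save_labels`."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None, ...]
    return np.ascontiguousarray(arr.transpose(2, 1, 0).astype(np.int32))


_DET_COLUMNS = ["id", "x_um", "y_um", "z_um", "score", "scale", "labels"]


def _detections_to_frame(dets: DetectionSet) -> pd.DataFrame:
    n = len(dets)
    scales = dets.scales if dets.scales is not None else np.full(n, np.nan)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "x_um": dets.coords_um[:, 0],
            "y_um": dets.coords_um[:, 1],
            "z_um": dets.coords_um[:, 2],
            "score": dets.scores,
            "scale": scales,
            "labels": [";".join(sorted(s)) for s in dets.labels],
        }
    )


def save_detections(dets: DetectionSet, path) -> None:
    """Write detections as CSV (or JSON for a ``.json`` path)."""
    path = Path(path)
    frame = _detections_to_frame(dets)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
    else:
        frame.to_csv(path, index=False, float_format="%.10g")


def load_detections(path, bounds_um=None) -> DetectionSet:
    """Read a detection table; warn (not fail) on out-of-bounds coordinates."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()))
    else:
        frame = pd.read_csv(path)
    missing = {"x_um", "y_um", "z_um", "score"} - set(frame.columns)
    if missing:
        raise ValueError(f"malformed detection table, missing columns {sorted(missing)}")
    coords = frame[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    labels = [
        set(str(s).split(";")) if isinstance(s, str) and s else set()
        for s in frame.get("labels", [""] * len(frame))
    ]
    scales = frame["scale"].to_numpy(dtype=float) if "scale" in frame else None
    if bounds_um is not None:
        bounds_um = np.asarray(bounds_um, dtype=float)
        if np.any(coords < 0) or np.any(coords >= bounds_um):
            warnings.warn("detections outside declared stack bounds", stacklevel=2)
    return DetectionSet(coords, frame["score"].to_numpy(dtype=float), scales, labels)
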