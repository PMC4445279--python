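"""Domain types, stack/marker I/O and ROI extraction shared by all stages.

Conventions
-----------
* Volumes are indexed ``(z, y, x)`` with z the slice (page) index.
* Coordinates are 0-based voxel indices written ``(x, y, z)``.
* A box of size ``a x b x c`` means a in x, b in y, c in z, centered:
  ``|dx| <= (a-1)/2`` etc.  All box dimensions must be odd.
* Out-of-bounds access during ROI extraction is filled by mirror
  reflection (the plane at z=-1 mirrors the plane at z=+1), which avoids
  artificial dark borders that would bias intensity features.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile

#: voxel pitch (dx, dy, dz) in nm of the confocal system the defaults target
DEFAULT_VOXEL_SIZE = (80.0, 80.0, 400.0)

_VALID_STATUS = {"raw", "classified", "shifted", "merged", "validated"}


class VoxelCoord(NamedTuple):
    """A 0-based voxel index, ordered (x, y, z)."""

    x: int
    y: int
    z: int

    def zyx(self) -> tuple[int, int, int]:
        return (self.z, self.y, self.x)


@dataclass(frozen=True)
class Marker:
    """A detected or annotated punctum center with provenance flags."""

    coord: VoxelCoord
    score: float = 0.0
    status: frozenset = frozenset({"raw"})

    def with_status(self, *extra: str) -> "Marker":
        bad = set(extra) - _VALID_STATUS
        if bad:
            raise ValueError(f"unknown marker status flags: {sorted(bad)}")
        return replace(self, status=self.status | frozenset(extra))


class MarkerSet:
    """Ordered collection of markers (detected or annotated punctum centers)."""

    def __init__(self, markers: Iterable[Marker] = ()):
        self.markers: list[Marker] = list(markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.markers)

    def __getitem__(self, i):
        return self.markers[i]

    def add(self, coord: VoxelCoord, score: float = 0.0, status: Iterable[str] = ("raw",)) -> None:
        self.markers.append(Marker(coord, float(score), frozenset(status)))

    def coords(self) -> np.ndarray:
        """Marker coordinates as an (n, 3) int array of (x, y, z) rows."""
        if not self.markers:
            return np.empty((0, 3), dtype=int)
        return np.array([[m.coord.x, m.coord.y, m.coord.z] for m in self.markers], dtype=int)

    def scores(self) -> np.ndarray:
        return np.array([m.score for m in self.markers], dtype=float)

    @classmethod
    def from_coords(
        cls,
        coords: Sequence[Sequence[int]],
        scores: Sequence[float] | None = None,
        status: Iterable[str] = ("raw",),
    ) -> "MarkerSet":
        ms = cls()
        for i, c in enumerate(coords):
            s = 0.0 if scores is None else float(scores[i])
            ms.add(VoxelCoord(int(c[0]), int(c[1]), int(c[2])), s, status)
        return ms


@dataclass
class VolumeStack:
    """A 3D intensity grid with voxel-size metadata.

    ``data`` is indexed (z, y, x); intensities are nonnegative.
    ``voxel_size`` is (dx, dy, dz) in nm; dz >= dx = dy is the expected
    (not enforced) confocal anisotropy.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel_name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3D (z, y, x), got ndim={self.data.ndim}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def z_anisotropy(self) -> float:
        """dz / dx — how many xy voxel pitches one z step spans."""
        return self.voxel_size[2] / self.voxel_size[0]

    def contains(self, c: VoxelCoord) -> bool:
        nz, ny, nx = self.data.shape
        return 0 <= c.x < nx and 0 <= c.y < ny and 0 <= c.z < nz


@dataclass
class Roi3D:
    """A small odd-sized sub-volume centered on a voxel of interest."""

    data: np.ndarray  # (d, h, w) indexed (z, y, x)
    center: VoxelCoord
    label: str = "unlabeled"  # {"positive", "negative", "unlabeled"}

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("ROI data must be 3D")
        if any(s % 2 == 0 for s in self.data.shape):
            raise ValueError(f"ROI dimensions must be odd, got {self.data.shape}")
        if self.label not in ("positive", "negative", "unlabeled"):
            raise ValueError(f"invalid ROI label {self.label!r}")

    @property
    def size_xyz(self) -> tuple[int, int, int]:
        d, h, w = self.data.shape
        return (w, h, d)


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: str | os.PathLike,
    channel: int = 0,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    channel_name: str = "",
) -> VolumeStack:
    """Read one channel of a single- or multi-channel multi-page TIFF.

    Page order is preserved as slice (z) order.  A 4D array is interpreted
    as (z, channel, y, x); a 3D array as a single-channel (z, y, x) stack;
    a 2D array as a single slice.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface a format error
        raise ValueError(f"{path}: not a readable TIFF file ({exc})") from exc
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    elif arr.ndim != 4:
        raise ValueError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
    n_channels = arr.shape[1]
    if not 0 <= channel < n_channels:
        raise IndexError(f"channel {channel} out of range for {n_channels}-channel stack")
    return VolumeStack(arr[:, channel], voxel_size=voxel_size, channel_name=channel_name)


def write_stack(stack: VolumeStack, path: str | os.PathLike) -> None:
    """Write a stack as a multi-page grayscale TIFF (one page per z slice)."""
    tifffile.imwrite(path, np.asarray(stack.data))


def write_labels(labels: np.ndarray, path: str | os.PathLike) -> None:
    """Write an integer label grid as a 16-bit multi-page TIFF."""
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be written as 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi(
    volume: VolumeStack | np.ndarray,
    center: VoxelCoord,
    size: tuple[int, int, int] = (9, 9, 3),
    label: str = "unlabeled",
) -> Roi3D:
    """Extract an odd-sized (w, h, d) ROI centered at ``center``.

    Positions falling outside the volume are filled by mirror reflection
    about the border (no edge repetition).
    """
    data = volume.data if isinstance(volume, VolumeStack) else np.asarray(volume)
    w, h, d = size
    if any(s % 2 == 0 or s < 1 for s in size):
        raise ValueError(f"ROI size must be odd and positive, got {size}")
    nz, ny, nx = data.shape
    x, y, z = center.x, center.y, center.z
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise ValueError(f"ROI center {center} outside volume of shape (z,y,x)={data.shape}")
    rx, ry, rz = (w - 1) // 2, (h - 1) // 2, (d - 1) // 2

    z0, z1 = z - rz, z + rz + 1
    y0, y1 = y - ry, y + ry + 1
    x0, x1 = x - rx, x + rx + 1
    if z0 >= 0 and y0 >= 0 and x0 >= 0 and z1 <= nz and y1 <= ny and x1 <= nx:
        block = data[z0:z1, y0:y1, x0:x1].copy()
    else:
        cz0, cz1 = max(z0, 0), min(z1, nz)
        cy0, cy1 = max(y0, 0), min(y1, ny)
        cx0, cx1 = max(x0, 0), min(x1, nx)
        inner = data[cz0:cz1, cy0:cy1, cx0:cx1]
        pads = (
            (cz0 - z0, z1 - cz1),
            (cy0 - y0, y1 - cy1),
            (cx0 - x0, x1 - cx1),
        )
        block = np.pad(inner, pads, mode="reflect")
    return Roi3D(block, center=center, label=label)


# ---------------------------------------------------------------------------
# marker CSV I/O
# ---------------------------------------------------------------------------

def write_markers(markers: MarkerSet, path: str | os.PathLike) -> None:
    """Write markers as a CSV with header ``x,y,z,score,status``."""
    rows = [
        {
            "x": m.coord.x,
            "y": m.coord.y,
            "z": m.coord.z,
            "score": m.score,
            "status": "|".join(sorted(m.status)),
        }
        for m in markers
    ]
    df = pd.DataFrame(rows, columns=["x", "y", "z", "score", "status"])
    df.to_csv(path, index=False, float_format="%.8g")


def read_markers(path: str | os.PathLike) -> MarkerSet:
    """Read a marker CSV written by :func:`write_markers`.

    Score and status columns are optional.  Malformed or negative
    coordinates raise a :class:`ValueError` naming the offending line
    (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    ms = MarkerSet()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            x, y, z = int(row.x), int(row.y), int(row.z)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {line}: non-integer coordinate") from exc
        if x < 0 or y < 0 or z < 0:
            raise ValueError(f"{path}: line {line}: negative coordinate ({x},{y},{z})")
        score = 0.0
        if hasattr(row, "score") and str(row.score) != "":
            try:
                score = float(row.score)
            except ValueError as exc:
                raise ValueError(f"{path}: line {line}: malformed score {row.score!r}") from exc
        status: Iterable[str] = ("raw",)
        if hasattr(row, "status") and str(row.status) != "":
            status = str(row.status).split("|")
            bad = set(status) - _VALID_STATUS
            if bad:
                raise ValueError(f"{path}: line {line}: unknown status flags {sorted(bad)}")
        ms.add(VoxelCoord(x, y, z), score, status)
    return ms
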