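"""Candidate generation, model classification, mean-shift refinement, merging.

Candidates are masked 3D local maxima: a voxel survives iff it is mask
foreground and no voxel in its centered search neighborhood (default
7x7x5, i.e. |dx|,|dy| <= 3 and |dz| <= 2) is brighter.  Within a plateau
of equal maxima only the voxel with the smallest (z, y, x) is kept.
Positively classified candidates are refined by iterative mean shift to
the nearby intensity center of mass, then markers closer than a fraction
of the expected punctum diameter are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from puncta3d.core import Marker, MarkerSet, VolumeStack, VoxelCoord, extract_roi
from puncta3d.features import get_extractor
from puncta3d.learning import TrainedModel, chain_features

__all__ = [
    "DetectionParams",
    "local_maxima",
    "classify_candidates",
    "mean_shift_refine",
    "merge_close",
]


@dataclass(frozen=True)
class DetectionParams:
    maxima_neighborhood: tuple[int, int, int] = (7, 7, 5)  # (x, y, z)
    roi_size: tuple[int, int, int] = (9, 9, 3)
    shift_window: tuple[int, int, int] = (9, 9, 3)
    shift_tol: float = 0.5  # voxels
    shift_max_iter: int = 20
    expected_size_xy: float = 7.0  # expected punctum diameter, voxels
    merge_fraction: float = 0.5

    def __post_init__(self):
        for dims in (self.maxima_neighborhood, self.roi_size, self.shift_window):
            if any(d % 2 == 0 or d < 1 for d in dims):
                raise ValueError(f"box dimensions must be odd and positive: {dims}")
        if not 0.0 < self.merge_fraction <= 1.0:
            raise ValueError("merge_fraction must lie in (0, 1]")

    @property
    def min_sep(self) -> float:
        return self.merge_fraction * self.expected_size_xy


def local_maxima(
    volume: VolumeStack | np.ndarray,
    mask: np.ndarray,
    neighborhood: tuple[int, int, int] = (7, 7, 5),
) -> MarkerSet:
    """Masked local maxima over a centered (w, h, d) neighborhood."""
    data = volume.data if isinstance(volume, VolumeStack) else np.asarray(volume)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError("mask shape must match volume shape")
    w, h, d = neighborhood
    if any(v % 2 == 0 or v < 1 for v in neighborhood):
        raise ValueError(f"neighborhood dimensions must be odd: {neighborhood}")
    filt = ndimage.maximum_filter(data, size=(d, h, w), mode="reflect")
    cand = mask & (data >= filt)
    if not cand.any():
        return MarkerSet()
    # adjacent candidate voxels are equal-valued by the maximum property;
    # keep one representative (smallest z, y, x) per connected plateau
    lab, n = ndimage.label(cand, structure=np.ones((3, 3, 3), dtype=bool))
    coords = np.argwhere(cand)  # argwhere returns lexicographic (z, y, x) order
    labels_at = lab[coords[:, 0], coords[:, 1], coords[:, 2]]
    first = np.unique(labels_at, return_index=True)[1]
    ms = MarkerSet()
    for i in sorted(first):
        z, y, x = (int(v) for v in coords[i])
        ms.add(VoxelCoord(x, y, z), score=float(data[z, y, x]), status=("raw",))
    return ms


def classify_candidates(
    model: TrainedModel,
    volume: VolumeStack,
    candidates: MarkerSet,
    roi_size: tuple[int, int, int] = (9, 9, 3),
) -> MarkerSet:
    """Keep candidates the model calls punctum centers; store their scores."""
    if len(candidates) == 0:
        return MarkerSet()
    rois = [extract_roi(volume, m.coord, roi_size) for m in candidates]
    X = chain_features(model.chain, rois)
    scores = model.predict_scores(X)
    out = MarkerSet()
    for m, s in zip(candidates, scores):
        if s > 0.5:
            out.markers.append(Marker(m.coord, float(s), m.status | {"classified"}))
    return out


def mean_shift_refine(
    volume: VolumeStack | np.ndarray,
    marker: Marker,
    window: tuple[int, int, int] = (9, 9, 3),
    tol: float = 0.5,
    max_iter: int = 20,
) -> Marker:
    """Iterate to the intensity-weighted centroid of the centered window.

    Stops when the continuous displacement drops below ``tol`` voxels or
    after ``max_iter`` iterations; the final position is rounded to the
    nearest voxel.  An all-zero window returns the marker unchanged.
    """
    data = volume.data if isinstance(volume, VolumeStack) else np.asarray(volume)
    if any(v % 2 == 0 or v < 1 for v in window):
        raise ValueError(f"window dimensions must be odd: {window}")
    nz, ny, nx = data.shape
    w, h, d = window
    rx, ry, rz = (w - 1) // 2, (h - 1) // 2, (d - 1) // 2
    pos = np.array([marker.coord.x, marker.coord.y, marker.coord.z], dtype=float)
    for _ in range(max_iter):
        cx, cy, cz = (int(round(v)) for v in pos)
        cx = int(np.clip(cx, 0, nx - 1))
        cy = int(np.clip(cy, 0, ny - 1))
        cz = int(np.clip(cz, 0, nz - 1))
        roi = extract_roi(data, VoxelCoord(cx, cy, cz), window)
        total = float(roi.data.sum())
        if total <= 0:
            if np.array_equal(pos, [marker.coord.x, marker.coord.y, marker.coord.z]):
                return marker
            break
        zz, yy, xx = np.meshgrid(
            np.arange(-rz, rz + 1), np.arange(-ry, ry + 1), np.arange(-rx, rx + 1), indexing="ij"
        )
        new = np.array([
            cx + float((roi.data * xx).sum()) / total,
            cy + float((roi.data * yy).sum()) / total,
            cz + float((roi.data * zz).sum()) / total,
        ])
        disp = float(np.linalg.norm(new - pos))
        pos = new
        if disp < tol:
            break
    x = int(np.clip(round(pos[0]), 0, nx - 1))
    y = int(np.clip(round(pos[1]), 0, ny - 1))
    z = int(np.clip(round(pos[2]), 0, nz - 1))
    return Marker(VoxelCoord(x, y, z), marker.score, marker.status | {"shifted"})


def merge_close(
    markers: MarkerSet,
    min_sep: float,
    z_scale: float = 1.0,
) -> MarkerSet:
    """Merge marker pairs closer than ``min_sep`` (z scaled by dz/dx).

    The globally closest qualifying pair (ties by smallest (z, y, x)) is
    merged into its score-weighted centroid until every surviving pair is
    at least ``min_sep`` apart.  Order-independent by construction.
    """
    if min_sep <= 0:
        raise ValueError("min_sep must be > 0")
    pts = [np.array([m.coord.x, m.coord.y, m.coord.z], dtype=float) for m in markers]
    scores = [max(m.score, 1e-12) for m in markers]
    status = [set(m.status) for m in markers]
    scale = np.array([1.0, 1.0, z_scale])

    def closest_pair():
        if len(pts) < 2:
            return None
        P = np.asarray(pts) * scale
        diff = P[:, None, :] - P[None, :, :]
        dmat = np.sqrt((diff**2).sum(axis=2))
        iu = np.triu_indices(len(pts), k=1)
        dists = dmat[iu]
        hit = dists < min_sep
        if not hit.any():
            return None
        best = None
        for i, j, dist in zip(iu[0][hit], iu[1][hit], dists[hit]):
            ti = tuple(np.round(pts[i])[::-1])
            tj = tuple(np.round(pts[j])[::-1])
            key = (float(dist), min(ti, tj), max(ti, tj))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        return best

    while True:
        hit = closest_pair()
        if hit is None:
            break
        _, i, j = hit
        wsum = scores[i] + scores[j]
        merged = (pts[i] * scores[i] + pts[j] * scores[j]) / wsum
        pts[i] = merged
        scores[i] = max(scores[i], scores[j])
        status[i] = status[i] | status[j] | {"merged"}
        del pts[j], scores[j], status[j]

    out = MarkerSet()
    seen = set()
    for p, s, st in zip(pts, scores, status):
        coord = VoxelCoord(int(round(p[0])), int(round(p[1])), int(round(p[2])))
        if coord in seen:  # rounding collision after a merge pass
            continue
        seen.add(coord)
        out.markers.append(Marker(coord, s, frozenset(st)))
    return out
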