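"""Marker-guided splitting of punctum clumps.

A clump is a connected foreground component containing several detected
centers.  Splitting works on the xy maximum-intensity projection (MIP) of
the component: the ordered boundary is traced, every contour point i gets
a concavity score

    C(i) = w(i-1) + w(i) + w(i+1)      (cyclic indices)

with w(k) the number of foreground pixels in the 5x5 window centered on
contour point k — high at inward notches.  A cut is the straight chord
between the contour pair {i, j} maximizing the split energy

    E({i, j}) = C(i) * C(j) / d(i, j)

among pairs whose chord actually separates the target marker from all
remaining markers (8-connectivity after chord removal).  Clumps with more
than two centers are split recursively, always separating first the
marker whose summed distance to the rest is largest, until one center per
child remains.  Voxels follow their xy projection pixel; chord pixels go
to the side whose marker projection is nearer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as _bresenham_line

from puncta3d.core import Marker, MarkerSet, VoxelCoord

__all__ = [
    "ObjectStats",
    "LabeledObjects",
    "ContourPoint",
    "SplitPair",
    "connected_components_26",
    "mip_project",
    "trace_contour",
    "split_energy",
    "find_split",
    "recursive_split",
    "split_objects",
    "quantify",
]

MIN_OBJECT_VOXELS = 8  # smaller components are discarded as noise


@dataclass
class ObjectStats:
    label: int
    voxel_count: int
    centroid: tuple[float, float, float]  # (z, y, x)
    bbox: tuple[int, int, int, int, int, int]  # z0, y0, x0, z1, y1, x1 (half-open)
    n_markers: int = 0
    unsplittable: bool = False


@dataclass
class LabeledObjects:
    """Integer-labeled 3D components; labels contiguous 1..L by decreasing size."""

    labels: np.ndarray
    stats: list[ObjectStats] = field(default_factory=list)

    @property
    def n_objects(self) -> int:
        return len(self.stats)


@dataclass(frozen=True)
class ContourPoint:
    index: int
    x: int
    y: int
    w: int  # foreground pixels in the centered 5x5 window
    C: int  # concavity score


@dataclass(frozen=True)
class SplitPair:
    i: int
    j: int
    E: float
    d: float


def _relabel_by_size(lab: np.ndarray, n: int, min_size: int) -> LabeledObjects:
    """Drop components below min_size and renumber by decreasing size,
    ties by smallest bounding-box origin (z, y, x)."""
    if n == 0:
        return LabeledObjects(np.zeros_like(lab, dtype=np.int32), [])
    counts = np.bincount(lab.ravel(), minlength=n + 1)
    slices = ndimage.find_objects(lab)
    order = []
    for old in range(1, n + 1):
        if counts[old] < min_size or slices[old - 1] is None:
            continue
        sl = slices[old - 1]
        origin = (sl[0].start, sl[1].start, sl[2].start)
        order.append((-int(counts[old]), origin, old))
    order.sort()
    remap = np.zeros(n + 1, dtype=np.int32)
    stats = []
    for new, (_, origin, old) in enumerate(order, start=1):
        remap[old] = new
    out = remap[lab]
    coms = ndimage.center_of_mass(out > 0, out, [i for i in range(1, len(order) + 1)]) if order else []
    new_slices = ndimage.find_objects(out)
    for new, (negcount, origin, old) in enumerate(order, start=1):
        sl = new_slices[new - 1]
        stats.append(
            ObjectStats(
                label=new,
                voxel_count=-negcount,
                centroid=tuple(float(c) for c in coms[new - 1]),
                bbox=(sl[0].start, sl[1].start, sl[2].start, sl[0].stop, sl[1].stop, sl[2].stop),
            )
        )
    return LabeledObjects(out, stats)


def connected_components_26(mask: np.ndarray, min_size: int = MIN_OBJECT_VOXELS) -> LabeledObjects:
    """26-connected 3D components with small objects discarded as noise."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    return _relabel_by_size(lab, n, min_size)


def mip_project(object_mask: np.ndarray) -> np.ndarray:
    """xy projection of a 3D object mask: pixel true iff any voxel in its column."""
    object_mask = np.asarray(object_mask, dtype=bool)
    if not object_mask.any():
        raise ValueError("cannot project an empty object")
    return object_mask.any(axis=0)


# clockwise Moore neighborhood, starting north, in (dy, dx)
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def trace_contour(mask2d: np.ndarray) -> list[ContourPoint]:
    """Ordered closed boundary of one 8-connected 2D object (Moore tracing,
    clockwise, starting at the topmost-then-leftmost pixel), annotated with
    the 5x5 window count w and the concavity score C.

    Window counts clip literally at the image border (outside = background).
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    ys, xs = np.nonzero(mask2d)
    if len(ys) == 0:
        raise ValueError("empty mask has no contour")
    start_i = int(np.lexsort((xs, ys))[0])
    sy, sx = int(ys[start_i]), int(xs[start_i])
    H, W = mask2d.shape

    def fg(y, x):
        return 0 <= y < H and 0 <= x < W and mask2d[y, x]

    points: list[tuple[int, int]] = [(sy, sx)]
    if any(fg(sy + dy, sx + dx) for dy, dx in _MOORE):
        # backtrack starts west of the start pixel (background by construction)
        b_idx = 6
        p = (sy, sx)
        first_state = None
        max_steps = 8 * (len(ys) + 8)
        for _ in range(max_steps):
            found = None
            for k in range(1, 9):
                idx = (b_idx + k) % 8
                dy, dx = _MOORE[idx]
                if fg(p[0] + dy, p[1] + dx):
                    found = idx
                    break
            if found is None:
                break
            nxt = (p[0] + _MOORE[found][0], p[1] + _MOORE[found][1])
            # new backtrack: the background neighbor scanned just before the
            # hit, re-expressed relative to the new pixel
            prev_idx = (found + 7) % 8
            by, bx = p[0] + _MOORE[prev_idx][0], p[1] + _MOORE[prev_idx][1]
            b_idx = _MOORE.index((by - nxt[0], bx - nxt[1]))
            state = (nxt, b_idx)
            if first_state is None:
                first_state = state
            elif state == first_state:
                break  # the first move repeated: the loop is closed
            points.append(nxt)
            p = nxt
        if len(points) > 1 and points[-1] == points[0]:
            points.pop()  # closure re-appended the start pixel
    boundary = points

    counts = ndimage.convolve(mask2d.astype(np.int32), np.ones((5, 5), dtype=np.int32), mode="constant")
    ws = [int(counts[y, x]) for y, x in boundary]
    n = len(boundary)
    out = []
    for i, (y, x) in enumerate(boundary):
        C = ws[(i - 1) % n] + ws[i] + ws[(i + 1) % n]
        out.append(ContourPoint(index=i, x=x, y=y, w=ws[i], C=C))
    return out


def split_energy(p_i: ContourPoint, p_j: ContourPoint) -> SplitPair:
    """E = C(i) * C(j) / d(i, j) with d the Euclidean pixel distance."""
    d = math.hypot(p_i.x - p_j.x, p_i.y - p_j.y)
    if d == 0:
        raise ValueError("coincident contour points have no split energy")
    return SplitPair(i=p_i.index, j=p_j.index, E=p_i.C * p_j.C / d, d=d)


def _chord(p_a: ContourPoint, p_b: ContourPoint) -> np.ndarray:
    rr, cc = _bresenham_line(p_a.y, p_a.x, p_b.y, p_b.x)
    return np.stack([rr, cc], axis=1)


def find_split(
    contour: list[ContourPoint],
    mask2d: np.ndarray,
    markers_yx: np.ndarray,
    target: int,
) -> tuple[SplitPair, np.ndarray] | None:
    """Best separating chord for one marker, or None when unsplittable.

    Contour points A are visited in decreasing concavity; for the first A
    admitting any chord AB that leaves the target marker 8-disconnected
    from every other marker, the pair maximizing the split energy is
    returned together with the rasterized chord pixels (ties: smaller
    contour index of B, then of A).
    """
    markers_yx = np.asarray(markers_yx, dtype=int)
    if len(markers_yx) < 2:
        raise ValueError("need at least two markers to split")
    mask2d = np.asarray(mask2d, dtype=bool)
    others = [i for i in range(len(markers_yx)) if i != target]
    order = sorted(range(len(contour)), key=lambda i: (-contour[i].C, i))
    s8 = np.ones((3, 3), dtype=bool)
    for ai in order:
        A = contour[ai]
        # visit B in decreasing split energy: the first separating chord is
        # the maximizer (ties by smaller contour index of B)
        cands = []
        for bi in range(len(contour)):
            if bi == ai or (contour[bi].y, contour[bi].x) == (A.y, A.x):
                continue
            pair = split_energy(A, contour[bi])
            cands.append((-pair.E, bi, pair))
        cands.sort(key=lambda t: (t[0], t[1]))
        for _, bi, pair in cands:
            B = contour[bi]
            chord = _chord(A, B)
            # a chord running through a marker cannot assign it a side
            if any((markers_yx == c).all(axis=1).any() for c in chord):
                continue
            work = mask2d.copy()
            work[chord[:, 0], chord[:, 1]] = False
            lab, _ = ndimage.label(work, structure=s8)
            lt = lab[markers_yx[target, 0], markers_yx[target, 1]]
            if lt == 0:
                continue
            if any(lab[markers_yx[o, 0], markers_yx[o, 1]] == lt for o in others):
                continue
            return pair, chord
    return None


def _snap_to_mask(yx: np.ndarray, mask2d: np.ndarray) -> np.ndarray:
    """Snap marker projections falling off the object onto the nearest pixel."""
    pix = np.argwhere(mask2d)
    out = yx.copy()
    for i, (y, x) in enumerate(yx):
        if not mask2d[y, x]:
            d = np.abs(pix - np.array([y, x])).astype(float)
            j = int(np.argmin(np.hypot(d[:, 0], d[:, 1])))
            out[i] = pix[j]
    return out


def recursive_split(
    object_mask: np.ndarray,
    markers_zyx: np.ndarray,
    z_scale: float = 1.0,
) -> list[tuple[np.ndarray, list[int], bool]]:
    """Split a 3D object into one child per guiding marker.

    Returns ``(child_mask, marker_indices, unsplittable)`` triples whose
    masks partition the object exactly.  When no separating chord exists
    at some stage, the remaining markers share one child flagged
    unsplittable.
    """
    object_mask = np.asarray(object_mask, dtype=bool)
    markers_zyx = np.asarray(markers_zyx, dtype=int)
    k = len(markers_zyx)
    if k == 0:
        raise ValueError("object carries no marker")
    return _split_rec(object_mask, markers_zyx, list(range(k)), z_scale)


def _split_rec(mask, markers, idxs, z_scale):
    if len(idxs) == 1:
        return [(mask, idxs, False)]
    pts = markers[idxs].astype(float)
    scaled = pts * np.array([z_scale, 1.0, 1.0])
    dmat = np.linalg.norm(scaled[:, None, :] - scaled[None, :, :], axis=2)
    sums = dmat.sum(axis=1)
    # M1: maximal summed distance to the rest; ties by smallest (z, y, x)
    best = max(range(len(idxs)), key=lambda i: (sums[i], tuple(-pts[i])))
    target_local = best

    proj = mask.any(axis=0)
    yx = markers[idxs][:, 1:3].copy()  # (y, x)
    yx = _snap_to_mask(yx, proj)
    try:
        contour = trace_contour(proj)
    except ValueError:
        contour = []
    hit = None
    if len(contour) >= 2:
        hit = find_split(contour, proj, yx, target_local)
    if hit is None:
        return [(mask, idxs, True)]
    _, chord = hit

    work = proj.copy()
    work[chord[:, 0], chord[:, 1]] = False
    lab, _ = ndimage.label(work, structure=np.ones((3, 3), dtype=bool))
    lt = lab[yx[target_local, 0], yx[target_local, 1]]
    other_labels = {int(lab[yx[o, 0], yx[o, 1]]) for o in range(len(idxs)) if o != target_local}
    side1 = lab == lt
    # chord pixels and stray fragments: nearer marker side wins
    unassigned = proj & ~side1 & ~np.isin(lab, list(other_labels))
    if unassigned.any():
        t_yx = yx[target_local].astype(float)
        o_yx = yx[[o for o in range(len(idxs)) if o != target_local]].astype(float)
        for y, x in np.argwhere(unassigned):
            dt = math.hypot(y - t_yx[0], x - t_yx[1])
            do = float(np.min(np.hypot(o_yx[:, 0] - y, o_yx[:, 1] - x)))
            if dt <= do:
                side1[y, x] = True

    child1 = mask & side1[None, :, :]
    rest = mask & ~side1[None, :, :]
    out = [(child1, [idxs[target_local]], False)]
    rest_idxs = [idxs[o] for o in range(len(idxs)) if o != target_local]
    if not rest.any():
        # degenerate: the cut starved the remainder; flag instead of losing markers
        return [(mask, idxs, True)]
    out.extend(_split_rec(rest, markers, rest_idxs, z_scale))
    return out


def split_objects(
    labeled: LabeledObjects,
    markers: MarkerSet,
    z_scale: float = 1.0,
) -> tuple[LabeledObjects, MarkerSet]:
    """Split every multi-marker object; return new labels + refined centers.

    Every cleanly split child yields exactly one refined center: its voxel
    centroid, rounded.  An unsplittable child (no separating chord exists,
    e.g. marker projections coincide) passes its guiding markers through
    unchanged — the split evidence is unreliable there, so the detections
    are kept as-is.  Markers not backed by any segmented object (their
    voxel falls outside the mask, e.g. after morphological cleanup) also
    pass through unchanged: segmentation support refines positions but
    does not veto detections.
    """
    lab = labeled.labels
    coords = markers.coords()  # (x, y, z)
    owner = np.zeros(len(coords), dtype=int)
    for i, (x, y, z) in enumerate(coords):
        if 0 <= z < lab.shape[0] and 0 <= y < lab.shape[1] and 0 <= x < lab.shape[2]:
            owner[i] = lab[z, y, x]

    out_labels = np.zeros_like(lab, dtype=np.int32)
    refined = MarkerSet()
    stats: list[ObjectStats] = []
    next_label = 1

    def emit(child_mask, origin, marker_ids, unsplittable):
        nonlocal next_label
        z0, y0, x0 = origin
        vox = int(child_mask.sum())
        zz, yy, xx = np.nonzero(child_mask)
        out_labels[z0:z0 + child_mask.shape[0],
                   y0:y0 + child_mask.shape[1],
                   x0:x0 + child_mask.shape[2]][child_mask] = next_label
        centroid = (z0 + float(zz.mean()), y0 + float(yy.mean()), x0 + float(xx.mean()))
        stats.append(ObjectStats(
            label=next_label, voxel_count=vox, centroid=centroid,
            bbox=(z0 + int(zz.min()), y0 + int(yy.min()), x0 + int(xx.min()),
                  z0 + int(zz.max()) + 1, y0 + int(yy.max()) + 1, x0 + int(xx.max()) + 1),
            n_markers=len(marker_ids), unsplittable=unsplittable,
        ))
        next_label += 1
        if unsplittable:
            for mi in marker_ids:
                refined.markers.append(markers[mi])
        elif marker_ids:
            cx, cy, cz = int(round(centroid[2])), int(round(centroid[1])), int(round(centroid[0]))
            score = max(markers[mi].score for mi in marker_ids)
            status = frozenset().union(*(markers[mi].status for mi in marker_ids)) | {"shifted"}
            refined.markers.append(Marker(VoxelCoord(cx, cy, cz), score, status))

    for st in labeled.stats:
        obj_markers = np.nonzero(owner == st.label)[0]
        z0, y0, x0, z1, y1, x1 = st.bbox
        sub = lab[z0:z1, y0:y1, x0:x1] == st.label
        if len(obj_markers) == 0:
            emit(sub, (z0, y0, x0), [], False)
            continue
        local = np.array([[c[2] - z0, c[1] - y0, c[0] - x0] for c in coords[obj_markers]])
        children = recursive_split(sub, local, z_scale)
        for child_mask, local_ids, flag in children:
            emit(child_mask, (z0, y0, x0), [int(obj_markers[li]) for li in local_ids], flag)

    for i in np.nonzero(owner == 0)[0]:
        refined.markers.append(markers[i])

    return LabeledObjects(out_labels, stats), refined


def quantify(objects: LabeledObjects, size_range: tuple[int, int] = (8, 1000)) -> dict:
    """Count and size statistics over objects within the size window."""
    sizes = np.array([s.voxel_count for s in objects.stats], dtype=int)
    lo, hi = size_range
    kept = sizes[(sizes >= lo) & (sizes <= hi)]
    return {
        "n_objects": int(len(sizes)),
        "n_in_range": int(len(kept)),
        "sizes": kept,
        "min_size": int(kept.min()) if len(kept) else 0,
        "max_size": int(kept.max()) if len(kept) else 0,
        "mean_size": float(kept.mean()) if len(kept) else 0.0,
    }
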