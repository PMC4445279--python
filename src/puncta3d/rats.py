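"""Robust Adaptive Threshold Selection (RATS) with quadtree interpolation.

Each 2D slice is divided into a quadtree of sub-regions; the smallest
region is the leaflet.  Each leaflet's threshold is the gradient-weighted
mean intensity

    T = sum(G^2 * I) / sum(G^2)

with G the Sobel gradient magnitude, the sums running over pixels whose
gradient exceeds the noise floor lambda = scaling_factor * min_noise
(sub-noise gradients carry no edge information and are truncated from
the weighting).  A region whose surviving gradients merely graze the
floor is invalid and defers to the nearest valid ancestor; an invalid
root falls back to the unconditional global formula, then to the slice
median for gradient-free slices.  Leaflet thresholds sit at region
centers and are bilinearly interpolated to every pixel; a pixel is
foreground iff its intensity strictly exceeds its interpolated
threshold.

Volumes are thresholded pseudo-3D: one parameter set, sanity-checked on a
reference slice (by default the middle slice, which is the brightest in
typical confocal stacks), applied slice by slice with per-slice
recomputation.  ``reference_field=True`` switches to the alternative
reading where the reference slice's threshold surface is reused verbatim
on every slice.

Two named parameterizations cover the two roles RATS plays in the
pipeline: ``overmask`` (permissive; the noise floor is halved) guarantees
that true local maxima survive into candidate detection, ``segmask``
(nominal) feeds connected-component segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from puncta3d.core import VolumeStack

__all__ = [
    "RatsParams",
    "QuadtreeNode",
    "ThresholdField",
    "sobel_gradient",
    "leaflet_threshold",
    "build_threshold_field",
    "rats_mask_pseudo3d",
    "overmask_params",
    "calibrate_params",
]


@dataclass(frozen=True)
class RatsParams:
    leaflet_size: int = 32  # smallest quadtree region edge, pixels
    min_noise: float = 10.0  # intensity-scale noise estimate
    scaling_factor: float = 3.0  # multiplies min_noise in the validity test
    min_depth: int = 5  # quadtree levels (where image size permits)

    def __post_init__(self):
        if self.leaflet_size < 2:
            raise ValueError("leaflet_size must be >= 2")
        if self.min_noise < 0:
            raise ValueError("min_noise must be >= 0")
        if self.scaling_factor <= 0:
            raise ValueError("scaling_factor must be > 0")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def overmask_params(params: RatsParams) -> RatsParams:
    """Permissive variant used as the support for local-maxima detection."""
    return replace(params, min_noise=params.min_noise / 2.0)


def calibrate_params(
    volume: "VolumeStack | np.ndarray",
    reference: Literal["middle"] | int = "middle",
    leaflet_size: int = 32,
    scaling_factor: float = 3.0,
    min_depth: int = 5,
    noise_factor: float = 2.5,
) -> RatsParams:
    """Choose one parameter set from the reference slice of a stack.

    ``min_noise`` is set to ``noise_factor`` times the wavelet-based noise
    standard-deviation estimate of the reference slice (the middle slice
    by default, the brightest in a typical stack).  The validity floor is
    then ``scaling_factor * min_noise`` = 7.5 estimated noise sd on the
    RMS Sobel response of a region; iid noise alone produces an RMS Sobel
    response of sqrt(24) sd ~ 4.9 sd, so featureless regions fall ~35 %
    below the floor and defer to their parent threshold, while regions
    holding real edges clear it.
    """
    from skimage.restoration import estimate_sigma

    data = volume.data if isinstance(volume, VolumeStack) else np.asarray(volume)
    nz = data.shape[0]
    ref = nz // 2 if reference == "middle" else int(reference)
    if not 0 <= ref < nz:
        raise IndexError(f"reference slice {ref} out of range for {nz} slices")
    sigma = float(estimate_sigma(np.asarray(data[ref], dtype=np.float64)))
    if not np.isfinite(sigma) or sigma <= 0:
        sigma = 1.0
    return RatsParams(
        leaflet_size=leaflet_size,
        min_noise=noise_factor * sigma,
        scaling_factor=scaling_factor,
        min_depth=min_depth,
    )


@dataclass
class QuadtreeNode:
    """One quadtree region, bounds half-open (y0:y1, x0:x1)."""

    y0: int
    y1: int
    x0: int
    x1: int
    threshold: float | None = None  # own gradient-weighted threshold, if valid
    effective: float = np.nan  # threshold after ancestor fallback
    children: list["QuadtreeNode"] | None = None

    @property
    def center(self) -> tuple[float, float]:
        return ((self.y0 + self.y1 - 1) / 2.0, (self.x0 + self.x1 - 1) / 2.0)

    def leaves(self) -> list["QuadtreeNode"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class ThresholdField:
    """Per-pixel threshold surface for one slice."""

    values: np.ndarray
    params: RatsParams
    root: QuadtreeNode | None = None


def sobel_gradient(slice_: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude with mirror-extended borders."""
    a = np.asarray(slice_, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError(f"slice must be 2D and at least 3x3, got shape {a.shape}")
    gy = ndimage.sobel(a, axis=0, mode="reflect")
    gx = ndimage.sobel(a, axis=1, mode="reflect")
    return np.hypot(gx, gy)


def leaflet_threshold(
    I: np.ndarray,
    G: np.ndarray,
    params: RatsParams,
    require_valid: bool = True,
) -> float | None:
    """Gradient-weighted mean intensity of a region, or None when invalid.

    Gradients at or below the noise floor lambda = scaling_factor *
    min_noise are truncated from the weighting, so the threshold is the
    G^2-weighted mean intensity over supra-floor (edge) pixels only.
    Validity: the mean G^2 among those pixels must exceed 2 lambda^2 —
    i.e. the surviving gradients must stand clear of the floor rather
    than merely graze it, which rejects regions whose only supra-floor
    pixels are noise outliers.  With min_noise = 0 this reduces to the
    plain gradient-weighted mean over all nonzero-gradient pixels.
    """
    I = np.asarray(I, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if I.shape != G.shape:
        raise ValueError(f"intensity/gradient shape mismatch: {I.shape} vs {G.shape}")
    lam = params.scaling_factor * params.min_noise
    sup = G > lam
    n_sup = int(np.count_nonzero(sup))
    if n_sup == 0:
        return None
    w = G[sup] ** 2
    s = float(w.sum())
    if require_valid and params.min_noise > 0 and s <= 2.0 * lam * lam * n_sup:
        return None
    return float((w * I[sup]).sum() / s)


def _build_node(I, G, params, y0, y1, x0, x1, depth) -> QuadtreeNode:
    node = QuadtreeNode(y0, y1, x0, x1)
    node.threshold = leaflet_threshold(I[y0:y1, x0:x1], G[y0:y1, x0:x1], params)
    h, w = y1 - y0, x1 - x0
    if depth < params.min_depth and min(h, w) >= params.leaflet_size and min(h, w) >= 2:
        ym, xm = y0 + h // 2, x0 + w // 2  # odd sizes: larger first half via integer midpoint
        node.children = [
            _build_node(I, G, params, y0, ym, x0, xm, depth + 1),
            _build_node(I, G, params, y0, ym, xm, x1, depth + 1),
            _build_node(I, G, params, ym, y1, x0, xm, depth + 1),
            _build_node(I, G, params, ym, y1, xm, x1, depth + 1),
        ]
    return node


def _propagate(node: QuadtreeNode, inherited: float) -> None:
    eff = node.threshold if node.threshold is not None else inherited
    node.effective = eff
    if node.children:
        for c in node.children:
            _propagate(c, eff)


def build_threshold_field(
    slice_: np.ndarray,
    params: RatsParams,
    global_fallback: float | None = None,
) -> ThresholdField:
    """Build the quadtree and interpolate leaflet thresholds to every pixel.

    ``global_fallback`` replaces the slice's own last-resort threshold when
    the root region is invalid — used by the pseudo-3D stack masking to
    impose the reference slice's global threshold on near-empty slices.
    """
    a = np.asarray(slice_, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("slice must be 2D and at least 3x3")
    G = sobel_gradient(a)
    root = _build_node(a, G, params, 0, a.shape[0], 0, a.shape[1], depth=1)
    if root.threshold is not None:
        fallback = root.threshold
    elif global_fallback is not None:
        fallback = float(global_fallback)
    else:
        # last resort: the global formula without the validity test (the
        # whole slice always yields some threshold), then the median for
        # gradient-free slices
        fallback = leaflet_threshold(a, G, params, require_valid=False)
        if fallback is None:
            fallback = float(np.median(a))
    _propagate(root, fallback)

    leaves = root.leaves()
    ys = sorted({leaf.center[0] for leaf in leaves})
    xs = sorted({leaf.center[1] for leaf in leaves})
    grid = np.full((len(ys), len(xs)), np.nan)
    yi = {v: i for i, v in enumerate(ys)}
    xi = {v: i for i, v in enumerate(xs)}
    for leaf in leaves:
        cy, cx = leaf.center
        grid[yi[cy], xi[cx]] = leaf.effective
    if np.isnan(grid).any():  # ragged tree (non-square image): fill from row/col means
        col_mean = np.nanmean(grid, axis=0)
        ind = np.where(np.isnan(grid))
        grid[ind] = np.take(col_mean, ind[1])
        grid[np.isnan(grid)] = fallback

    if len(ys) == 1 and len(xs) == 1:
        field = np.full(a.shape, grid[0, 0])
    else:
        # bilinear interpolation between region centers, constant beyond them
        yq = np.clip(np.arange(a.shape[0], dtype=float), ys[0], ys[-1])
        xq = np.clip(np.arange(a.shape[1], dtype=float), xs[0], xs[-1])
        ys_a, xs_a = np.asarray(ys), np.asarray(xs)
        rows = np.empty((len(ys), a.shape[1]))
        for i in range(len(ys)):
            rows[i] = np.interp(xq, xs_a, grid[i])
        field = np.empty(a.shape)
        j = np.searchsorted(ys_a, yq, side="right").clip(1, len(ys_a) - 1) if len(ys_a) > 1 else None
        if len(ys_a) == 1:
            field[:] = rows[0][None, :]
        else:
            y0 = ys_a[j - 1]
            y1 = ys_a[j]
            t = ((yq - y0) / (y1 - y0))[:, None]
            field = (1 - t) * rows[j - 1] + t * rows[j]
    field = np.clip(field, a.min(), a.max())
    return ThresholdField(values=field, params=params, root=root)


def rats_mask_pseudo3d(
    volume: VolumeStack | np.ndarray,
    params: RatsParams,
    reference: Literal["middle"] | int = "middle",
    reference_field: bool = False,
) -> np.ndarray:
    """Slice-wise RATS mask of a stack (boolean, foreground = I > T).

    ``reference`` names the slice used to validate the parameter set (and,
    with ``reference_field=True``, the slice whose threshold surface is
    applied to all slices).
    """
    data = volume.data if isinstance(volume, VolumeStack) else np.asarray(volume)
    nz = data.shape[0]
    ref = nz // 2 if reference == "middle" else int(reference)
    if not 0 <= ref < nz:
        raise IndexError(f"reference slice {ref} out of range for {nz} slices")
    mask = np.zeros(data.shape, dtype=bool)
    if reference_field:
        fld = build_threshold_field(data[ref], params).values
        for z in range(nz):
            mask[z] = data[z] > fld
        return mask
    # the reference slice (brightest, structure-rich) anchors the global
    # fallback so that darker, near-empty slices do not over-detect
    ref_field = build_threshold_field(data[ref], params)
    ref_fallback = ref_field.root.effective if ref_field.root is not None else None
    for z in range(nz):
        if z == ref:
            fld = ref_field.values
        else:
            fld = build_threshold_field(data[z], params, global_fallback=ref_fallback).values
        mask[z] = data[z] > fld
    return mask
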