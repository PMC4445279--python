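"""Anisotropic 3D Haar wavelet descriptor for small ROIs.

The descriptor adapts multi-scale Haar wavelet features to the z-resolution
disparity of confocal stacks: each xy plane of the ROI is mirror-padded to
a dyadic size and decomposed with an orthonormal 2D Haar wavelet, and the
per-slice coefficient vectors are combined as a weighted sum across z with
the middle slice weighted heaviest.  This captures in-plane structure at
multiple scales while avoiding a full (and expensive) 3D wavelet.

A small registry exposes extractors by name so alternative descriptors can
be plugged into algorithm chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pywt

from puncta3d.core import Roi3D

__all__ = ["HaarConfig", "FeatureVector", "haar2d", "anisotropic_haar_3d",
           "get_extractor", "register_extractor", "EXTRACTORS"]


@dataclass(frozen=True)
class HaarConfig:
    levels: int = 2
    pad_to: int = 16
    z_weights: tuple[float, ...] = (0.25, 0.5, 0.25)

    def __post_init__(self):
        if self.pad_to < 1 or (self.pad_to & (self.pad_to - 1)) != 0:
            raise ValueError("pad_to must be a power of two")
        if self.levels < 1 or 2**self.levels > self.pad_to:
            raise ValueError(f"{self.levels} levels too deep for pad_to={self.pad_to}")
        w = np.asarray(self.z_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("z_weights must sum to 1")
        if not np.allclose(w, w[::-1]):
            raise ValueError("z_weights must be symmetric about the middle slice")
        if w[len(w) // 2] < w.max() - 1e-12:
            raise ValueError("middle z weight must be maximal")

    @property
    def n_coefficients(self) -> int:
        return self.pad_to * self.pad_to


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    extractor_id: str


def _pad_plane(plane: np.ndarray, pad_to: int) -> np.ndarray:
    h, w = plane.shape
    if h > pad_to or w > pad_to:
        raise ValueError(f"plane {plane.shape} larger than pad_to={pad_to}")
    if (h, w) == (pad_to, pad_to):
        return plane
    py, px = pad_to - h, pad_to - w
    return np.pad(plane, ((py // 2, py - py // 2), (px // 2, px - px // 2)), mode="reflect")


def haar2d(plane: np.ndarray, levels: int = 2, pad_to: int = 16) -> np.ndarray:
    """Orthonormal 2D Haar coefficients of a mirror-padded plane.

    The output order is fixed: approximation block first, then for each
    level from coarsest to finest the (horizontal, vertical, diagonal)
    detail blocks, each flattened row-major.  The transform is orthonormal
    (periodization mode on a dyadic grid), so coefficient energy equals
    pixel energy.
    """
    a = _pad_plane(np.asarray(plane, dtype=np.float64), pad_to)
    coeffs = pywt.wavedec2(a, "haar", mode="periodization", level=levels)
    parts = [coeffs[0].ravel()]
    for detail in coeffs[1:]:
        for band in detail:
            parts.append(band.ravel())
    return np.concatenate(parts)


def anisotropic_haar_3d(roi: Roi3D, config: HaarConfig = HaarConfig()) -> FeatureVector:
    """z-weighted sum of per-slice 2D Haar coefficient vectors."""
    d = roi.data.shape[0]
    if d != len(config.z_weights):
        raise ValueError(f"ROI depth {d} does not match {len(config.z_weights)} z weights")
    acc = None
    for z, w in enumerate(config.z_weights):
        c = haar2d(roi.data[z], config.levels, config.pad_to)
        acc = w * c if acc is None else acc + w * c
    return FeatureVector(values=acc, extractor_id="haar3d")


def _intensity_stats(roi: Roi3D) -> FeatureVector:
    """Raw intensity summary (mean, max, center voxel) — a deliberately weak
    baseline descriptor for chain comparison."""
    d, h, w = roi.data.shape
    center = float(roi.data[d // 2, h // 2, w // 2])
    vals = np.array([float(roi.data.mean()), float(roi.data.max()), center])
    return FeatureVector(values=vals, extractor_id="intensity_stats")


EXTRACTORS: dict[str, Callable[..., FeatureVector]] = {}


def register_extractor(name: str, fn: Callable[..., FeatureVector]) -> None:
    EXTRACTORS[name] = fn


def get_extractor(name: str) -> Callable[..., FeatureVector]:
    try:
        return EXTRACTORS[name]
    except KeyError:
        raise KeyError(f"unknown feature extractor {name!r}; known: {sorted(EXTRACTORS)}") from None


register_extractor("haar3d", anisotropic_haar_3d)
register_extractor("intensity_stats", _intensity_stats)
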