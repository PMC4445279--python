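"""Multi-channel co-localization filter.

Detected punctum centers must sit near the neuron morphology: a marker is
kept iff any morphology-foreground voxel lies inside the centered 9x9x5
proximity box (|dx| <= 4, |dy| <= 4, |dz| <= 2).  Centers failing the
test are discarded as staining artifacts.  The morphology foreground is
the nominal (segmask) pseudo-3D RATS segmentation of the morphology
channel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from puncta3d.core import Marker, MarkerSet, VolumeStack
from puncta3d.rats import RatsParams, rats_mask_pseudo3d

__all__ = ["morphology_foreground", "colocalize_filter"]


def morphology_foreground(morph: VolumeStack, params: RatsParams) -> np.ndarray:
    """Pseudo-3D RATS segmentation mask of the morphology channel."""
    return rats_mask_pseudo3d(morph, params)


def colocalize_filter(
    markers: MarkerSet,
    morph_mask: np.ndarray,
    box: tuple[int, int, int] = (9, 9, 5),
) -> MarkerSet:
    """Keep markers with morphology foreground inside the centered box.

    Output is a subset of the input and the filter is idempotent; kept
    markers gain the ``validated`` status flag.
    """
    if any(b % 2 == 0 or b < 1 for b in box):
        raise ValueError(f"box dimensions must be odd: {box}")
    morph_mask = np.asarray(morph_mask, dtype=bool)
    w, h, d = box
    # marker kept iff the box around it meets the mask <=> the mask dilated
    # by the box covers the marker voxel
    reach = ndimage.binary_dilation(morph_mask, structure=np.ones((d, h, w), dtype=bool))
    out = MarkerSet()
    nz, ny, nx = morph_mask.shape
    for m in markers:
        x, y, z = m.coord
        if 0 <= z < nz and 0 <= y < ny and 0 <= x < nx and reach[z, y, x]:
            out.markers.append(Marker(m.coord, m.score, m.status | {"validated"}))
    return out
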