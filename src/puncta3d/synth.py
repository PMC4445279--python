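"""Seeded two-channel synthetic confocal scenes with ground truth.

The generator emulates the image properties that drive every downstream
stage of the pipeline:

* bright oval puncta whose xy extent exceeds their z extent (anisotropic
  Gaussian blobs truncated at 3 sigma);
* fused clumps of 2-3 puncta spaced 1.0-1.5 x the xy sigma so their
  blobs merge into one connected foreground object;
* dim staining artifacts placed well off the neuron morphology;
* regional contrast variation: a smooth additive background gradient, a
  multiplicative stitching-seam step at a random x column, and mild z
  attenuation toward the stack boundaries;
* a tube-like morphology channel rendered from a persistent random walk.

Identical parameters (including the seed) produce bit-identical stacks
and ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from puncta3d.core import Marker, MarkerSet, Roi3D, VolumeStack, VoxelCoord, extract_roi

__all__ = ["SceneParams", "SyntheticScene", "generate_scene", "sample_training_rois"]


@dataclass
class SceneParams:
    """Parameters of a synthetic scene.  Defaults are the benchmark scene."""

    shape: tuple[int, int, int] = (16, 256, 256)  # (Z, Y, X)
    n_synapses: int = 150
    xy_sigma: float = 1.6
    z_sigma: float = 0.8
    peak_intensity: tuple[float, float] = (150.0, 250.0)
    clump_fraction: float = 0.3
    clump_sizes: tuple[int, ...] = (2, 3)
    artifact_count: int = 10
    artifact_intensity_factor: float = 0.3
    background_base: float = 10.0
    background_gradient: float = 15.0
    seam_contrast: tuple[float, float] = (0.65, 0.85)  # multiplicative seam factor range; () disables
    z_attenuation: float = 0.15
    noise_sigma: float | None = None  # None -> 0.1 x median blob peak
    tube_radius: float = 4.0
    tube_intensity: float = 120.0
    tube_step: float = 1.0
    tube_n_steps: int = 1500
    tube_persistence: float = 0.97
    morph_z_scale: float = 2.5  # apparent z elongation of the tube (PSF smear)
    min_separation_xy: int = 6  # Chebyshev xy spacing between distinct puncta groups
    voxel_size: tuple[float, float, float] = (80.0, 80.0, 400.0)
    seed: int = 42

    def __post_init__(self):
        if self.n_synapses < 0 or self.artifact_count < 0:
            raise ValueError("counts must be nonnegative")
        if not 0.0 <= self.clump_fraction <= 1.0:
            raise ValueError("clump_fraction must lie in [0, 1]")
        if not 0.0 < self.artifact_intensity_factor < 1.0:
            raise ValueError("artifact_intensity_factor must lie in (0, 1)")
        if self.xy_sigma < self.z_sigma:
            raise ValueError("xy_sigma >= z_sigma expected (confocal anisotropy)")
        if any(s not in (2, 3) for s in self.clump_sizes):
            raise ValueError("clump sizes must be 2 or 3")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SyntheticScene:
    """Ground-truth record for one generated scene."""

    true_centers: MarkerSet
    true_labels: np.ndarray  # int grid, 0 background, 1..n per punctum
    morphology_mask: np.ndarray  # bool grid
    params: SceneParams
    artifact_centers: MarkerSet = field(default_factory=MarkerSet)
    clump_groups: list[list[int]] = field(default_factory=list)  # indices into true_centers
    synapse_stack: VolumeStack | None = None
    morphology_stack: VolumeStack | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _tube_path(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Persistent random walk through the volume, (n, 3) float (z, y, x)."""
    Z, Y, X = params.shape
    pos = np.array([Z / 2.0, rng.uniform(0.2 * Y, 0.8 * Y), 5.0])
    theta = rng.uniform(-0.6, 0.6)  # initial heading, roughly +x
    zdrift = 0.0
    pts = [pos.copy()]
    for _ in range(params.tube_n_steps):
        theta = params.tube_persistence * theta + rng.normal(0.0, 0.15)
        zdrift = 0.9 * zdrift + rng.normal(0.0, 0.02)
        step = np.array([zdrift, math.sin(theta) * params.tube_step, math.cos(theta) * params.tube_step])
        pos = pos + step
        # reflect off the usable interior so the tube stays inside the field
        if not 4.0 <= pos[2] <= X - 5.0:
            pos[2] = float(np.clip(pos[2], 4.0, X - 5.0))
            theta = math.pi - theta
        if not 4.0 <= pos[1] <= Y - 5.0:
            pos[1] = float(np.clip(pos[1], 4.0, Y - 5.0))
            theta = -theta
        if not 2.0 <= pos[0] <= Z - 3.0:
            pos[0] = float(np.clip(pos[0], 2.0, Z - 3.0))
            zdrift = -zdrift
        pts.append(pos.copy())
    return np.array(pts)


def _tube_mask(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    Z, Y, X = params.shape
    path = _tube_path(params, rng)
    seed_grid = np.zeros((Z, Y, X), dtype=bool)
    idx = np.round(path).astype(int)
    idx[:, 0] = np.clip(idx[:, 0], 0, Z - 1)
    idx[:, 1] = np.clip(idx[:, 1], 0, Y - 1)
    idx[:, 2] = np.clip(idx[:, 2], 0, X - 1)
    seed_grid[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~seed_grid, sampling=(params.morph_z_scale, 1.0, 1.0))
    return dist <= params.tube_radius


def _integer_offset(theta: float, lo: float, hi: float) -> tuple[int, int]:
    """Integer (dx, dy) of norm in [max(1, lo), max(hi, sqrt(2))] nearest to heading theta."""
    hi = max(hi, math.sqrt(2.0))
    lo = max(lo, 1.0)
    best, best_err = None, None
    r = int(math.ceil(hi))
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            n = math.hypot(dx, dy)
            if n < lo - 1e-9 or n > hi + 1e-9 or n == 0:
                continue
            err = abs(math.atan2(dy, dx) - theta)
            err = min(err, 2 * math.pi - err)
            if best is None or err < best_err - 1e-12 or (abs(err - best_err) < 1e-12 and n < math.hypot(*best)):
                best, best_err = (dx, dy), err
    assert best is not None
    return best


def _group_conflict(c: np.ndarray, accepted: list[np.ndarray], sep_xy: int) -> bool:
    """Two distinct puncta groups conflict when one would suppress or absorb
    the other during 7x7x5 local-maxima detection: |dz| <= 2 and xy
    Chebyshev distance < sep_xy."""
    for a in accepted:
        if abs(int(c[0]) - int(a[0])) <= 2 and max(abs(int(c[1]) - int(a[1])), abs(int(c[2]) - int(a[2]))) < sep_xy:
            return True
    return False


def _render_blob(canvas: np.ndarray, center_zyx: tuple[int, int, int], peak: float,
                 z_sigma: float, xy_sigma: float) -> None:
    """Add a truncated (3 sigma) anisotropic Gaussian blob in place."""
    Z, Y, X = canvas.shape
    cz, cy, cx = center_zyx
    rz, rxy = int(math.ceil(3 * z_sigma)), int(math.ceil(3 * xy_sigma))
    z0, z1 = max(cz - rz, 0), min(cz + rz + 1, Z)
    y0, y1 = max(cy - rxy, 0), min(cy + rxy + 1, Y)
    x0, x1 = max(cx - rxy, 0), min(cx + rxy + 1, X)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1) - cz, np.arange(y0, y1) - cy, np.arange(x0, x1) - cx, indexing="ij"
    )
    m2 = (xx**2 + yy**2) / xy_sigma**2 + zz**2 / z_sigma**2
    blob = peak * np.exp(-0.5 * m2)
    blob[m2 > 9.0] = 0.0  # truncate at 3 sigma (Mahalanobis)
    canvas[z0:z1, y0:y1, x0:x1] += blob


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_scene(params: SceneParams) -> tuple[VolumeStack, VolumeStack, SyntheticScene]:
    """Generate a two-channel scene and its ground truth.

    Returns ``(synapse_channel, morphology_channel, scene)``.  Raises
    :class:`RuntimeError` when ``n_synapses`` puncta cannot be placed on
    the morphology at the required mutual separation.
    """
    rng = np.random.default_rng(params.seed)
    Z, Y, X = params.shape

    tube = _tube_mask(params, rng)

    # --- stitching seam (decided before placement so puncta avoid it) ---
    seam_x = None
    seam_factor = 1.0
    if params.seam_contrast:
        seam_x = int(rng.integers(X // 3, 2 * X // 3))
        seam_factor = float(rng.uniform(*params.seam_contrast))
    seam_margin = int(math.ceil(2 * params.xy_sigma)) + 1

    # --- choose puncta group anchors on/near the tube ---
    n_clumped = int(round(params.clump_fraction * params.n_synapses))
    clump_sizes: list[int] = []
    remaining = n_clumped
    while remaining >= 2:
        s = int(rng.choice(params.clump_sizes))
        s = min(s, remaining)
        if s < 2:
            break
        clump_sizes.append(s)
        remaining -= s
    n_isolated = params.n_synapses - sum(clump_sizes)
    n_groups = n_isolated + len(clump_sizes)

    near_tube = ndimage.binary_dilation(tube, iterations=2)
    cand = np.argwhere(near_tube)
    # keep candidates away from the field border and the seam
    keep = (
        (cand[:, 0] >= 2) & (cand[:, 0] <= Z - 3)
        & (cand[:, 1] >= 5) & (cand[:, 1] <= Y - 6)
        & (cand[:, 2] >= 5) & (cand[:, 2] <= X - 6)
    )
    if seam_x is not None:
        keep &= np.abs(cand[:, 2] - seam_x) > seam_margin
    cand = cand[keep]
    cand = cand[rng.permutation(len(cand))]

    anchors: list[np.ndarray] = []
    for c in cand:
        if len(anchors) == n_groups:
            break
        if not _group_conflict(c, anchors, params.min_separation_xy):
            anchors.append(c)
    if len(anchors) < n_groups:
        raise RuntimeError(
            f"could not place {n_groups} puncta groups on the morphology at "
            f"separation {params.min_separation_xy}; reduce n_synapses or enlarge the scene"
        )

    # --- expand clump anchors into 2-3 member groups ---
    centers: list[tuple[int, int, int]] = []  # (z, y, x)
    clump_groups: list[list[int]] = []
    for gi, anchor in enumerate(anchors):
        az, ay, ax = (int(v) for v in anchor)
        if gi < len(clump_sizes):
            members = [(az, ay, ax)]
            tries = 0
            while len(members) < clump_sizes[gi] and tries < 50:
                tries += 1
                theta = float(rng.uniform(0, 2 * math.pi))
                dx, dy = _integer_offset(theta, 1.0 * params.xy_sigma, 1.5 * params.xy_sigma)
                m = (az, ay + dy, ax + dx)
                if m in members:
                    continue
                if not (0 <= m[1] < Y and 0 <= m[2] < X):
                    continue
                members.append(m)
            idx0 = len(centers)
            centers.extend(members)
            clump_groups.append(list(range(idx0, idx0 + len(members))))
        else:
            centers.append((az, ay, ax))
    if len(centers) != params.n_synapses:
        # rounding in clump partitioning or failed clump growth: top up with
        # isolated centers from the remaining candidates
        for c in cand:
            if len(centers) == params.n_synapses:
                break
            if not _group_conflict(c, [np.array(p) for p in centers], params.min_separation_xy):
                centers.append((int(c[0]), int(c[1]), int(c[2])))
        if len(centers) != params.n_synapses:
            raise RuntimeError("could not place the requested number of puncta")

    # --- render the synapse channel ---
    syn = np.zeros((Z, Y, X), dtype=np.float64)
    peaks = rng.uniform(*params.peak_intensity, size=len(centers))
    for (cz, cy, cx), pk in zip(centers, peaks):
        _render_blob(syn, (cz, cy, cx), pk, params.z_sigma, params.xy_sigma)

    # --- artifacts: dim blobs far off the tube ---
    artifact_centers = MarkerSet()
    if params.artifact_count > 0:
        dist_tube = ndimage.distance_transform_edt(~tube, sampling=(params.morph_z_scale, 1.0, 1.0))
        far = np.argwhere(
            (dist_tube > 14.0)
            & (np.arange(Z)[:, None, None] >= 2) & (np.arange(Z)[:, None, None] <= Z - 3)
        )
        far = far[(far[:, 1] >= 5) & (far[:, 1] <= Y - 6) & (far[:, 2] >= 5) & (far[:, 2] <= X - 6)]
        if seam_x is not None:
            far = far[np.abs(far[:, 2] - seam_x) > seam_margin]
        far = far[rng.permutation(len(far))]
        placed: list[np.ndarray] = [np.array(c) for c in centers]
        median_peak = float(np.median(peaks)) if len(peaks) else float(np.mean(params.peak_intensity))
        for c in far:
            if len(artifact_centers) == params.artifact_count:
                break
            if _group_conflict(c, placed, params.min_separation_xy):
                continue
            placed.append(c)
            pk = params.artifact_intensity_factor * median_peak
            _render_blob(syn, (int(c[0]), int(c[1]), int(c[2])), pk, params.z_sigma, params.xy_sigma)
            artifact_centers.add(VoxelCoord(int(c[2]), int(c[1]), int(c[0])))

    # --- background, seam, z attenuation, noise ---
    gdir = rng.uniform(-1.0, 1.0, size=2)
    gnorm = np.linalg.norm(gdir)
    gdir = gdir / gnorm if gnorm > 0 else np.array([1.0, 0.0])
    yy = np.arange(Y)[:, None] / max(Y - 1, 1)
    xx = np.arange(X)[None, :] / max(X - 1, 1)
    background = params.background_base + params.background_gradient * (
        0.5 + 0.5 * (gdir[0] * (2 * yy - 1) + gdir[1] * (2 * xx - 1))
    )
    syn += background[None, :, :]
    if seam_x is not None:
        syn[:, :, seam_x:] *= seam_factor
    if params.z_attenuation > 0 and Z > 1:
        zprof = 1.0 - params.z_attenuation * ((np.arange(Z) - (Z - 1) / 2.0) / ((Z - 1) / 2.0)) ** 2
        syn *= zprof[:, None, None]

    median_peak = float(np.median(peaks)) if len(peaks) else float(np.mean(params.peak_intensity))
    noise_sigma = params.noise_sigma if params.noise_sigma is not None else 0.1 * median_peak
    if noise_sigma > 0:
        syn += rng.normal(0.0, noise_sigma, size=syn.shape)
    syn = np.clip(syn, 0.0, None).astype(np.float32)

    # --- morphology channel ---
    morph = np.zeros((Z, Y, X), dtype=np.float64)
    morph[tube] = params.tube_intensity
    morph = ndimage.gaussian_filter(morph, sigma=(0.5, 1.0, 1.0))
    morph += params.background_base
    if noise_sigma > 0:
        morph += rng.normal(0.0, 0.5 * noise_sigma, size=morph.shape)
    morph = np.clip(morph, 0.0, None).astype(np.float32)

    # --- ground-truth per-voxel labels: nearest center under the blob metric ---
    labels = np.zeros((Z, Y, X), dtype=np.int32)
    best = np.full((Z, Y, X), np.inf, dtype=np.float64)
    rz, rxy = int(math.ceil(3 * params.z_sigma)), int(math.ceil(3 * params.xy_sigma))
    for li, (cz, cy, cx) in enumerate(centers, start=1):
        z0, z1 = max(cz - rz, 0), min(cz + rz + 1, Z)
        y0, y1 = max(cy - rxy, 0), min(cy + rxy + 1, Y)
        x0, x1 = max(cx - rxy, 0), min(cx + rxy + 1, X)
        zz, yy2, xx2 = np.meshgrid(
            np.arange(z0, z1) - cz, np.arange(y0, y1) - cy, np.arange(x0, x1) - cx, indexing="ij"
        )
        m2 = (xx2**2 + yy2**2) / params.xy_sigma**2 + zz**2 / params.z_sigma**2
        sub = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
        take = (m2 <= 9.0) & (m2 < best[sub])
        labels[sub][take] = li
        best[sub][take] = m2[take]

    true_centers = MarkerSet(
        Marker(VoxelCoord(cx, cy, cz), 1.0, frozenset({"raw"})) for (cz, cy, cx) in centers
    )
    scene = SyntheticScene(
        true_centers=true_centers,
        true_labels=labels,
        morphology_mask=tube,
        params=params,
        artifact_centers=artifact_centers,
        clump_groups=clump_groups,
    )
    syn_stack = VolumeStack(syn, voxel_size=params.voxel_size, channel_name="synapse")
    morph_stack = VolumeStack(morph, voxel_size=params.voxel_size, channel_name="morphology")
    scene.synapse_stack = syn_stack
    scene.morphology_stack = morph_stack
    return syn_stack, morph_stack, scene


def sample_training_rois(
    scene: SyntheticScene,
    n_pos: int = 25,
    n_neg: int = 25,
    seed: int = 0,
    roi_size: tuple[int, int, int] = (9, 9, 3),
) -> list[Roi3D]:
    """Draw labeled training ROIs from a generated scene.

    Positives are centered on true punctum centers.  Negatives mix
    punctum-adjacent voxels, plain background and artifact centers, all at
    xy Euclidean distance >= 3 voxels from every true center.
    """
    if scene.synapse_stack is None:
        raise ValueError("scene does not carry its synapse channel")
    if n_pos > len(scene.true_centers):
        raise ValueError(f"requested {n_pos} positives but scene has {len(scene.true_centers)} centers")
    rng = np.random.default_rng(seed)
    vol = scene.synapse_stack
    Z, Y, X = vol.shape
    centers_xy = scene.true_centers.coords()[:, :2].astype(float)

    def far_from_centers(x: int, y: int) -> bool:
        if len(centers_xy) == 0:
            return True
        d = np.hypot(centers_xy[:, 0] - x, centers_xy[:, 1] - y)
        return bool(np.min(d) >= 3.0)

    rois: list[Roi3D] = []
    pick = rng.choice(len(scene.true_centers), size=n_pos, replace=False)
    for i in pick:
        rois.append(extract_roi(vol, scene.true_centers[i].coord, roi_size, label="positive"))

    neg: list[VoxelCoord] = []
    # artifact centers first: they teach the model that dim blobs are not puncta
    for m in scene.artifact_centers:
        if len(neg) >= n_neg // 4:
            break
        if far_from_centers(m.coord.x, m.coord.y):
            neg.append(m.coord)
    n_adjacent = (n_neg - len(neg) + 1) // 2
    attempts = 0
    while len(neg) < n_neg and attempts < 20000:
        attempts += 1
        if len(neg) < n_adjacent + n_neg // 4 and len(scene.true_centers) > 0:
            i = int(rng.integers(len(scene.true_centers)))
            c = scene.true_centers[i].coord
            theta = rng.uniform(0, 2 * math.pi)
            r = rng.uniform(3.5, 6.5)
            x = int(round(c.x + r * math.cos(theta)))
            y = int(round(c.y + r * math.sin(theta)))
            z = int(np.clip(c.z + rng.integers(-1, 2), 0, Z - 1))
        else:
            x = int(rng.integers(0, X))
            y = int(rng.integers(0, Y))
            z = int(rng.integers(0, Z))
        if not (0 <= x < X and 0 <= y < Y):
            continue
        if far_from_centers(x, y) and VoxelCoord(x, y, z) not in neg:
            neg.append(VoxelCoord(x, y, z))
    if len(neg) < n_neg:
        raise RuntimeError("could not sample enough negative ROIs")
    for c in neg:
        rois.append(extract_roi(vol, c, roi_size, label="negative"))
    return rois
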