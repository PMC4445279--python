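import numpy as np
import pytest
from skimage.draw import disk

from puncta3d.core import MarkerSet
from puncta3d.splitting import (
    ContourPoint,
    connected_components_26,
    find_split,
    mip_project,
    quantify,
    recursive_split,
    split_energy,
    split_objects,
    trace_contour,
)


def flood_fill_26(mask):
    """Oracle labeling: BFS flood fill over the 26-neighborhood."""
    from collections import deque

    lab = np.zeros(mask.shape, dtype=int)
    nxt = 1
    offs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if lab[start]:
            continue
        q = deque([start])
        lab[start] = nxt
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in offs:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)) and mask[p] and not lab[p]:
                    lab[p] = nxt
                    q.append(p)
        nxt += 1
    return lab, nxt - 1


class TestConnectedComponents:
    def test_corner_touch_is_one_component(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = m[1, 1, 1] = True
        lab, n = flood_fill_26(m)
        assert n == 1

    def test_size_filter_boundary(self):
        m = np.zeros((3, 6, 12), bool)
        m[1, 1:2, 1:8] = True  # 7 voxels -> discarded
        m[0:2, 3:5, 9:11] = True  # 8 voxels -> retained
        lo = connected_components_26(m)
        assert lo.n_objects == 1
        assert lo.stats[0].voxel_count == 8

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        for rep in range(20):
            m = rng.uniform(size=(6, 15, 15)) < 0.25
            lo = connected_components_26(m, min_size=1)
            oracle, n = flood_fill_26(m)
            assert lo.n_objects == n, f"rep {rep}"
            # same partition: bijection between label sets
            for i in range(1, n + 1):
                vals = np.unique(lo.labels[oracle == i])
                assert len(vals) == 1 and vals[0] > 0

    def test_labels_ordered_by_decreasing_size(self):
        m = np.zeros((3, 20, 20), bool)
        m[0:2, 1:4, 1:4] = True  # 18 voxels
        m[1, 10:13, 10:13] = True  # 9 voxels
        lo = connected_components_26(m)
        sizes = [s.voxel_count for s in lo.stats]
        assert sizes == sorted(sizes, reverse=True)
        assert [s.label for s in lo.stats] == [1, 2]


class TestMip:
    def test_single_slice_identity(self):
        m = np.zeros((1, 5, 7), bool)
        m[0, 1:4, 2:6] = True
        assert np.array_equal(mip_project(m), m[0])

    def test_stacked_slices_same_projection(self):
        sl = np.zeros((5, 7), bool)
        sl[1:4, 2:6] = True
        one = mip_project(sl[None])
        two = mip_project(np.stack([sl, sl]))
        assert np.array_equal(one, two)

    def test_area_bounded_by_voxel_count(self, rng):
        m = rng.uniform(size=(4, 10, 10)) < 0.3
        if not m.any():
            m[0, 0, 0] = True
        assert mip_project(m).sum() <= m.sum()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mip_project(np.zeros((2, 4, 4), bool))


class TestContour:
    def test_filled_square_boundary(self):
        m = np.zeros((9, 9), bool)
        m[2:7, 2:7] = True
        pts = trace_contour(m)
        assert len(pts) == 16
        # every boundary pixel of the square appears exactly once
        expected = {(y, x) for y in range(2, 7) for x in range(2, 7)
                    if y in (2, 6) or x in (2, 6)}
        assert {(p.y, p.x) for p in pts} == expected

    def test_concavity_ordering_on_dumbbell(self):
        """Concave notch C > straight edge C > convex corner C, with window
        counts verified against brute-force 5x5 pixel counting."""
        m = np.zeros((15, 22), bool)
        rr, cc = disk((7, 6), 3.6)
        m[rr, cc] = True
        rr, cc = disk((7, 15), 3.6)
        m[rr, cc] = True
        m[6:9, 9:13] = True  # bridge creating two waist notches
        pts = trace_contour(m)
        # brute-force window counts
        for p in pts:
            y0, y1 = max(p.y - 2, 0), min(p.y + 3, m.shape[0])
            x0, x1 = max(p.x - 2, 0), min(p.x + 3, m.shape[1])
            assert p.w == int(m[y0:y1, x0:x1].sum())
        notch = [p for p in pts if p.x in (10, 11) and abs(p.y - 7) <= 3]
        xmin = min(p.x for p in pts)
        convex = [p for p in pts if p.x == xmin]  # leftmost rim of the left disc
        assert notch and convex
        assert min(p.C for p in notch) > max(p.C for p in convex)
        # the notch points carry the globally top concavities
        top = sorted(pts, key=lambda p: -p.C)[:4]
        assert all(9 <= p.x <= 13 for p in top)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trace_contour(np.zeros((4, 4), bool))


class TestSplitEnergy:
    def test_direct_evaluation(self):
        a = ContourPoint(0, x=0, y=0, w=15, C=45)
        b = ContourPoint(1, x=10, y=0, w=15, C=45)
        assert split_energy(a, b).E == pytest.approx(202.5)

    def test_symmetry_and_distance_scaling(self):
        a = ContourPoint(0, x=0, y=0, w=10, C=30)
        b = ContourPoint(1, x=4, y=3, w=12, C=36)
        c = ContourPoint(2, x=8, y=6, w=12, C=36)
        assert split_energy(a, b).E == split_energy(b, a).E
        assert split_energy(a, c).E == pytest.approx(split_energy(a, b).E / 2)

    def test_coincident_rejected(self):
        a = ContourPoint(0, x=3, y=3, w=10, C=30)
        b = ContourPoint(5, x=3, y=3, w=10, C=30)
        with pytest.raises(ValueError):
            split_energy(a, b)


def _dumbbell2d():
    m = np.zeros((15, 20), bool)
    rr, cc = disk((7, 6), 3.5)
    m[rr, cc] = True
    rr, cc = disk((7, 11), 3.5)
    m[rr, cc] = True
    return m


class TestFindSplit:
    def test_dumbbell_chord_separates_markers(self):
        m = _dumbbell2d()
        contour = trace_contour(m)
        markers = np.array([[7, 6], [7, 11]])
        pair, chord = find_split(contour, m, markers, target=0)
        # chord passes through the waist (between the discs)
        assert all(7 <= c[1] <= 10 for c in chord)
        # verify separation with an independent labeling
        from scipy import ndimage

        work = m.copy()
        work[chord[:, 0], chord[:, 1]] = False
        lab, _ = ndimage.label(work, structure=np.ones((3, 3), bool))
        assert lab[7, 6] != lab[7, 11] and lab[7, 6] > 0 and lab[7, 11] > 0

    def test_chosen_pair_is_valid_maximizer(self):
        """Brute force over all contour pairs for the winning A: no valid
        chord from that A has higher split energy."""
        from scipy import ndimage

        m = _dumbbell2d()
        contour = trace_contour(m)
        markers = np.array([[7, 6], [7, 11]])
        pair, _ = find_split(contour, m, markers, target=0)
        A = contour[pair.i]
        from skimage.draw import line

        best_E = 0.0
        for B in contour:
            if (B.y, B.x) == (A.y, A.x):
                continue
            rr, cc = line(A.y, A.x, B.y, B.x)
            if any((markers == np.array([r, c])).all(axis=1).any() for r, c in zip(rr, cc)):
                continue
            work = m.copy()
            work[rr, cc] = False
            lab, _ = ndimage.label(work, structure=np.ones((3, 3), bool))
            if lab[7, 6] > 0 and lab[7, 11] > 0 and lab[7, 6] != lab[7, 11]:
                best_E = max(best_E, split_energy(A, B).E)
        assert pair.E == pytest.approx(best_E)

    def test_coincident_marker_projection_unsplittable(self):
        m = _dumbbell2d()
        contour = trace_contour(m)
        markers = np.array([[7, 8], [7, 8]])
        assert find_split(contour, m, markers, target=0) is None

    def test_convex_disc_still_splittable(self):
        m = np.zeros((15, 15), bool)
        rr, cc = disk((7, 7), 5.5)
        m[rr, cc] = True
        contour = trace_contour(m)
        markers = np.array([[7, 4], [7, 10]])
        hit = find_split(contour, m, markers, target=0)
        assert hit is not None


class TestRecursiveSplit:
    def test_single_marker_object_unchanged(self):
        m = np.zeros((3, 8, 8), bool)
        m[1, 2:6, 2:6] = True
        children = recursive_split(m, np.array([[1, 4, 4]]))
        assert len(children) == 1
        assert np.array_equal(children[0][0], m)
        assert children[0][2] is False

    def test_dumbbell_partition_conservation(self):
        m2 = _dumbbell2d()
        m = np.stack([np.zeros_like(m2), m2, m2])
        markers = np.array([[1, 7, 6], [2, 7, 11]])
        children = recursive_split(m, markers, z_scale=5.0)
        assert len(children) == 2
        total = np.zeros(m.shape, int)
        for cm, ids, flag in children:
            assert not flag
            assert len(ids) == 1
            total += cm.astype(int)
        assert np.array_equal(total > 0, m)  # exhaustive
        assert total.max() == 1  # disjoint
        # each child contains its own marker
        for cm, ids, _ in children:
            z, y, x = markers[ids[0]]
            assert cm[z, y, x]

    def test_triple_blob_one_child_per_marker(self):
        m2 = np.zeros((15, 28), bool)
        for cx in (6, 11, 16):
            rr, cc = disk((7, cx), 3.5)
            m2[rr, cc] = True
        m = m2[None]
        markers = np.array([[0, 7, 6], [0, 7, 11], [0, 7, 16]])
        children = recursive_split(m, markers)
        assert len(children) == 3
        # first split separates an end marker (maximal summed distance)
        assert children[0][1] in ([0], [2])
        total = sum(c[0].astype(int) for c in children)
        assert np.array_equal(total > 0, m) and total.max() == 1
        owned = sorted(ids[0] for _, ids, _ in children)
        assert owned == [0, 1, 2]

    def test_no_marker_rejected(self):
        with pytest.raises(ValueError):
            recursive_split(np.ones((2, 4, 4), bool), np.empty((0, 3)))


class TestSplitObjectsAndQuantify:
    def test_refined_centers_one_per_child(self):
        m2 = _dumbbell2d()
        mask = np.stack([np.zeros_like(m2), m2, m2])
        lo = connected_components_26(mask)
        ms = MarkerSet.from_coords([(6, 7, 1), (11, 7, 2)], scores=[0.9, 0.8])
        split_lab, refined = split_objects(lo, ms, z_scale=5.0)
        assert split_lab.n_objects == 2
        assert len(refined) == 2
        assert np.array_equal(split_lab.labels > 0, mask)

    def test_orphan_marker_passes_through(self):
        mask = np.zeros((3, 10, 10), bool)
        mask[1, 1:4, 1:4] = True  # 9 voxels, marker-less
        lo = connected_components_26(mask)
        ms = MarkerSet.from_coords([(8, 8, 2)], scores=[0.7])
        _, refined = split_objects(lo, ms)
        assert len(refined) == 1
        assert tuple(refined[0].coord) == (8, 8, 2)

    def test_quantify_size_window(self):
        class S:  # minimal stats stand-ins
            def __init__(self, n):
                self.voxel_count = n

        from puncta3d.splitting import LabeledObjects

        lo = LabeledObjects(np.zeros((1, 1, 1), int),
                            [S(8), S(20), S(1200)])  # type: ignore[list-item]
        q = quantify(lo)
        assert q["n_in_range"] == 2
        assert q["min_size"] == 8 and q["max_size"] == 20
        assert q["mean_size"] == pytest.approx((8 + 20) / 2)

    def test_quantify_empty(self):
        from puncta3d.splitting import LabeledObjects

        q = quantify(LabeledObjects(np.zeros((1, 1, 1), int), []))
        assert q["n_objects"] == 0 and q["n_in_range"] == 0
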