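"""Domain types, rasterization and frame-stack / ROI I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nirfperf as nf
from nirfperf.core import rasterize_polygon


def _point_in_polygon(y, x, poly):
    """Independent brute-force even-odd crossing counter for one point."""
    inside = False
    n = len(poly)
    for k in range(n):
        r1, c1 = poly[k]
        r2, c2 = poly[(k + 1) % n]
        if (r1 > y) != (r2 > y):
            x_int = (c2 - c1) * (y - r1) / (r2 - r1) + c1
            if x < x_int:
                inside = not inside
    return inside


class TestFrameStack:
    def test_invariants_enforced(self):
        frames = np.zeros((3, 4, 4))
        with pytest.raises(ValueError, match="insufficient frames"):
            nf.FrameStack(frames=frames[:1], timestamps=[0.0])
        with pytest.raises(ValueError, match="timestamp count"):
            nf.FrameStack(frames=frames, timestamps=[0.0, 1.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            nf.FrameStack(frames=frames, timestamps=[0.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="non-negative"):
            nf.FrameStack(frames=frames - 1.0, timestamps=[0, 1, 2])

    def test_fixed_rate_timestamps(self, tmp_path):
        import tifffile

        path = tmp_path / "s.tif"
        tifffile.imwrite(path, np.zeros((3, 4, 4), dtype=np.uint8))
        stack = nf.load_frame_stack(path, timestamps=1.0)
        assert np.array_equal(stack.timestamps, [0.0, 1.0, 2.0])

    def test_roundtrip_bit_exact_uint16(self, tmp_path):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 2**16, size=(5, 8, 9)).astype(np.uint16)
        stack = nf.FrameStack(frames=frames, timestamps=np.arange(5) * 0.4, meta={"dose_mg": 5})
        path = nf.save_frame_stack(stack, tmp_path / "s.tif")
        back = nf.load_frame_stack(path)
        assert back.frames.dtype == np.uint16
        assert np.array_equal(back.frames, frames)
        assert np.array_equal(back.timestamps, stack.timestamps)
        assert back.meta == {"dose_mg": 5}

    def test_simulated_stack_roundtrip(self, tmp_path, success_run):
        _, stack, _, _ = success_run
        path = nf.save_frame_stack(stack, tmp_path / "sim.tif")
        back = nf.load_frame_stack(path)
        assert np.array_equal(back.frames, stack.frames)
        assert np.array_equal(back.timestamps, stack.timestamps)

    def test_single_frame_file_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "one.tif"
        tifffile.imwrite(path, np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="insufficient frames"):
            nf.load_frame_stack(path, timestamps=1.0)


class TestRasterization:
    def test_rectangle_includes_strictly_interior_centers(self):
        mask = rasterize_polygon([[0, 0], [0, 2], [2, 2], [2, 0]], (5, 5))
        expected = np.zeros((5, 5), dtype=bool)
        expected[:2, :2] = True
        assert mask.sum() == 4
        assert np.array_equal(mask, expected)

    def test_explicit_mask_passes_through(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        roi = nf.Roi(label="1", role="muscle", mask=mask)
        assert np.array_equal(nf.rasterize_roi(roi, (4, 4)), mask)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            nf.Roi(label="1", role="muscle", polygon=[[0, 0], [1, 1]])

    def test_empty_mask_rejected(self):
        roi = nf.Roi(label="1", role="muscle", polygon=[[0, 0], [0, 0.2], [0.2, 0.1]])
        with pytest.raises(ValueError, match="empty"):
            nf.rasterize_roi(roi, (5, 5))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 10), st.floats(0, 10)), min_size=3, max_size=7),
           st.integers(0, 1000))
    def test_matches_bruteforce_oracle(self, verts, _salt):
        poly = np.array(verts)
        mask = rasterize_polygon(poly, (10, 10))
        for r in range(10):
            for c in range(10):
                assert mask[r, c] == _point_in_polygon(r + 0.5, c + 0.5, poly)

    def test_convex_polygons_match_shapely(self):
        from shapely.geometry import Point, Polygon

        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.uniform(0, 12, size=(6, 2))
            from scipy.spatial import ConvexHull

            hull = pts[ConvexHull(pts).vertices]
            mask = rasterize_polygon(hull, (12, 12))
            # shapely uses (x, y); our vertices are (row, col)
            sp = Polygon([(c, r) for r, c in hull])
            for r in range(12):
                for c in range(12):
                    p = Point(c + 0.5, r + 0.5)
                    if sp.exterior.distance(p) > 1e-9:  # centers on the boundary are convention-dependent
                        assert mask[r, c] == sp.contains(p)

    def test_adjacent_rectangles_are_disjoint(self):
        left = rasterize_polygon([[0, 0], [0, 3], [6, 3], [6, 0]], (6, 6))
        right = rasterize_polygon([[0, 3], [0, 6], [6, 6], [6, 3]], (6, 6))
        assert not (left & right).any()
        assert (left | right).sum() == 36


class TestRoiSetIO:
    def _set(self):
        rois = [
            nf.Roi(label=str(i), role="muscle", polygon=[[0, i - 1], [0, i], [3, i], [3, i - 1]])
            for i in range(1, 11)
        ]
        mask = np.zeros((8, 12), dtype=bool)
        mask[6:8, 0:5] = True
        rois.append(nf.Roi(label="skin", role="control", mask=mask))
        return nf.RoiSet(rois=rois, frame_shape=(8, 12))

    def test_full_set_structure(self):
        rs = self._set()
        assert len(rs.rois) == 11
        assert [r.label for r in rs.muscle_rois] == [str(i) for i in range(1, 11)]
        assert [r.label for r in rs.control_rois] == ["skin"]

    def test_roundtrip_identity(self, tmp_path):
        rs = self._set()
        path = nf.write_roi_set(rs, tmp_path / "rois.json")
        back = nf.read_roi_set(path, (8, 12))
        assert [r.label for r in back.rois] == [r.label for r in rs.rois]
        for a, b in zip(rs.rois, back.rois):
            assert a.role == b.role
            assert np.array_equal(
                nf.rasterize_roi(a, rs.frame_shape), nf.rasterize_roi(b, rs.frame_shape)
            )
        # second round trip is byte-identical (idempotent canonical form)
        path2 = nf.write_roi_set(back, tmp_path / "rois2.json")
        assert path.read_text() == path2.read_text()

    def test_duplicate_labels_rejected(self):
        rois = [
            nf.Roi(label="3", role="muscle", polygon=[[0, 0], [0, 1], [1, 1]]),
            nf.Roi(label="3", role="muscle", polygon=[[0, 1], [0, 2], [1, 2]]),
        ]
        with pytest.raises(ValueError, match="duplicate label"):
            nf.RoiSet(rois=rois, frame_shape=(4, 4))

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="unknown role"):
            nf.Roi(label="1", role="tendon", polygon=[[0, 0], [0, 1], [1, 1]])

    def test_geometry_outside_frame_rejected(self, tmp_path):
        rs = nf.RoiSet(
            rois=[nf.Roi(label="1", role="muscle", polygon=[[0, 0], [0, 20], [3, 20]])],
            frame_shape=(8, 12),
        )
        path = nf.write_roi_set(rs, tmp_path / "bad.json")
        with pytest.raises(ValueError, match="outside frame"):
            nf.read_roi_set(path)
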