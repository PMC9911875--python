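"""Camera model, frame I/O and depth/colour alignment."""

import json

import imageio.v3 as iio
import numpy as np
import pytest

from canopyrecon.camera import (
    CameraExtrinsics,
    CameraIntrinsics,
    RGBDFrame,
    depth_for_color_pixels,
    depth_map_for_color_image,
    frame_to_pointcloud,
    load_frame,
    map_color_pixel_to_depth_pixel,
)


def tiny_intr(w=8, h=6, fx=10.0, scale=0.001):
    return CameraIntrinsics(fx=fx, fy=fx, cx=w / 2, cy=h / 2, width=w, height=h,
                            depth_scale=scale)


def make_frame(depth, color=None, intr_d=None, intr_c=None, extr=None, index=0):
    h, w = depth.shape
    intr_d = intr_d or tiny_intr(w, h)
    intr_c = intr_c or intr_d
    if color is None:
        color = np.full((intr_c.height, intr_c.width, 3), 128, dtype=np.uint8)
    return RGBDFrame(
        index=index, depth=depth.astype(np.uint16), color=color,
        intr_depth=intr_d, intr_color=intr_c,
        extr=extr or CameraExtrinsics.identity(),
    )


def write_fixture(tmp_path, depth, color, intr):
    spec = {"depth": intr.to_dict(), "color": intr.to_dict(),
            "extrinsics": CameraExtrinsics.identity().to_dict()}
    dp = tmp_path / "depth_0042.png"
    cp = tmp_path / "color_0042.png"
    sp = tmp_path / "camera.json"
    iio.imwrite(dp, depth.astype(np.uint16))
    iio.imwrite(cp, color)
    sp.write_text(json.dumps(spec))
    return dp, cp, sp


class TestLoadFrame:
    def test_round_trip_with_index_from_filename(self, tmp_path):
        intr = tiny_intr(4, 4)
        depth = np.arange(16, dtype=np.uint16).reshape(4, 4) * 100
        color = np.random.default_rng(0).integers(0, 255, (4, 4, 3), dtype=np.uint8)
        dp, cp, sp = write_fixture(tmp_path, depth, color, intr)
        frame = load_frame(dp, cp, sp)
        assert frame.index == 42
        np.testing.assert_array_equal(frame.depth, depth)
        np.testing.assert_array_equal(frame.color, color)

    def test_alpha_channel_stripped(self, tmp_path):
        intr = tiny_intr(4, 4)
        depth = np.full((4, 4), 500, dtype=np.uint16)
        rgba = np.random.default_rng(1).integers(0, 255, (4, 4, 4), dtype=np.uint8)
        dp, cp, sp = write_fixture(tmp_path, depth, rgba, intr)
        frame = load_frame(dp, cp, sp)
        np.testing.assert_array_equal(frame.color, rgba[:, :, :3])

    def test_dimension_mismatch(self, tmp_path):
        intr = tiny_intr(8, 8)  # claims 8x8 but images are 4x4
        depth = np.zeros((4, 4), dtype=np.uint16)
        color = np.zeros((4, 4, 3), dtype=np.uint8)
        dp, cp, sp = write_fixture(tmp_path, depth, color, intr)
        with pytest.raises(ValueError, match="does not match"):
            load_frame(dp, cp, sp)

    def test_wrong_bit_depth(self, tmp_path):
        intr = tiny_intr(4, 4)
        depth = np.zeros((4, 4), dtype=np.uint16)
        color = np.zeros((4, 4, 3), dtype=np.uint8)
        dp, cp, sp = write_fixture(tmp_path, depth, color, intr)
        iio.imwrite(dp, depth.astype(np.uint8))  # 8-bit depth is invalid
        with pytest.raises(ValueError, match="16-bit"):
            load_frame(dp, cp, sp)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_frame(tmp_path / "nope.png", tmp_path / "nope2.png",
                       tmp_path / "cam.json")


class TestPixelMapping:
    def test_identity_maps_pixel_to_itself(self):
        frame = make_frame(np.full((6, 8), 1000, dtype=np.uint16))
        for uv in [(3.0, 2.0), (0.0, 0.0), (7.0, 5.0)]:
            out = map_color_pixel_to_depth_pixel(uv, 1.0, frame)
            np.testing.assert_allclose(out, uv, atol=1e-12)

    def test_lateral_offset_shifts_by_fx_tx_over_z(self):
        # R=I, T=(0.01,0,0) m, fx=600, depth 1 m: shift of -fx*Tx/Z = -6 px
        intr = CameraIntrinsics(fx=600, fy=600, cx=320, cy=240,
                                width=640, height=480)
        extr = CameraExtrinsics(np.eye(3), [0.01, 0.0, 0.0])
        frame = make_frame(np.full((480, 640), 1000, dtype=np.uint16),
                           intr_d=intr, intr_c=intr, extr=extr)
        out = map_color_pixel_to_depth_pixel((320.0, 240.0), 1.0, frame)
        np.testing.assert_allclose(out, (320.0 - 6.0, 240.0), atol=1e-9)

    def test_matches_explicit_backproject_transform_reproject(self):
        rng = np.random.default_rng(5)
        intr_c = CameraIntrinsics(fx=500, fy=510, cx=315, cy=245,
                                  width=640, height=480)
        intr_d = CameraIntrinsics(fx=480, fy=480, cx=320, cy=240,
                                  width=640, height=480)
        from canopyrecon.geometry import rotation_about_axis
        R = rotation_about_axis([0.1, 0.3, 1.0], 0.01)
        extr = CameraExtrinsics(R, [0.015, -0.002, 0.001])
        frame = make_frame(np.full((480, 640), 900, dtype=np.uint16),
                           intr_d=intr_d, intr_c=intr_c, extr=extr)
        for _ in range(20):
            u, v = rng.uniform(0, 639), rng.uniform(0, 479)
            z = rng.uniform(0.5, 1.4)
            # independent scalar chain
            X = (u - intr_c.cx) * z / intr_c.fx
            Y = (v - intr_c.cy) * z / intr_c.fy
            P_ir = R.T @ (np.array([X, Y, z]) - extr.T)
            expect = (intr_d.fx * P_ir[0] / P_ir[2] + intr_d.cx,
                      intr_d.fy * P_ir[1] / P_ir[2] + intr_d.cy)
            out = map_color_pixel_to_depth_pixel((u, v), z, frame)
            np.testing.assert_allclose(out, expect, atol=1e-9)

    def test_zero_depth_means_no_mapping(self):
        frame = make_frame(np.full((6, 8), 1000, dtype=np.uint16))
        assert map_color_pixel_to_depth_pixel((3, 2), 0.0, frame) is None

    def test_alignment_chain_self_inverse(self):
        """colour->depth then depth->colour returns the pixel within 0.5 px."""
        intr = CameraIntrinsics(fx=400, fy=400, cx=212, cy=120,
                                width=424, height=240)
        from canopyrecon.geometry import rotation_about_axis
        extr = CameraExtrinsics(rotation_about_axis([0, 1, 0], 0.005),
                                [0.014, 0.0, 0.0])
        frame = make_frame(np.full((240, 424), 1100, dtype=np.uint16),
                           intr_d=intr, intr_c=intr, extr=extr)
        rng = np.random.default_rng(0)
        for _ in range(20):
            uv = np.array([rng.uniform(50, 374), rng.uniform(30, 210)])
            z = 1.1
            p_ir = map_color_pixel_to_depth_pixel(uv, z, frame)
            # forward: back-project depth pixel, apply extrinsics, project
            P_ir = intr.back_project(p_ir, z)
            uv_back, _ = intr.project(frame.extr.depth_to_color(P_ir))
            np.testing.assert_allclose(uv_back[0], uv, atol=0.5)


class TestDepthForColorPixels:
    def test_constant_aligned_field(self):
        frame = make_frame(np.full((6, 8), 1100, dtype=np.uint16))
        px = [(u, v) for u in range(8) for v in range(6)]
        z = depth_for_color_pixels(frame, px)
        np.testing.assert_allclose(z, 1.1)

    def test_out_of_bounds_pixel_raises(self):
        frame = make_frame(np.full((6, 8), 1100, dtype=np.uint16))
        with pytest.raises(ValueError, match="bounds"):
            depth_for_color_pixels(frame, [(9, 2)])

    def test_missing_depth_is_nan(self):
        depth = np.zeros((6, 8), dtype=np.uint16)
        depth[2, 3] = 1000
        frame = make_frame(depth)
        z = depth_for_color_pixels(frame, [(3, 2), (4, 4)])
        assert z[0] == pytest.approx(1.0)
        assert np.isnan(z[1])

    def test_offset_extrinsics_matches_per_pixel_chain(self):
        """Vectorised lookup equals the scalar mapping chain, pixel by pixel."""
        intr = CameraIntrinsics(fx=100, fy=100, cx=32, cy=24,
                                width=64, height=48)
        extr = CameraExtrinsics(np.eye(3), [0.02, 0.005, 0.0])
        rng = np.random.default_rng(2)
        # smooth depth surface ~1 m with a gentle ramp
        vv, uu = np.mgrid[0:48, 0:64]
        depth = (1000 + 2 * uu + rng.integers(0, 3, (48, 64))).astype(np.uint16)
        frame = make_frame(depth, intr_d=intr, intr_c=intr, extr=extr)
        dm = depth_map_for_color_image(frame)
        from canopyrecon.camera import _aligned_depth_image
        cand = _aligned_depth_image(frame)
        checked = 0
        for v in range(5, 43, 7):
            for u in range(5, 59, 7):
                if cand[v, u] <= 0:
                    continue
                z = cand[v, u]
                for _ in range(2):
                    p = map_color_pixel_to_depth_pixel((u, v), z, frame)
                    ui, vi = int(round(p[0])), int(round(p[1]))
                    if not (0 <= ui < 64 and 0 <= vi < 48):
                        z = 0.0
                        break
                    z = depth[vi, ui] * 0.001
                    if z == 0:
                        break
                assert dm[v, u] == pytest.approx(z), (u, v)
                checked += 1
        assert checked > 20


class TestFrameToPointcloud:
    def test_principal_point_ray(self):
        depth = np.zeros((6, 8), dtype=np.uint16)
        depth[3, 4] = 1000  # principal pixel (cx=4, cy=3)
        frame = make_frame(depth)
        cloud = frame_to_pointcloud(frame)
        assert len(cloud) == 1
        np.testing.assert_allclose(cloud.points[0], [0.0, 0.0, 1.0], atol=1e-12)

    def test_all_zero_depth_gives_empty_cloud(self):
        frame = make_frame(np.zeros((6, 8), dtype=np.uint16))
        assert len(frame_to_pointcloud(frame)) == 0

    def test_ramp_equals_brute_force_backprojection(self):
        intr = tiny_intr(8, 8, fx=12.0)
        vv, uu = np.mgrid[0:8, 0:8]
        depth = (400 + 50 * uu + 25 * vv).astype(np.uint16)
        color = np.random.default_rng(3).integers(0, 255, (8, 8, 3), dtype=np.uint8)
        frame = make_frame(depth, color=color, intr_d=intr)
        cloud = frame_to_pointcloud(frame, depth_min=0.3, depth_max=1.0)
        expect_pts, expect_cols = [], []
        for v in range(8):
            for u in range(8):
                z = depth[v, u] * 0.001
                if 0.3 <= z <= 1.0:
                    expect_pts.append([(u - 4.0) * z / 12.0,
                                       (v - 4.0) * z / 12.0, z])
                    expect_cols.append(color[v, u] / 255.0)
        assert len(cloud) == len(expect_pts)
        np.testing.assert_allclose(
            sorted(map(tuple, cloud.points)), sorted(map(tuple, expect_pts)),
            atol=1e-12,
        )

    def test_point_count_equals_in_range_pixels(self, rendered_frame):
        cloud = frame_to_pointcloud(rendered_frame, 0.11, 1.5)
        z = rendered_frame.depth * rendered_frame.intr_depth.depth_scale
        expect = int(np.sum((z >= 0.11) & (z <= 1.5)))
        assert len(cloud) == expect

    def test_depth_range_is_enforced(self):
        depth = np.full((6, 8), 2000, dtype=np.uint16)  # 2 m: out of range
        frame = make_frame(depth)
        assert len(frame_to_pointcloud(frame, 0.11, 1.5)) == 0
        with pytest.raises(ValueError):
            frame_to_pointcloud(frame, 1.0, 0.5)
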