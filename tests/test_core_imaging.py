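"""Image model, I/O round trips, preprocessing, virtual slicing, Otsu, composites."""

import numpy as np
import pytest

from histoct import (
    BinaryMask,
    PlaneSpec,
    RasterImage,
    VolumeImage,
    checkerboard,
    downscale,
    extract_plane,
    fuse_overlay,
    invert,
    otsu_threshold,
    read_image,
    read_volume,
    to_grey,
    write_image,
    write_volume,
)
from histoct.core_imaging import DegenerateInputError, FormatError, ParameterError


class TestIO:
    @pytest.mark.parametrize(
        "shape,bit_depth,suffix",
        [
            ((17, 23, 3), 8, ".png"),
            ((17, 23), 8, ".png"),
            ((17, 23), 16, ".png"),
            ((17, 23, 3), 8, ".tif"),
            ((17, 23), 16, ".tif"),
        ],
    )
    def test_round_trip_pixel_identical(self, tmp_path, rng, shape, bit_depth, suffix):
        data = rng.integers(0, 2**bit_depth, shape).astype(float)
        img = RasterImage(data, bit_depth=bit_depth)
        path = tmp_path / f"img{suffix}"
        write_image(img, path)
        back = read_image(path)
        assert back.bit_depth == bit_depth
        assert back.n_channels == (shape[2] if len(shape) == 3 else 1)
        np.testing.assert_array_equal(back.pixels, img.pixels)

    def test_alpha_channel_dropped_with_warning(self, tmp_path, rng, caplog):
        import tifffile

        rgba = rng.integers(0, 256, (8, 8, 4)).astype(np.uint8)
        path = tmp_path / "rgba.tif"
        tifffile.imwrite(str(path), rgba)
        with caplog.at_level("WARNING"):
            img = read_image(path)
        assert img.n_channels == 3
        assert any("alpha" in r.message for r in caplog.records)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            read_image(tmp_path / "nope.png")

    def test_unsupported_channel_count_rejected(self, tmp_path, rng):
        import tifffile

        path = tmp_path / "weird.tif"
        tifffile.imwrite(str(path), rng.integers(0, 256, (8, 8, 5)).astype(np.uint8))
        with pytest.raises(FormatError):
            read_image(path)

    def test_volume_round_trip_tiff_and_raw(self, tmp_path, rng):
        vox = rng.integers(0, 65536, (5, 6, 7)).astype(float)
        vol = VolumeImage(vox, voxel_size_um=2.0, bit_depth=16)
        tpath = tmp_path / "vol.tif"
        write_volume(vol, tpath)
        back = read_volume(tpath)
        np.testing.assert_array_equal(back.voxels, vox)
        # raw + sidecar
        raw = tmp_path / "vol.raw"
        vox.astype(np.uint16).tofile(raw)
        (tmp_path / "vol.raw.meta").write_text(
            "shape = 5 6 7\ndtype = uint16\nvoxel_size_um = 2.0\norigin = 1 2 3\n"
        )
        back2 = read_volume(raw)
        np.testing.assert_array_equal(back2.voxels, vox)
        assert back2.voxel_size_um == 2.0
        assert back2.origin == (1.0, 2.0, 3.0)


class TestPreprocessing:
    def test_to_grey_channel_projection(self, rgb_image):
        g = to_grey(rgb_image, "channel:1")
        np.testing.assert_array_equal(g.grey2d, rgb_image.channel(1))
        np.testing.assert_array_equal(to_grey(rgb_image, "g").grey2d, g.grey2d)

    def test_to_grey_average_rounds_half_up(self):
        img = RasterImage(np.array([[[10.0, 20.0, 30.0]], [[1.0, 2.0, 2.0]]]), bit_depth=8)
        g = to_grey(img, "average")
        assert g.grey2d[0, 0] == 20.0
        assert g.grey2d[1, 0] == 2.0  # 5/3 = 1.67 -> 2

    def test_to_grey_identity_on_grey(self, grey_image):
        np.testing.assert_array_equal(to_grey(grey_image, "average").pixels, grey_image.pixels)

    def test_to_grey_invalid_channel(self, rgb_image):
        with pytest.raises(ParameterError):
            to_grey(rgb_image, "channel:7")

    def test_invert_involution_and_values(self, rgb_image):
        assert invert(RasterImage(np.zeros((2, 2)), bit_depth=8)).grey2d[0, 0] == 255
        img16 = RasterImage(np.full((2, 2), 40000.0), bit_depth=16)
        assert invert(img16).grey2d[0, 0] == 25535
        np.testing.assert_array_equal(invert(invert(rgb_image)).pixels, rgb_image.pixels)

    def test_downscale_identity_and_constant(self):
        const = RasterImage(np.full((10, 10), 37.0), bit_depth=8, pixel_size_um=1.5)
        assert downscale(const, 1).pixels.shape == const.pixels.shape
        small = downscale(const, 10)
        assert small.pixels.shape == (1, 1, 1)
        assert small.pixels[0, 0, 0] == 37.0
        assert small.pixel_size_um == 15.0

    def test_downscale_equals_block_mean_oracle(self, rng):
        data = rng.integers(0, 256, (40, 60)).astype(float)
        out = downscale(RasterImage(data, bit_depth=8), 10)
        assert out.pixels.shape == (4, 6, 1)
        expected = np.empty((4, 6))
        for i in range(4):
            for j in range(6):
                expected[i, j] = data[10 * i : 10 * i + 10, 10 * j : 10 * j + 10].mean()
        np.testing.assert_allclose(out.grey2d, expected, atol=1e-12)

    def test_downscale_preserves_total_sum(self, rng):
        data = rng.integers(0, 256, (40, 60)).astype(float)
        out = downscale(RasterImage(data, bit_depth=8), 10)
        assert np.isclose(out.grey2d.sum() * 100, data.sum())

    def test_downscale_factor_too_large(self, grey_image):
        with pytest.raises(ParameterError):
            downscale(grey_image, 100)


class TestExtractPlane:
    @pytest.fixture
    def volume(self, rng):
        return VolumeImage(rng.integers(0, 256, (8, 10, 12)).astype(float), voxel_size_um=1.0)

    def test_axial_plane_reproduces_z_slice(self, volume):
        nz, ny, nx = volume.shape
        k = 3
        plane = PlaneSpec(
            center=((nx - 1) / 2, (ny - 1) / 2, float(k)),
            normal=(0, 0, 1),
            extent=(ny, nx),
            sample_spacing_um=1.0,
        )
        out = extract_plane(volume, plane)
        np.testing.assert_allclose(out.grey2d, volume.voxels[k], atol=1e-10)

    def test_y_plane_matches_direct_slice_up_to_axis_convention(self, volume):
        # normal (0,1,0): u = x_hat, v = -z_hat; rows descend in z
        nz, ny, nx = volume.shape
        j = 4
        plane = PlaneSpec(
            center=((nx - 1) / 2, float(j), (nz - 1) / 2),
            normal=(0, 1, 0),
            extent=(nz, nx),
            sample_spacing_um=1.0,
        )
        out = extract_plane(volume, plane)
        np.testing.assert_allclose(out.grey2d, volume.voxels[::-1, j, :], atol=1e-10)

    def test_plane_outside_volume_is_fill(self, volume):
        plane = PlaneSpec(center=(1000.0, 1000.0, 1000.0), normal=(0, 0, 1), extent=(4, 4))
        out = extract_plane(volume, plane, fill=7.0)
        np.testing.assert_array_equal(out.grey2d, np.full((4, 4), 7.0))

    def test_degenerate_normal_rejected(self):
        with pytest.raises(ParameterError):
            PlaneSpec(center=(0, 0, 0), normal=(0, 0, 0))

    def test_plane_spec_text_round_trip(self):
        p = PlaneSpec(center=(1, 2, 3), normal=(0, 0.6, 0.8), in_plane_rotation=15.0,
                      extent=(32, 48), sample_spacing_um=0.5)
        q = PlaneSpec.from_text(p.to_text())
        assert q.center == p.center
        np.testing.assert_allclose(q.normal, p.normal)
        assert q.extent == p.extent


class TestOtsu:
    def test_two_level_separation(self):
        data = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)])
        img = RasterImage(data.reshape(10, 10), bit_depth=8)
        mask = otsu_threshold(img)
        assert 10 <= mask.threshold_used < 200
        np.testing.assert_array_equal(mask.pixels, img.grey2d == 200.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_between_class_variance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        vals = np.concatenate(
            [rng.normal(70, 12, n // 2), rng.normal(180, 15, n - n // 2)]
        )
        vals = np.clip(np.rint(vals), 0, 255)
        img = RasterImage(vals.reshape(20, 20), bit_depth=8)
        got = otsu_threshold(img).threshold_used

        # brute-force oracle: scan every candidate threshold
        best_t, best_v = None, -1.0
        for t in np.unique(vals):
            lo, hi = vals[vals <= t], vals[vals > t]
            if lo.size == 0 or hi.size == 0:
                continue
            v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
            if v > best_v:
                best_v, best_t = v, t
        assert got == best_t

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(RasterImage(np.full((5, 5), 9.0), bit_depth=8))


class TestComposites:
    def test_checkerboard_identity_and_quadrants(self, grey_image):
        np.testing.assert_array_equal(
            checkerboard(grey_image, grey_image, 8).pixels, grey_image.pixels
        )
        big = checkerboard(grey_image, invert(grey_image), 1000)
        np.testing.assert_array_equal(big.pixels, grey_image.pixels)
        a = RasterImage(np.zeros((4, 4)), bit_depth=8)
        b = RasterImage(np.full((4, 4), 9.0), bit_depth=8)
        board = checkerboard(a, b, 2).grey2d
        np.testing.assert_array_equal(board[:2, :2], 0)
        np.testing.assert_array_equal(board[:2, 2:], 9)
        np.testing.assert_array_equal(board[2:, :2], 9)
        np.testing.assert_array_equal(board[2:, 2:], 0)

    def test_checkerboard_dim_mismatch(self, grey_image, rgb_image):
        with pytest.raises(ParameterError):
            checkerboard(grey_image, RasterImage(np.zeros((3, 3)), bit_depth=8), 2)

    def test_fuse_overlay_blending(self, rgb_image):
        empty = BinaryMask(np.zeros((rgb_image.height, rgb_image.width), bool))
        full = BinaryMask(np.ones((rgb_image.height, rgb_image.width), bool))
        np.testing.assert_array_equal(
            fuse_overlay(rgb_image, full, (255, 255, 0), alpha=0.0).pixels, rgb_image.pixels
        )
        np.testing.assert_array_equal(
            fuse_overlay(rgb_image, empty, (255, 255, 0), alpha=1.0).pixels, rgb_image.pixels
        )
        solid = fuse_overlay(rgb_image, full, (255, 255, 0), alpha=1.0)
        assert np.all(solid.pixels == np.array([255.0, 255.0, 0.0]))
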