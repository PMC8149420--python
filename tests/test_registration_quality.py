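"""Displacement Index: block matching, the DI equation, diagnostics, statistics."""

import numpy as np
import pytest

from histoct import (
    BlockMatch,
    RasterImage,
    block_match,
    compare_di_sets,
    compute_di,
    displacement_index,
    render_di_diagnostic,
)
from histoct.core_imaging import DegenerateInputError, ParameterError
from histoct.registration_quality import _binned, _mi_counts


def _mk(d_len, mi):
    return BlockMatch(0, (0.0, 0.0), (d_len, 0), mi)


class TestDisplacementIndexEquation:
    def test_hand_evaluated_two_block_case(self):
        """Two blocks (d=5, MI=0.5) and (d=10, MI=2.0): G=2.5, DI=(2*5+0.5*10)/2.5=6."""
        res = displacement_index([_mk(5.0, 0.5), _mk(10.0, 2.0)])
        assert res.g == pytest.approx(2.5)
        assert res.di == pytest.approx(6.0)

    def test_zero_displacements_give_zero(self):
        res = displacement_index([_mk(0.0, 0.3), _mk(0.0, 1.7)])
        assert res.di == 0.0

    def test_equal_mi_reduces_to_mean_displacement(self):
        ds = [3.0, 5.0, 7.0, 9.0]
        res = displacement_index([_mk(d, 0.8) for d in ds])
        assert res.di == pytest.approx(np.mean(ds))

    def test_invariant_to_block_order_and_mi_scaling(self, rng):
        blocks = [_mk(rng.uniform(0, 10), rng.uniform(0.1, 2)) for _ in range(12)]
        base = displacement_index(blocks).di
        shuffled = list(blocks)
        rng.shuffle(shuffled)
        assert displacement_index(shuffled).di == pytest.approx(base)
        scaled = [BlockMatch(b.block_index, b.block_center_px, b.displacement_vec, 3.7 * b.mi)
                  for b in blocks]
        assert displacement_index(scaled).di == pytest.approx(base)

    def test_scales_linearly_with_displacements(self, rng):
        blocks = [_mk(rng.uniform(0, 10), rng.uniform(0.1, 2)) for _ in range(8)]
        doubled = [BlockMatch(b.block_index, b.block_center_px,
                              (2 * b.displacement_vec[0], 2 * b.displacement_vec[1]), b.mi)
                   for b in blocks]
        assert displacement_index(doubled).di == pytest.approx(2 * displacement_index(blocks).di)

    def test_no_blocks_rejected(self):
        with pytest.raises(DegenerateInputError):
            displacement_index([])


class TestBlockMatch:
    @pytest.fixture
    def textured(self, rng):
        from scipy import ndimage

        smooth = ndimage.gaussian_filter(rng.standard_normal((96, 96)), 2)
        return 128 + 120 * smooth / np.abs(smooth).max()

    def test_self_match_is_zero_everywhere(self, textured):
        for b in block_match(textured, textured, 32, 0.5, 8):
            assert b.displacement_vec == (0, 0)

    def test_known_integer_shift_recovered(self, textured):
        shifted = np.roll(textured, (7, -3), axis=(0, 1))
        # 8 bins: a 32 px block holds 1024 samples, so a 32-bin joint
        # histogram would be too sparse for a reliable argmax
        blocks = block_match(textured, shifted, 32, 0.5, 10, mi_bins=8)
        # keep blocks whose true-offset window stays inside the frame and
        # clear of np.roll's wrap-around seam
        interior = [b for b in blocks
                    if 24 <= b.block_center_px[0] <= 72 and 24 <= b.block_center_px[1] <= 72]
        assert interior
        for b in interior:
            assert b.displacement_vec == (7, -3)

    def test_matches_brute_force_oracle(self, rng):
        """Exhaustive double-loop oracle over all offsets on a small instance."""
        from scipy import ndimage

        f = 128 + 100 * ndimage.gaussian_filter(rng.standard_normal((64, 64)), 1.5)
        m = np.roll(f, (2, 1), axis=(0, 1)) + rng.normal(0, 2, f.shape)
        bins, bs, radius = 8, 32, 4
        got = block_match(f, m, bs, 0.5, radius, mi_bins=bins,
                          background_value=-1e9, background_tol=0.0)
        fb, mb = _binned(f, bins), _binned(m, bins)
        idx = 0
        expected = {}
        for r0 in range(0, 64 - bs + 1, bs // 2):
            for c0 in range(0, 64 - bs + 1, bs // 2):
                best = (-np.inf, None, (np.inf, np.inf, np.inf))
                for dr in range(-radius, radius + 1):
                    for dc in range(-radius, radius + 1):
                        rs, cs = r0 + dr, c0 + dc
                        if rs < 0 or cs < 0 or rs + bs > 64 or cs + bs > 64:
                            continue
                        joint = np.zeros((bins, bins))
                        for i in range(bs):
                            for j in range(bs):
                                joint[fb[r0 + i, c0 + j], mb[rs + i, cs + j]] += 1
                        mi = _mi_counts(joint, bs * bs)
                        key = (dr * dr + dc * dc, dr, dc)
                        if mi > best[0] or (mi == best[0] and key < best[2]):
                            best = (mi, (dr, dc), key)
                expected[idx] = best
                idx += 1
        for b in got:
            mi, off, _ = expected[b.block_index]
            assert b.displacement_vec == off
            assert b.mi == pytest.approx(mi, abs=1e-12)

    def test_block_larger_than_image_rejected(self, textured):
        with pytest.raises(ParameterError):
            block_match(textured, textured, 1000, 0.5, 4)

    def test_background_blocks_excluded(self, rng):
        f = np.zeros((96, 96))
        f[40:, 40:] = 100 + rng.normal(0, 5, (56, 56))
        blocks = block_match(f, f, 32, 0.5, 4, background_value=0.0, background_tol=0.5)
        centers = [b.block_center_px for b in blocks]
        assert (15.5, 15.5) not in centers  # pure-background corner tile dropped
        assert blocks  # textured tiles retained


class TestDiagnosticsAndStats:
    def test_perfect_match_renders_no_displacement_lines(self, rng):
        from scipy import ndimage

        f = RasterImage(
            128 + 100 * ndimage.gaussian_filter(rng.standard_normal((64, 64)), 2), bit_depth=8
        )
        res = compute_di(f, f, block_size_px=32, overlap_fraction=0.5, search_radius_px=4)
        assert res.di == 0.0
        img = render_di_diagnostic(f, f, res)
        img2 = render_di_diagnostic(f, f, res)
        np.testing.assert_array_equal(img.pixels, img2.pixels)  # deterministic
        # red lines are single pixels (zero length) when displacement is zero
        red = (img.pixels[:, :, 0] == 255) & (img.pixels[:, :, 1] == 0)
        assert red.sum() == len(res.blocks)

    def test_largest_circle_goes_to_max_mi_block(self, rng):
        from scipy import ndimage

        f = RasterImage(
            128 + 100 * ndimage.gaussian_filter(rng.standard_normal((64, 64)), 2), bit_depth=8
        )
        res = compute_di(f, f, block_size_px=32, overlap_fraction=0.5, search_radius_px=2)
        best = max(res.blocks, key=lambda b: b.mi)
        img = render_di_diagnostic(f, f, res)
        greenish = img.pixels[:, :, 1] > img.pixels[:, :, 0]
        # the most confident block's centre must be inside a green circle
        assert greenish[int(best.block_center_px[0]), int(best.block_center_px[1])]

    def test_t_test_identical_groups(self):
        t, p, means, sds = compare_di_sets([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_t_test_matches_hand_pooled_variance(self):
        before = [1.0, 2.0, 3.0]
        after = [11.0, 12.0, 13.0]
        t, p, means, sds = compare_di_sets(before, after)
        # pooled variance = 1, se = sqrt(1*(1/3+1/3)), t = (2-12)/se
        expected_t = (2.0 - 12.0) / np.sqrt(2.0 / 3.0)
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert means == (2.0, 12.0)
        assert sds[0] == pytest.approx(1.0)

    def test_seeded_group_simulation_is_significant(self):
        """Draws matching DI 11.7 +- 2.0 vs 6.9 +- 2.0 (n=15) separate almost surely."""
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            before = rng.normal(11.7, 2.0, 15)
            after = rng.normal(6.9, 2.0, 15)
            _, p, _, _ = compare_di_sets(before, after)
            hits += p < 0.05
        assert hits >= 99

    def test_zero_variance_groups_by_convention(self):
        t, p, _, _ = compare_di_sets([5.0, 5.0], [5.0, 5.0])
        assert (t, p) == (0.0, 1.0)

    def test_table_export_contains_summary(self, rng):
        blocks = [_mk(rng.uniform(0, 5), rng.uniform(0.5, 2)) for _ in range(4)]
        res = displacement_index(blocks)
        table = res.to_table()
        assert table.startswith("index\t")
        assert f"DI = {res.di:.6f}" in table
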