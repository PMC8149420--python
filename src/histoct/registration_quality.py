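"""Block-matching Displacement Index (DI) registration-quality metric.

The two images are tiled into blocks (default 500 px with 50 % overlap).
For each fixed-image block the integer offset within a search radius that
maximises the mutual information with the correspondingly shifted moving
block is found; the offset is the block's displacement vector ``d_i`` and
the maximal MI its similarity weight ``MI_i``.  The Displacement Index is
the inverse-MI-weighted mean displacement length

    DI = (1/G) * sum_i |d_i| / MI_i      with  G = sum_i 1 / MI_i ,

so blocks matched with high confidence (high MI) pull the score towards
their displacement less than poorly matched ones push it up; well-aligned
image pairs have a small DI.  Because CT and histology never show identical
content the DI of a perfect registration is positive but small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.draw import disk, line

from .core_imaging import DegenerateInputError, ParameterError, RasterImage

__all__ = [
    "BlockMatch",
    "DisplacementIndexResult",
    "block_match",
    "displacement_index",
    "compute_di",
    "render_di_diagnostic",
    "compare_di_sets",
]

_MI_FLOOR = 1e-6  # avoids 1/MI blow-up on pathological blocks


@dataclass
class BlockMatch:
    block_index: int
    block_center_px: tuple[float, float]
    displacement_vec: tuple[int, int]
    mi: float

    @property
    def displacement_len(self) -> float:
        return float(np.hypot(*self.displacement_vec))


@dataclass
class DisplacementIndexResult:
    blocks: list[BlockMatch]
    di: float
    g: float
    block_size_px: int
    overlap_fraction: float

    def to_table(self) -> str:
        lines = ["index\tcenter_row\tcenter_col\td_row\td_col\td_len\tmi"]
        for b in self.blocks:
            lines.append(
                f"{b.block_index}\t{b.block_center_px[0]:.1f}\t{b.block_center_px[1]:.1f}"
                f"\t{b.displacement_vec[0]}\t{b.displacement_vec[1]}"
                f"\t{b.displacement_len:.4f}\t{b.mi:.6f}"
            )
        lines.append(f"summary\tDI = {self.di:.6f}\tG = {self.g:.6f}\tn_blocks = {len(self.blocks)}")
        return "\n".join(lines) + "\n"


def _binned(arr: np.ndarray, bins: int) -> np.ndarray:
    """Global equal-width binning of an image to integer bin labels.

    Blocks are compared on globally binned intensities so that the MI
    weights of different blocks are on a common footing.
    """
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.int64)
    idx = ((arr - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def _mi_counts(joint: np.ndarray, n: int) -> float:
    p = joint / n
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (pa[:, None] * pb[None, :])[nz])))


def block_match(
    fixed: RasterImage | np.ndarray,
    moving: RasterImage | np.ndarray,
    block_size_px: int = 500,
    overlap_fraction: float = 0.5,
    search_radius_px: int | None = None,
    mi_bins: int = 32,
    background_value: float | None = None,
    background_tol: float | None = None,
) -> list[BlockMatch]:
    """Exhaustive integer-offset block matching maximising per-block MI.

    Blocks tile the fixed image on a stride of
    ``block_size_px * (1 - overlap_fraction)`` anchored at the origin;
    partial blocks at the right/bottom edge are dropped.  For each block
    every offset with the shifted moving window fully inside the image is
    scored.  Ties prefer the smallest displacement magnitude (then scan
    order).  Blocks whose fixed tile is more than 90 % background are
    excluded.  The default search radius is ``block_size_px // 4``.
    """
    f = fixed.grey2d if isinstance(fixed, RasterImage) else np.asarray(fixed, dtype=np.float64)
    m = moving.grey2d if isinstance(moving, RasterImage) else np.asarray(moving, dtype=np.float64)
    if f.shape != m.shape:
        raise ParameterError("fixed and moving must share dimensions")
    h, w = f.shape
    if block_size_px > min(h, w):
        raise ParameterError(f"block size {block_size_px} exceeds image {h}x{w}")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ParameterError("overlap_fraction must lie in [0, 1)")
    radius = block_size_px // 4 if search_radius_px is None else int(search_radius_px)
    stride = max(1, int(round(block_size_px * (1.0 - overlap_fraction))))
    # default background model: the image border of a sectioned-tissue frame is
    # paraffin/air; noise and texture keep it off a single fill value, so a band
    # around the border median stands in for "equals the fill value".  When the
    # border is no flatter than the image interior there is no background frame
    # and the admission filter stays inactive.
    border = np.concatenate([f[0], f[-1], f[:, 0], f[:, -1]])
    if background_value is not None:
        bg = float(background_value)
        bg_tol = 0.0 if background_tol is None else float(background_tol)
    elif border.std() < 0.5 * f.std():
        bg = float(np.median(border))
        bg_tol = (
            max(0.02 * float(np.ptp(f)), 3.0 * float(border.std()))
            if background_tol is None
            else float(background_tol)
        )
    else:
        bg, bg_tol = float(f.min()) - 1.0, 0.0  # matches nothing

    fb = _binned(f, mi_bins)
    mb = _binned(m, mi_bins)
    bins = mi_bins
    npix = block_size_px * block_size_px

    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
    ]
    offsets.sort(key=lambda o: (o[0] * o[0] + o[1] * o[1], o[0], o[1]))

    matches: list[BlockMatch] = []
    index = 0
    for r0 in range(0, h - block_size_px + 1, stride):
        for c0 in range(0, w - block_size_px + 1, stride):
            tile_f = f[r0 : r0 + block_size_px, c0 : c0 + block_size_px]
            if np.mean(np.abs(tile_f - bg) <= bg_tol) > 0.9:
                index += 1
                continue
            tile_fb = fb[r0 : r0 + block_size_px, c0 : c0 + block_size_px]
            flat_fb = tile_fb.ravel() * bins
            best_mi = -np.inf
            best_off = (0, 0)
            for dr, dc in offsets:
                rs, cs = r0 + dr, c0 + dc
                if rs < 0 or cs < 0 or rs + block_size_px > h or cs + block_size_px > w:
                    continue
                tile_mb = mb[rs : rs + block_size_px, cs : cs + block_size_px]
                joint = np.bincount(flat_fb + tile_mb.ravel(), minlength=bins * bins).reshape(
                    bins, bins
                )
                mi = _mi_counts(joint, npix)
                if mi > best_mi:  # offsets pre-sorted: first win = smallest |d|
                    best_mi = mi
                    best_off = (dr, dc)
            matches.append(
                BlockMatch(
                    block_index=index,
                    block_center_px=(r0 + (block_size_px - 1) / 2.0, c0 + (block_size_px - 1) / 2.0),
                    displacement_vec=best_off,
                    mi=max(best_mi, _MI_FLOOR),
                )
            )
            index += 1
    return matches


def displacement_index(blocks: list[BlockMatch]) -> DisplacementIndexResult:
    """Aggregate block matches into the scalar Displacement Index."""
    if not blocks:
        raise DegenerateInputError("no admissible blocks")
    inv_mi = np.array([1.0 / max(b.mi, _MI_FLOOR) for b in blocks])
    d_len = np.array([b.displacement_len for b in blocks])
    g = float(inv_mi.sum())
    di = float((d_len * inv_mi).sum() / g)
    # block size/overlap are unknown at this level unless recorded by the caller
    return DisplacementIndexResult(blocks=list(blocks), di=di, g=g, block_size_px=0, overlap_fraction=0.0)


def compute_di(
    fixed: RasterImage | np.ndarray,
    moving: RasterImage | np.ndarray,
    block_size_px: int = 500,
    overlap_fraction: float = 0.5,
    search_radius_px: int | None = None,
    mi_bins: int = 32,
) -> DisplacementIndexResult:
    """Block-match two images and return their Displacement Index."""
    blocks = block_match(
        fixed, moving, block_size_px, overlap_fraction, search_radius_px, mi_bins
    )
    result = displacement_index(blocks)
    result.block_size_px = block_size_px
    result.overlap_fraction = overlap_fraction
    return result


def render_di_diagnostic(
    fixed: RasterImage,
    moving: RasterImage,
    result: DisplacementIndexResult,
    magnification: float = 5.0,
) -> RasterImage:
    """Tile diagnostic: green circles sized by MI, red displacement lines.

    The circle radius in each tile is proportional to that block's MI
    (normalised to the maximum over blocks); the red line points from the
    block centre along the displacement vector, magnified for visibility.
    """
    base = fixed.grey2d if fixed.n_channels == 1 else fixed.pixels.mean(axis=2)
    h, w = base.shape
    scale = 255.0 / max(float(base.max()), 1.0)
    rgb = np.repeat((base * scale)[:, :, None], 3, axis=2)
    mi_max = max(b.mi for b in result.blocks)
    r_max = max(4.0, result.block_size_px / 2.5) if result.block_size_px else 10.0
    for b in result.blocks:
        cr, cc = b.block_center_px
        radius = max(1.0, r_max * b.mi / mi_max)
        rr, cc_idx = disk((cr, cc), radius, shape=(h, w))
        rgb[rr, cc_idx, 1] = 0.6 * rgb[rr, cc_idx, 1] + 0.4 * 255.0
        er = int(round(cr + magnification * b.displacement_vec[0]))
        ec = int(round(cc + magnification * b.displacement_vec[1]))
        er, ec = np.clip(er, 0, h - 1), np.clip(ec, 0, w - 1)
        lr, lc = line(int(round(cr)), int(round(cc)), er, ec)
        rgb[lr, lc, 0] = 255.0
        rgb[lr, lc, 1:] = 0.0
    return RasterImage(rgb, bit_depth=8, pixel_size_um=fixed.pixel_size_um)


def compare_di_sets(
    before: list[float] | np.ndarray, after: list[float] | np.ndarray
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Unpaired two-tailed Student's t-test (pooled variance) on two DI sets.

    Returns ``(t, p, (mean_before, mean_after), (sd_before, sd_after))``
    with sample standard deviations (ddof=1), matching the
    "mean +- sd (n = ...)" reporting style.  Two zero-variance groups with
    equal means give ``t = 0, p = 1`` by convention.
    """
    b = np.asarray(before, dtype=np.float64)
    a = np.asarray(after, dtype=np.float64)
    if b.size < 2 or a.size < 2:
        raise ParameterError("each group needs n >= 2")
    means = (float(b.mean()), float(a.mean()))
    sds = (float(b.std(ddof=1)), float(a.std(ddof=1)))
    if sds[0] == 0.0 and sds[1] == 0.0:
        if means[0] == means[1]:
            return 0.0, 1.0, means, sds
        return float(np.inf if means[0] > means[1] else -np.inf), 0.0, means, sds
    t, p = stats.ttest_ind(b, a, equal_var=True)
    return float(t), float(p), means, sds


def format_di_summary(values: np.ndarray | list[float]) -> str:
    """Render a DI sample as ``mean +- sd (n = k)``."""
    v = np.asarray(values, dtype=np.float64)
    return f"{v.mean():.1f} ± {v.std(ddof=1):.1f} (n = {v.size})"
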