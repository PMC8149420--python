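"""Mutual-information B-spline elastic registration.

The deformable stage models the section-induced distortion of the histology
("moving") image as a cubic B-spline free-form deformation and maximises
the mutual information (MI) between the fixed CT virtual slice and the
warped moving image.  Registration runs at 1/10 of the original resolution
(the working scale); the recovered deformation is then rescaled and applied
to every colour channel of the full-resolution moving image.

Two MI estimators coexist deliberately:

* :func:`mutual_information` — the exact joint-histogram MI in bits, used
  for evaluation, block matching and all reporting;
* a Parzen-windowed (cubic B-spline window) MI inside the optimiser, which
  is differentiable with respect to the control-point displacements and
  drives an adaptive-gain gradient ascent.

The optimiser is deterministic: full-image sampling, fixed iteration
schedule, no stochastic subsampling, so identical inputs give bit-identical
fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .bspline import (
    BSplineField,
    bspline3,
    bspline3_deriv,
    fit_field,
    zero_field,
)
from .core_imaging import (
    DegenerateInputError,
    ParameterError,
    RasterImage,
    BinaryMask,
    downscale,
    invert as invert_image,
    to_grey,
)
from .rigid_prealign import RigidTransform2D, apply_rigid, estimate_rigid

logger = logging.getLogger(__name__)

__all__ = [
    "RegistrationParams",
    "JointHistogram",
    "mutual_information",
    "joint_histogram",
    "warp",
    "register_elastic",
    "upscale_field",
    "transform_colour",
    "run_pipeline",
]


@dataclass
class RegistrationParams:
    """Tunable knobs of the elastic registration stage.

    ``downscale_factor`` and ``mi_bins`` default to the pipeline's standard
    settings (1/10 working scale, 32 intensity bins).  ``grid_spacing_px``
    is the control-point spacing at the working scale on the finest pyramid
    level; coarser levels double it.  ``step_schedule`` is
    ``(initial_step_px, decay)`` for the adaptive gain
    ``step = initial / (1 + iter / decay)``.
    """

    downscale_factor: int = 10
    mi_bins: int = 32
    grid_spacing_px: float = 16.0
    pyramid_levels: int = 3
    iterations_per_level: int = 60
    step_schedule: tuple[float, float] = (2.0, 20.0)
    bending_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mi_bins < 2:
            raise ParameterError("mi_bins must be >= 2")
        if self.downscale_factor < 1:
            raise ParameterError("downscale_factor must be >= 1")
        if self.grid_spacing_px < 2:
            raise ParameterError("grid_spacing_px must be >= 2 px")
        if self.pyramid_levels < 1:
            raise ParameterError("pyramid_levels must be >= 1")

    _KEYS = (
        "downscale_factor",
        "mi_bins",
        "grid_spacing_px",
        "pyramid_levels",
        "iterations_per_level",
        "step_schedule",
        "bending_weight",
        "seed",
    )

    def to_text(self) -> str:
        lines = []
        for key in self._KEYS:
            value = getattr(self, key)
            if isinstance(value, tuple):
                value = " ".join(repr(float(v)) for v in value)
            lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RegistrationParams":
        kv: dict[str, str] = {}
        unknown: list[str] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if "=" not in stripped:
                raise ParameterError(f"malformed parameter line {lineno}: {line!r}")
            key, _, value = stripped.partition("=")
            key = key.strip()
            if key not in cls._KEYS:
                unknown.append(key)
                continue
            kv[key] = value.strip()
        if unknown:
            raise ParameterError(f"unknown parameter keys: {', '.join(sorted(unknown))}")
        kwargs: dict = {}
        for key, raw in kv.items():
            if key in ("downscale_factor", "mi_bins", "pyramid_levels", "iterations_per_level", "seed"):
                kwargs[key] = int(raw)
            elif key == "step_schedule":
                parts = raw.split()
                kwargs[key] = (float(parts[0]), float(parts[1]))
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


@dataclass
class JointHistogram:
    """Joint intensity histogram of a paired image sample."""

    counts: np.ndarray
    edges_a: np.ndarray
    edges_b: np.ndarray
    n: int


def joint_histogram(
    a: np.ndarray, b: np.ndarray, bins: int, mask: np.ndarray | None = None
) -> JointHistogram:
    """Joint histogram with linear bin edges over each image's min..max."""
    if a.shape != b.shape:
        raise ParameterError("paired images must share dimensions")
    if bins < 2:
        raise ParameterError("bins must be >= 2")
    if mask is not None:
        av, bv = a[mask], b[mask]
        if av.size == 0:
            raise DegenerateInputError("empty mask")
    else:
        av, bv = a.ravel(), b.ravel()
    ea = np.linspace(av.min(), av.max(), bins + 1)
    eb = np.linspace(bv.min(), bv.max(), bins + 1)
    if ea[0] == ea[-1]:
        ea = ea + np.arange(bins + 1) * 1e-9  # constant image: all mass in bin 0
        ea[-1] = ea[0] + max(1e-9 * bins, 1e-9)
    if eb[0] == eb[-1]:
        eb = eb + np.arange(bins + 1) * 1e-9
        eb[-1] = eb[0] + max(1e-9 * bins, 1e-9)
    counts, _, _ = np.histogram2d(av, bv, bins=[ea, eb])
    return JointHistogram(counts, ea, eb, int(av.size))


def _mi_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    outer = pa[:, None] * pb[None, :]
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


def mutual_information(
    a: RasterImage | np.ndarray,
    b: RasterImage | np.ndarray,
    bins: int = 32,
    mask: BinaryMask | np.ndarray | None = None,
) -> float:
    """Exact joint-histogram mutual information in bits.

    ``MI = sum p(x, y) log2[p(x, y) / (p(x) p(y))]`` over a ``bins x bins``
    joint histogram with linear edges spanning each image's intensity range;
    empty cells contribute zero.
    """
    aa = a.grey2d if isinstance(a, RasterImage) else np.asarray(a, dtype=np.float64)
    bb = b.grey2d if isinstance(b, RasterImage) else np.asarray(b, dtype=np.float64)
    m = mask.pixels if isinstance(mask, BinaryMask) else mask
    return _mi_from_counts(joint_histogram(aa, bb, bins, m).counts)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------


def warp(img: RasterImage, field_: BSplineField, fill: float = 0.0) -> RasterImage:
    """Backward-warp a single-channel image: ``out(x) = img(x + D(x))``."""
    if img.n_channels != 1:
        raise ParameterError("warp expects a single-channel image; use transform_colour")
    if field_.domain != (img.height, img.width):
        raise ParameterError(
            f"field domain {field_.domain} does not match image {img.height}x{img.width}"
        )
    out = _warp_array(img.grey2d, field_.dense(), fill)
    return RasterImage(
        np.clip(out, 0, img.max_value), img.bit_depth, img.pixel_size_um, img.channel_names
    )


def _warp_array(arr: np.ndarray, dense: np.ndarray, fill: float) -> np.ndarray:
    h, w = arr.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
    return ndimage.map_coordinates(
        arr,
        [rr + dense[:, :, 0], cc + dense[:, :, 1]],
        order=1,
        mode="constant",
        cval=fill,
    )


def transform_colour(
    moving: RasterImage, field_: BSplineField, fill: float | tuple[float, ...] = 0.0
) -> RasterImage:
    """Apply the same deformation to every channel and re-merge in order."""
    if field_.domain != (moving.height, moving.width):
        raise ParameterError(
            f"field domain {field_.domain} does not match image "
            f"{moving.height}x{moving.width}"
        )
    fills = (
        tuple(fill) if isinstance(fill, (tuple, list)) else (float(fill),) * moving.n_channels
    )
    if len(fills) != moving.n_channels:
        raise ParameterError("one fill value per channel required")
    dense = field_.dense()
    out = np.empty_like(moving.pixels)
    for c in range(moving.n_channels):
        out[:, :, c] = _warp_array(moving.pixels[:, :, c], dense, fills[c])
    return RasterImage(
        np.clip(out, 0, moving.max_value),
        moving.bit_depth,
        moving.pixel_size_um,
        moving.channel_names,
    )


def upscale_field(field_: BSplineField, factor: int, full_domain: tuple[int, int]) -> BSplineField:
    """Rescale a working-scale deformation to the full-resolution domain.

    Control-point spacing, lattice origin and the displacement vectors are
    all multiplied by ``factor``; the domain becomes ``full_domain``.
    """
    factor = int(factor)
    if factor < 1:
        raise ParameterError("factor must be >= 1")
    return BSplineField(
        field_.control_points * factor,
        field_.spacing_px * factor,
        (field_.origin_px[0] * factor, field_.origin_px[1] * factor),
        full_domain,
        dict(field_.metadata),
    )


# ---------------------------------------------------------------------------
# the optimiser
# ---------------------------------------------------------------------------


def _percentile_edges(values: np.ndarray, bins: int) -> tuple[float, float]:
    lo, hi = np.percentile(values, [1.0, 99.0])
    if hi <= lo:
        lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        hi = lo + 1.0
    return float(lo), float(hi)


class _ParzenMI:
    """Differentiable Parzen-window MI between a fixed image and a warped moving image.

    The fixed intensity is hard-binned; the moving intensity is distributed
    over bins with a cubic B-spline window, which makes the joint density —
    and hence MI — smooth in the moving intensities.  Intensity ranges are
    clamped to the 1st..99th percentiles so hot pixels cannot stretch the
    histogram.
    """

    def __init__(
        self,
        fixed: np.ndarray,
        moving: np.ndarray,
        bins: int,
        mask: np.ndarray,
    ) -> None:
        self.bins = bins
        self.mask = mask
        f_lo, f_hi = _percentile_edges(fixed[mask], bins)
        m_lo, m_hi = _percentile_edges(moving[mask], bins)
        self.f_idx = np.clip(
            ((fixed - f_lo) / (f_hi - f_lo) * bins).astype(np.int64), 0, bins - 1
        )
        self.m_lo, self.m_scale = m_lo, (bins - 3) / (m_hi - m_lo)  # keep window inside

    def value_and_pixel_grad(
        self, warped: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """MI (nats) of (fixed, warped) and dMI/dwarped per pixel."""
        bins = self.bins
        mask = self.mask
        u = 1.0 + (warped - self.m_lo) * self.m_scale  # continuous bin coordinate
        u = np.clip(u, 1.0, bins - 2.0)
        base = np.floor(u).astype(np.int64)
        base = np.clip(base, 1, bins - 3)
        frac = u - base

        n = int(mask.sum())
        fi = self.f_idx[mask]
        base_m = base[mask]
        frac_m = frac[mask]

        counts = np.zeros((bins, bins))
        wgts = []
        for off in (-1, 0, 1, 2):
            w = bspline3(frac_m - off)
            wgts.append(w)
            np.add.at(counts, (fi, base_m + off), w)
        p = counts / n
        pm = p.sum(axis=0)
        pf = p.sum(axis=1)
        nz = p > 1e-300
        mi = float(np.sum(p[nz] * np.log(p[nz] / (pf[:, None] * pm[None, :])[nz])))

        # dMI/du per masked pixel: sum_m beta3'(u - m) * log(p(f, m)/pm(m)) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            logterm = np.where(nz, np.log(np.maximum(p, 1e-300) / np.maximum(pm[None, :], 1e-300)), 0.0)
        du = np.zeros(n)
        for off, w in zip((-1, 0, 1, 2), wgts):
            dw = bspline3_deriv(frac_m - off)
            du += dw * logterm[fi, base_m + off]
        du /= n
        grad = np.zeros_like(warped)
        grad[mask] = du * self.m_scale  # chain rule u -> intensity
        return mi, grad


def _level_images(img: np.ndarray, factor: int) -> np.ndarray:
    """Smoothed + area-averaged pyramid level (factor a power of two)."""
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, sigma=0.5 * factor)
    h, w = (sm.shape[0] // factor) * factor, (sm.shape[1] // factor) * factor
    return sm[:h, :w].reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def register_elastic(
    fixed: RasterImage,
    moving: RasterImage,
    params: RegistrationParams | None = None,
    fixed_fill: float | None = None,
    moving_fill: float | None = None,
) -> BSplineField:
    """Estimate the B-spline deformation maximising MI(fixed, warp(moving)).

    Coarse-to-fine over ``params.pyramid_levels`` resolution levels with
    control-grid spacing halving per level.  Every candidate field is scored
    with the exact 32-bin histogram MI and the best-scoring field (the zero
    field included) is returned, so the result never has lower MI than the
    unregistered pair.  ``field.metadata`` records the MI trace and a
    ``converged`` flag.
    """
    params = params or RegistrationParams()
    if fixed.n_channels != 1 or moving.n_channels != 1:
        raise ParameterError("register_elastic expects single-channel images")
    if (fixed.height, fixed.width) != (moving.height, moving.width):
        raise ParameterError("fixed and moving must share dimensions")

    f_full = fixed.grey2d.astype(np.float64)
    m_full = moving.grey2d.astype(np.float64)
    h, w = f_full.shape
    f_fill = float(f_full.min()) if fixed_fill is None else float(fixed_fill)
    m_fill = float(m_full.min()) if moving_fill is None else float(moving_fill)

    levels = params.pyramid_levels
    best_field = zero_field((h, w), params.grid_spacing_px)
    # exact-MI scoring happens at full working resolution throughout
    score_mask = ~((f_full == f_fill) & (m_full == m_fill))
    if not score_mask.any():
        raise DegenerateInputError("both images are entirely background")

    def exact_score(fld: BSplineField) -> float:
        warped = _warp_array(m_full, fld.dense(), m_fill)
        return mutual_information(f_full, warped, params.mi_bins, score_mask)

    mi_initial = exact_score(best_field)
    best_mi = mi_initial
    trace = [mi_initial]
    current = best_field

    for level in range(levels):
        ds = 2 ** (levels - 1 - level)
        spacing_work = params.grid_spacing_px * ds
        f_lvl = _level_images(f_full, ds)
        m_lvl = _level_images(m_full, ds)
        hl, wl = f_lvl.shape
        spacing_lvl = spacing_work / ds
        if min(hl, wl) < 2 * spacing_lvl:
            continue  # level too small for this grid

        # carry the current working-scale field into level coordinates
        dense_work = current.dense()  # (h, w, 2)
        dense_lvl = np.stack(
            [_level_images(dense_work[:, :, 0], ds), _level_images(dense_work[:, :, 1], ds)],
            axis=-1,
        ) / ds
        fld = fit_field(dense_lvl, spacing_lvl)

        mask_lvl = ~((f_lvl == f_fill) & (m_lvl == m_fill))
        if not mask_lvl.any():
            continue
        # Parzen bin edges come from the unwarped moving image at this level
        parzen = _ParzenMI(f_lvl, m_lvl, params.mi_bins, mask_lvl)
        br, bc = fld.basis()
        g_r, g_c = np.gradient(m_lvl)
        step0, decay = params.step_schedule

        rr, cc = np.meshgrid(
            np.arange(hl, dtype=np.float64), np.arange(wl, dtype=np.float64), indexing="ij"
        )
        for it in range(params.iterations_per_level):
            dense = np.stack(
                [br @ fld.control_points[:, :, 0] @ bc.T, br @ fld.control_points[:, :, 1] @ bc.T],
                axis=-1,
            )
            pr, pc = rr + dense[:, :, 0], cc + dense[:, :, 1]
            warped = ndimage.map_coordinates(m_lvl, [pr, pc], order=1, mode="constant", cval=m_fill)
            mi, pix_grad = parzen.value_and_pixel_grad(warped)
            # spatial gradient of the moving image sampled at the warped positions
            gr = ndimage.map_coordinates(g_r, [pr, pc], order=1, mode="nearest")
            gc = ndimage.map_coordinates(g_c, [pr, pc], order=1, mode="nearest")
            wr_grad = br.T @ (pix_grad * gr) @ bc
            wc_grad = br.T @ (pix_grad * gc) @ bc
            if params.bending_weight > 0:
                wr_grad -= params.bending_weight * _bending_grad(fld.control_points[:, :, 0])
                wc_grad -= params.bending_weight * _bending_grad(fld.control_points[:, :, 1])
            gmax = max(np.abs(wr_grad).max(), np.abs(wc_grad).max(), 1e-12)
            gain = step0 / (1.0 + it / decay)
            fld.control_points[:, :, 0] += gain * wr_grad / gmax
            fld.control_points[:, :, 1] += gain * wc_grad / gmax

            # promote to working scale and score with the exact metric
            cand = BSplineField(
                fld.control_points * ds,
                spacing_work,
                (fld.origin_px[0] * ds, fld.origin_px[1] * ds),
                (h, w),
            )
            score = exact_score(cand)
            trace.append(score)
            if score > best_mi:
                best_mi = score
                best_field = cand
        current = best_field

    converged = best_mi >= mi_initial - 1e-9
    if not converged:  # pragma: no cover - best-so-far includes the zero field
        logger.warning("elastic registration did not improve MI; returning best-so-far")
    # refit the winning field onto the canonical finest lattice for a tidy contract
    final = fit_field(best_field.dense(), params.grid_spacing_px)
    final.metadata.update(
        mi_initial=mi_initial,
        mi_final=best_mi,
        mi_trace=trace,
        converged=bool(converged),
    )
    return final


def _bending_grad(cp: np.ndarray) -> np.ndarray:
    """Gradient of a discrete thin-plate bending penalty on the lattice."""
    lap = (
        -4 * cp
        + np.roll(cp, 1, 0)
        + np.roll(cp, -1, 0)
        + np.roll(cp, 1, 1)
        + np.roll(cp, -1, 1)
    )
    return -2 * (
        -4 * lap
        + np.roll(lap, 1, 0)
        + np.roll(lap, -1, 0)
        + np.roll(lap, 1, 1)
        + np.roll(lap, -1, 1)
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    transformed: RasterImage
    field_full: BSplineField
    rigid: RigidTransform2D
    moving_rigid: RasterImage
    moving_grey: RasterImage
    field_working: BSplineField
    params: RegistrationParams


def run_pipeline(
    fixed: RasterImage,
    moving: RasterImage,
    params: RegistrationParams | None = None,
    channel_mode: str = "average",
    invert_flag: bool = True,
) -> PipelineResult:
    """Execute the full co-registration workflow.

    Stages: grey conversion of the moving image per ``channel_mode`` —
    optional inversion (histology content becomes bright, like CT) —
    Fourier-Mellin rigid correction — 1/10 downscale of both images —
    elastic MI/B-spline registration — rescaling of the deformation to full
    resolution — per-channel application to the rigidly corrected moving
    image.  All intermediate artefacts are returned for audit.
    """
    params = params or RegistrationParams()
    fixed_grey = to_grey(fixed, "average") if fixed.n_channels != 1 else fixed
    logger.info("stage: channel selection (%s)", channel_mode)
    moving_grey = to_grey(moving, channel_mode)
    if invert_flag:
        logger.info("stage: inversion")
        moving_grey = invert_image(moving_grey)

    logger.info("stage: Fourier-Mellin rigid pre-alignment")
    rigid = estimate_rigid(fixed_grey, moving_grey)
    m_fill = float(moving_grey.grey2d.min())
    moving_grey_rigid = apply_rigid(moving_grey, rigid, fill=m_fill)
    colour_fill = (
        tuple(float(moving.pixels[:, :, c].min()) for c in range(moving.n_channels))
    )
    moving_rigid = apply_rigid(moving, rigid, fill=0.0)

    logger.info("stage: downscale x%d", params.downscale_factor)
    fixed_small = downscale(fixed_grey, params.downscale_factor)
    moving_small = downscale(moving_grey_rigid, params.downscale_factor)

    logger.info("stage: elastic registration")
    field_working = register_elastic(
        fixed_small,
        moving_small,
        params,
        fixed_fill=float(fixed_grey.grey2d.min()),
        moving_fill=m_fill,
    )

    logger.info("stage: field rescale + per-channel transform")
    field_full = upscale_field(
        field_working, params.downscale_factor, (moving.height, moving.width)
    )
    transformed = transform_colour(moving_rigid, field_full, fill=colour_fill)
    return PipelineResult(
        transformed=transformed,
        field_full=field_full,
        rigid=rigid,
        moving_rigid=moving_rigid,
        moving_grey=moving_grey,
        field_working=field_working,
        params=params,
    )
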