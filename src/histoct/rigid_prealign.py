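"""Fourier-Mellin rigid pre-alignment.

The elastic B-spline model cannot absorb large global rotations, so before
elastic registration the moving image's global rotation and translation are
estimated spectrally: rotation from phase correlation of the polar-resampled
Fourier magnitude spectra (which are translation-invariant), translation
from phase correlation after de-rotation.  Scale is deliberately not
estimated; histological sections and their CT counterparts share pixel
calibration after preprocessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import warp_polar

from .core_imaging import DegenerateInputError, RasterImage

__all__ = ["RigidTransform2D", "estimate_rigid", "apply_rigid"]


@dataclass
class RigidTransform2D:
    """Rotation about the image centre followed by a translation.

    Maps moving-image coordinates onto fixed-image coordinates:
    ``y = R(rotation_deg) @ (x - c) + c + t`` with ``c`` the image centre
    and ``t = translation_px`` in (row, col) order.
    """

    rotation_deg: float
    translation_px: tuple[float, float]

    def __post_init__(self) -> None:
        # normalise to (-180, 180]
        r = math.fmod(self.rotation_deg, 360.0)
        if r <= -180.0:
            r += 360.0
        elif r > 180.0:
            r -= 360.0
        self.rotation_deg = r
        self.translation_px = (float(self.translation_px[0]), float(self.translation_px[1]))

    def inverse(self) -> "RigidTransform2D":
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = np.asarray(self.translation_px)
        t_inv = -rot.T @ t
        return RigidTransform2D(-self.rotation_deg, tuple(t_inv))

    def to_text(self) -> str:
        return (
            f"rotation_deg = {float(self.rotation_deg)!r}\n"
            f"translation_px = {float(self.translation_px[0])!r} "
            f"{float(self.translation_px[1])!r}\n"
            "centre = image centre\n"
        )

    @classmethod
    def from_text(cls, text: str) -> "RigidTransform2D":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
        t = [float(tok) for tok in kv["translation_px"].split()]
        return cls(float(kv["rotation_deg"]), (t[0], t[1]))


# ---------------------------------------------------------------------------
# spectral building blocks
# ---------------------------------------------------------------------------


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wr = np.hanning(shape[0]) if shape[0] > 1 else np.ones(1)
    wc = np.hanning(shape[1]) if shape[1] > 1 else np.ones(1)
    return wr[:, None] * wc[None, :]


def _highpass(shape: tuple[int, int]) -> np.ndarray:
    # classic Fourier-Mellin emphasis: H = (1 - X)(2 - X), X = cos(pi xi) cos(pi eta)
    yy = np.linspace(-0.5, 0.5, shape[0], endpoint=True)
    xx = np.linspace(-0.5, 0.5, shape[1], endpoint=True)
    x = np.cos(np.pi * yy)[:, None] * np.cos(np.pi * xx)[None, :]
    return (1.0 - x) * (2.0 - x)


def _quadratic_peak_offset(ym: float, y0: float, yp: float) -> float:
    denom = ym - 2.0 * y0 + yp
    if abs(denom) < 1e-12:
        return 0.0
    off = 0.5 * (ym - yp) / denom
    return float(np.clip(off, -0.5, 0.5))


def _phase_correlate(
    a: np.ndarray, b: np.ndarray, whitening: float = 0.0
) -> tuple[tuple[float, float], float]:
    """Subpixel shift (dr, dc) that, applied to ``b``, re-aligns it with ``a``.

    With ``b(x) = a(x - d)`` the function returns ``-d``.  Returns the
    shift and the correlation-surface peak height.  ``whitening`` softens
    the spectral normalisation (``|F| + whitening * mean|F|``): 0 is pure
    phase correlation (sharpest peak, exact on undistorted content), larger
    values down-weight decorrelated high frequencies, which keeps the peak
    stable when the images differ by more than a rigid motion.  The peak is
    refined by a separable quadratic fit around the argmax; among equal
    integer peaks numpy's argmax picks the first in scan order, and the
    wrap-around convention keeps the reported displacement magnitude small.
    """
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    cross /= np.maximum(mag + whitening * mag.mean(), 1e-15)
    surface = np.real(np.fft.ifft2(cross))
    h, w = surface.shape
    pr, pc = np.unravel_index(int(np.argmax(surface)), surface.shape)
    peak = float(surface[pr, pc])
    dr = pr + _quadratic_peak_offset(
        surface[(pr - 1) % h, pc], surface[pr, pc], surface[(pr + 1) % h, pc]
    )
    dc = pc + _quadratic_peak_offset(
        surface[pr, (pc - 1) % w], surface[pr, pc], surface[pr, (pc + 1) % w]
    )
    if dr > h / 2:
        dr -= h
    if dc > w / 2:
        dc -= w
    return (float(dr), float(dc)), peak


def _spectral_magnitude(img: np.ndarray) -> np.ndarray:
    win = _hann2d(img.shape)
    f = np.fft.fftshift(np.abs(np.fft.fft2((img - img.mean()) * win)))
    return f * _highpass(img.shape)


def _pad_to(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pad with the image's own minimum (background) to the target shape."""
    out = np.full(shape, img.min(), dtype=np.float64)
    out[: img.shape[0], : img.shape[1]] = img
    return out


def _correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

_N_ANGLES = 1440  # 0.25 deg angular sampling of the polar spectrum


def _estimate_rotation(f: np.ndarray, m: np.ndarray, n_peaks: int = 1) -> list[float]:
    """Candidate rotations (deg) of ``m`` relative to ``f`` from polar magnitude spectra.

    Only low-to-mid spatial frequencies enter the polar image (radius up to
    a quarter of the frame, DC-adjacent bins dropped): residual elastic
    distortion between modalities decorrelates high frequencies first.
    Returns the ``n_peaks`` strongest, mutually non-adjacent peaks of the
    angular correlation curve, strongest first; secondary peaks matter when
    the dominant one is an alias of a near-symmetric structure.
    """
    spec_f = _spectral_magnitude(f)
    spec_m = _spectral_magnitude(m)
    radius = max(min(f.shape) // 4, 8)
    pol_f = warp_polar(spec_f, radius=radius, output_shape=(_N_ANGLES, radius))[:, 5:]
    pol_m = warp_polar(spec_m, radius=radius, output_shape=(_N_ANGLES, radius))[:, 5:]

    fa = np.fft.fft2(pol_f - pol_f.mean())
    fb = np.fft.fft2(pol_m - pol_m.mean())
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    cross /= np.maximum(mag + 1.0 * mag.mean(), 1e-15)
    surface = np.real(np.fft.ifft2(cross))
    # no scale is estimated, so only (near-)zero radial shifts are meaningful
    curve = np.concatenate([surface[:, :3], surface[:, -2:]], axis=1).max(axis=1)
    n = curve.size
    order = np.argsort(curve)[::-1]
    rows: list[int] = []
    for idx in order:
        if len(rows) >= n_peaks:
            break
        if all(min(abs(idx - r), n - abs(idx - r)) > 8 for r in rows):
            rows.append(int(idx))
    thetas = []
    for row in rows:
        off = _quadratic_peak_offset(curve[(row - 1) % n], curve[row], curve[(row + 1) % n])
        shift = row + off
        if shift > n / 2:
            shift -= n
        # the polar row shift is the rotation that produced moving; the correction undoes it
        thetas.append(-shift * 360.0 / _N_ANGLES)
    return thetas


def _mi_score(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    lo_a, hi_a = a.min(), a.max()
    lo_b, hi_b = b.min(), b.max()
    ia = ((a - lo_a) / max(hi_a - lo_a, 1e-12) * (bins - 1)).astype(np.int64)
    ib = ((b - lo_b) / max(hi_b - lo_b, 1e-12) * (bins - 1)).astype(np.int64)
    joint = np.bincount(ia.ravel() * bins + ib.ravel(), minlength=bins * bins).reshape(bins, bins)
    p = joint / joint.sum()
    pa, pb = p.sum(axis=1), p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (pa[:, None] * pb[None, :])[nz])))


def estimate_rigid(fixed: RasterImage, moving: RasterImage) -> RigidTransform2D:
    """Estimate the rigid transform mapping ``moving`` onto ``fixed``.

    Rotation comes from the angular phase-correlation shift between the
    polar-resampled magnitude spectra; the 180-degree ambiguity inherent in
    the (symmetric) magnitude spectrum is resolved by trying both candidates
    and keeping the one whose fully applied transform shares more mutual
    information with the fixed image (a correlation score would mislead
    across modalities).  Translation is recovered by phase correlation of
    the de-rotated moving image, and a second estimation pass on the
    corrected image absorbs the residual.
    """
    if fixed.n_channels != 1 or moving.n_channels != 1:
        raise ValueError("estimate_rigid expects single-channel images")
    f = fixed.grey2d.astype(np.float64)
    m = moving.grey2d.astype(np.float64)
    shape = (max(f.shape[0], m.shape[0]), max(f.shape[1], m.shape[1]))
    if f.shape != shape:
        f = _pad_to(f, shape)
    if m.shape != shape:
        m = _pad_to(m, shape)
    if np.ptp(f) == 0 or np.ptp(m) == 0:
        raise DegenerateInputError("constant image has no usable spectrum")
    m_fill = float(m.min())

    thetas = _estimate_rotation(f, m, n_peaks=5)
    best: RigidTransform2D | None = None
    best_score = -np.inf
    for theta in thetas:
        for cand in (theta, theta + 180.0):
            m_rot = _rotate_about_centre(m, cand, fill=m_fill)
            (dr, dc), _ = _phase_correlate(f, m_rot, whitening=0.1)
            t = RigidTransform2D(cand, (dr, dc))
            moved = _apply_rigid_array(m, t, fill=m_fill)
            score = _mi_score(f, moved)
            if score > best_score:
                best_score = score
                best = t
    assert best is not None

    # refinement pass: re-estimate the residual on the corrected image
    moved = _apply_rigid_array(m, best, fill=m_fill)
    d_theta = _estimate_rotation(f, moved)[0]
    if abs(d_theta) > 90.0:  # the residual is small by construction; reject flips
        d_theta = 0.0
    m_rot = _rotate_about_centre(moved, d_theta, fill=m_fill)
    (dr, dc), _ = _phase_correlate(f, m_rot, whitening=0.1)
    refined = _compose(RigidTransform2D(d_theta, (dr, dc)), best)
    if _mi_score(f, _apply_rigid_array(m, refined, fill=m_fill)) >= best_score:
        best = refined
    return _snap_tiny(best)


def _snap_tiny(t: RigidTransform2D, eps: float = 1e-2) -> RigidTransform2D:
    """Zero out sub-resolution components so an identity pair maps exactly."""
    rot = 0.0 if abs(t.rotation_deg) < eps else t.rotation_deg
    tr = tuple(0.0 if abs(v) < eps else v for v in t.translation_px)
    return RigidTransform2D(rot, tr)


def _compose(t2: RigidTransform2D, t1: RigidTransform2D) -> RigidTransform2D:
    """The transform applying ``t1`` first, then ``t2`` (both about the centre)."""
    th2 = np.deg2rad(t2.rotation_deg)
    rot2 = np.array([[np.cos(th2), -np.sin(th2)], [np.sin(th2), np.cos(th2)]])
    t = rot2 @ np.asarray(t1.translation_px) + np.asarray(t2.translation_px)
    return RigidTransform2D(t1.rotation_deg + t2.rotation_deg, tuple(t))


def _rotate_about_centre(img: np.ndarray, angle_deg: float, fill: float) -> np.ndarray:
    return _apply_rigid_array(img, RigidTransform2D(angle_deg, (0.0, 0.0)), fill)


def _apply_rigid_array(arr: np.ndarray, t: RigidTransform2D, fill: float) -> np.ndarray:
    h, w = arr.shape
    ctr = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    th = np.deg2rad(t.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    rr, cc = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
    out_pts = np.stack([rr.ravel(), cc.ravel()])
    src = rot.T @ (out_pts - ctr[:, None] - np.asarray(t.translation_px)[:, None]) + ctr[:, None]
    # snap near-integer coordinates so lattice-preserving motions stay exact
    near = np.abs(src - np.rint(src)) < 1e-9
    src[near] = np.rint(src[near])
    return ndimage.map_coordinates(arr, src, order=1, mode="constant", cval=fill).reshape(h, w)


def apply_rigid(img: RasterImage, t: RigidTransform2D, fill: float = 0.0) -> RasterImage:
    """Resample an image under a rigid transform (bilinear, inverse mapping)."""
    out = np.empty_like(img.pixels)
    for c in range(img.n_channels):
        out[:, :, c] = _apply_rigid_array(img.pixels[:, :, c], t, fill)
    return RasterImage(
        np.clip(out, 0, img.max_value), img.bit_depth, img.pixel_size_um, img.channel_names
    )
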