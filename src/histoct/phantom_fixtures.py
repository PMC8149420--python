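"""Seeded multimodal phantom generator with known ground truth.

The phantoms emulate the content of a stained tumour section and its CT
virtual slice: cell-dense regions, collagen-like fibre strands, fat-like
voids, vessel/hole lumina and radiopaque nanoparticle clusters — the last
bright in CT but invisible in histology, which is exactly what makes the
combined 4D classification informative.  Both modalities render the SAME
geometry under different contrast rules; the histology rendering is then
misaligned by a known rigid transform plus a smooth random B-spline field
and corrupted with noise, so every pair comes with an exact deformation
and class-label ground truth for scoring registration and classification.

The truth elastic field is generated on a lattice coarser than the
registration grid, so recovery is never a same-basis identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .bspline import BSplineField, invert_dense_field, zero_field
from .core_imaging import RasterImage
from .elastic_registration import _warp_array
from .rigid_prealign import RigidTransform2D, apply_rigid

__all__ = ["PhantomSpec", "PhantomTruth", "generate_pair", "generate_cohort", "CLASS_NAMES"]

CLASS_NAMES = ("background", "tumour_cells", "fibres", "fat", "vessels", "particles")
BACKGROUND, TUMOUR, FIBRE, FAT, VESSEL, PARTICLE = range(6)


@dataclass
class PhantomSpec:
    """Parameters of one phantom pair.

    Object counts scale with the canvas; displacement bounds are in pixels
    at the generated resolution.  ``style`` selects the histology palette:
    ``"mts"`` (trichrome: red cytoplasm, blue fibres, pale voids) or
    ``"ihc"`` (brown-on-pale immunostain).
    """

    seed: int = 0
    size: tuple[int, int] = (256, 256)
    n_fibres: int = 10
    fibre_width: float = 2.5
    n_fat: int = 8
    fat_radius: tuple[float, float] = (8.0, 16.0)
    n_vessels: int = 6
    vessel_radius: tuple[float, float] = (3.0, 6.0)
    n_particle_clusters: int = 5
    particle_radius: tuple[float, float] = (2.0, 4.0)
    rigid_rotation_deg: float = 0.0
    rigid_translation_px: tuple[float, float] = (0.0, 0.0)
    elastic_max_px: float = 0.0
    elastic_spacing_px: float = 48.0
    noise_sigma: float = 2.0
    style: str = "mts"


@dataclass
class PhantomTruth:
    """Ground truth shipped with each phantom pair."""

    rigid: RigidTransform2D
    elastic: BSplineField          # the field registration should recover (moving -> fixed)
    labels: np.ndarray             # per-pixel class index on the aligned geometry

    def elastic_dense(self) -> np.ndarray:
        return self.elastic.dense()


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _draw_disks(
    labels: np.ndarray, rng: np.random.Generator, n: int, radii: tuple[float, float], value: int,
    region: np.ndarray | None = None,
) -> None:
    h, w = labels.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for _ in range(n):
        r = rng.uniform(*radii)
        cy, cx = rng.uniform(0.1 * h, 0.9 * h), rng.uniform(0.1 * w, 0.9 * w)
        if region is not None and not region[int(cy), int(cx)]:
            continue
        disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= r * r
        labels[disk] = value


def _draw_fibres(labels: np.ndarray, rng: np.random.Generator, n: int, width: float) -> None:
    h, w = labels.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    for _ in range(n):
        # a gently curved strand: offset sinusoid across the frame
        theta = rng.uniform(0, np.pi)
        c, s = np.cos(theta), np.sin(theta)
        along = c * rr + s * cc
        across = -s * rr + c * cc
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(4.0, 14.0)
        freq = rng.uniform(0.01, 0.035)
        centre = rng.uniform(0.15, 0.85) * (abs(-s) * h + abs(c) * w)
        strand = np.abs(across - centre - amp * np.sin(freq * along + phase)) < width
        labels[strand & (labels != BACKGROUND)] = FIBRE


def _tissue_outline(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """A blobby tissue silhouette occupying the central canvas."""
    h, w = spec.size
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ang = np.arctan2(rr - cy, cc - cx)
    base = 0.36 * min(h, w)
    wobble = sum(
        rng.uniform(0.02, 0.08) * base * np.sin(k * ang + rng.uniform(0, 2 * np.pi))
        for k in (2, 3, 5)
    )
    return np.hypot(rr - cy, cc - cx) <= base + wobble


def _label_image(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    labels = np.full(spec.size, BACKGROUND, dtype=np.int32)
    tissue = _tissue_outline(spec, rng)
    labels[tissue] = TUMOUR
    _draw_fibres(labels, rng, spec.n_fibres, spec.fibre_width)
    _draw_disks(labels, rng, spec.n_fat, spec.fat_radius, FAT, region=tissue)
    _draw_disks(labels, rng, spec.n_vessels, spec.vessel_radius, VESSEL, region=tissue)
    # particles drawn last so no other structure can overwrite them
    _draw_disks(labels, rng, spec.n_particle_clusters, spec.particle_radius, PARTICLE, region=tissue)
    return labels


# ---------------------------------------------------------------------------
# modality renderers
# ---------------------------------------------------------------------------

_CT_LEVELS = {
    BACKGROUND: 30.0,   # paraffin
    TUMOUR: 110.0,
    FIBRE: 150.0,
    FAT: 55.0,
    VESSEL: 45.0,
    PARTICLE: 240.0,    # radiopaque nanoparticles
}

_MTS_COLOURS = {
    BACKGROUND: (245.0, 245.0, 245.0),
    TUMOUR: (200.0, 90.0, 110.0),     # red cytoplasm
    FIBRE: (80.0, 100.0, 200.0),      # collagen blue
    FAT: (235.0, 230.0, 235.0),       # washed-out voids
    VESSEL: (240.0, 225.0, 230.0),
    PARTICLE: (200.0, 90.0, 110.0),   # invisible: rendered like surrounding tissue
}

_IHC_COLOURS = {
    BACKGROUND: (250.0, 248.0, 245.0),
    TUMOUR: (210.0, 190.0, 215.0),    # pale haematoxylin counterstain
    FIBRE: (190.0, 170.0, 200.0),
    FAT: (245.0, 243.0, 240.0),
    VESSEL: (150.0, 100.0, 60.0),     # DAB-brown positive cells around lumina
    PARTICLE: (210.0, 190.0, 215.0),  # invisible in histology
}


def _texture(
    shape: tuple[int, int], rng: np.random.Generator, scale: float = 4.0, strength: float = 0.25
) -> np.ndarray:
    """Smooth multiplicative texture so blocks and spectra are feature-rich."""
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, scale)
    sm /= max(np.abs(sm).max(), 1e-9)
    return 1.0 + strength * sm


def _render_ct(
    labels: np.ndarray, rng: np.random.Generator, shared_texture: np.ndarray
) -> np.ndarray:
    out = np.zeros(labels.shape)
    for cls, level in _CT_LEVELS.items():
        out[labels == cls] = level
    # shared density texture: tissue fine structure shows up in BOTH modalities
    out *= shared_texture * _texture(labels.shape, rng, strength=0.08)
    out = ndimage.gaussian_filter(out, 0.8)
    return np.clip(out, 0, 255)


def _render_histology(
    labels: np.ndarray, rng: np.random.Generator, style: str, shared_texture: np.ndarray
) -> np.ndarray:
    palette = _MTS_COLOURS if style == "mts" else _IHC_COLOURS
    out = np.zeros(labels.shape + (3,))
    for cls, colour in palette.items():
        out[labels == cls] = colour
    tex = shared_texture * _texture(labels.shape, rng, scale=3.0, strength=0.08)
    out *= tex[:, :, None]
    out = ndimage.gaussian_filter(out, (0.8, 0.8, 0.0))
    return np.clip(out, 0, 255)


# ---------------------------------------------------------------------------
# deformation truth
# ---------------------------------------------------------------------------


def _random_truth_field(
    shape: tuple[int, int], spacing: float, max_px: float, rng: np.random.Generator
) -> BSplineField:
    fld = zero_field(shape, spacing)
    fld.control_points[:] = rng.standard_normal(fld.control_points.shape)
    dense_max = np.linalg.norm(fld.dense(), axis=-1).max()
    if max_px <= 0 or dense_max < 1e-12:
        fld.control_points[:] = 0.0
    else:
        fld.control_points *= max_px / dense_max
    return fld


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_pair(spec: PhantomSpec) -> tuple[RasterImage, RasterImage, PhantomTruth]:
    """Generate one (ct, histology, truth) phantom triple.

    The CT image and the class labels live on the aligned ("fixed")
    geometry.  The histology image is produced from the same geometry, then
    deformed so that warping it with ``truth.elastic`` (after undoing
    ``truth.rigid``) re-aligns it with the CT: ``truth.elastic`` is the
    field an ideal elastic registration should recover.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _label_image(spec, rng)
    shared = _texture(spec.size, rng, scale=3.0, strength=0.25)
    ct = _render_ct(labels, rng, shared)
    hist_aligned = _render_histology(labels, rng, spec.style, shared)

    truth_field = _random_truth_field(
        spec.size, spec.elastic_spacing_px, spec.elastic_max_px, rng
    )
    # moving(x + D(x)) == aligned(x)  =>  moving = aligned warped by D^-1
    if spec.elastic_max_px > 0:
        inv_dense = invert_dense_field(truth_field.dense())
        hist_moving = np.stack(
            [
                _warp_array(hist_aligned[:, :, c], inv_dense, fill=float(hist_aligned[:, :, c].min()))
                for c in range(3)
            ],
            axis=-1,
        )
    else:
        hist_moving = hist_aligned.copy()

    rigid_truth = RigidTransform2D(spec.rigid_rotation_deg, spec.rigid_translation_px)
    hist_img = RasterImage(np.clip(hist_moving, 0, 255), bit_depth=8)
    if spec.rigid_rotation_deg != 0.0 or spec.rigid_translation_px != (0.0, 0.0):
        # misalign by the inverse: the pipeline's estimated correction is then rigid_truth
        hist_img = apply_rigid(hist_img, rigid_truth.inverse(), fill=245.0)

    if spec.noise_sigma > 0:
        ct = np.clip(ct + rng.normal(0, spec.noise_sigma, ct.shape), 0, 255)
        hist_px = np.clip(
            hist_img.pixels + rng.normal(0, spec.noise_sigma, hist_img.pixels.shape), 0, 255
        )
        hist_img = RasterImage(hist_px, bit_depth=8)

    ct_img = RasterImage(ct, bit_depth=8)
    return ct_img, hist_img, PhantomTruth(rigid_truth, truth_field, labels)


def generate_cohort(
    base_spec: PhantomSpec, n: int
) -> list[tuple[RasterImage, RasterImage, PhantomTruth]]:
    """Generate ``n`` phantom pairs with distinct seeds derived from the base seed."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(base_spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [generate_pair(replace(base_spec, seed=int(s))) for s in seeds]
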