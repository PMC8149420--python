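"""Image and volume data model, file I/O and basic imaging operations.

Coordinate convention (used throughout the package): pixel indices are
0-based ``(row, col)`` with pixel centres at integer coordinates.  Volumes
are indexed ``(z, y, x)`` and physical points are ``(x, y, z)`` in
micrometres; voxel ``(k, j, i)`` sits at physical position
``origin + voxel_size_um * (i, j, k)``.

Intensities are stored as ``float64`` but always lie in
``[0, 2**bit_depth - 1]``; they are rounded to the native integer dtype
only when written to disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as _PILImage
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "RasterImage",
    "VolumeImage",
    "PlaneSpec",
    "BinaryMask",
    "read_image",
    "write_image",
    "read_volume",
    "write_volume",
    "to_grey",
    "invert",
    "downscale",
    "extract_plane",
    "otsu_threshold",
    "checkerboard",
    "fuse_overlay",
    "FormatError",
    "ParameterError",
    "DegenerateInputError",
]


class FormatError(ValueError):
    """Unsupported or malformed image file content."""


class ParameterError(ValueError):
    """Invalid argument to an imaging operation."""


class DegenerateInputError(ValueError):
    """Input that makes the requested operation meaningless (e.g. constant image)."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class RasterImage:
    """A 2D single- or multi-channel intensity grid with pixel-size metadata.

    ``pixels`` has shape ``(H, W, C)`` with ``C`` in ``{1, 3}``; values are
    floats within ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size_um: float | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise FormatError(f"expected 1 or 3 channels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("image must be at least 1x1")
        self.pixels = px
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.channel_names is None:
            self.channel_names = ("R", "G", "B") if px.shape[2] == 3 else ("grey",)

    # -- convenience accessors ------------------------------------------------
    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def grey2d(self) -> np.ndarray:
        """The single channel as a 2D array (single-channel images only)."""
        if self.n_channels != 1:
            raise ParameterError("grey2d requires a single-channel image")
        return self.pixels[:, :, 0]

    def channel(self, index: int) -> np.ndarray:
        if not 0 <= index < self.n_channels:
            raise ParameterError(f"channel index {index} out of range [0, {self.n_channels})")
        return self.pixels[:, :, index]

    def copy(self) -> "RasterImage":
        return RasterImage(
            self.pixels.copy(), self.bit_depth, self.pixel_size_um, self.channel_names
        )

    def as_dtype(self) -> np.ndarray:
        """Pixels rounded and cast to the native integer dtype, channel axis squeezed."""
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        out = np.clip(np.rint(self.pixels), 0, self.max_value).astype(dtype)
        return out[:, :, 0] if self.n_channels == 1 else out


@dataclass
class VolumeImage:
    """A 3D isotropic greyscale grid, indexed ``(z, y, x)``."""

    voxels: np.ndarray
    voxel_size_um: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim != 3 or min(v.shape) < 1:
            raise FormatError(f"volume must be 3D with positive dims, got {v.shape}")
        if self.voxel_size_um <= 0:
            raise ParameterError("voxel_size_um must be positive")
        self.voxels = v
        self.origin = tuple(float(c) for c in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class PlaneSpec:
    """An oblique cutting plane through a volume.

    ``center`` is a physical point (x, y, z); ``normal`` a unit 3-vector.
    The in-plane axes are ``u = normalise(normal x z_hat)`` (falling back
    to ``x_hat`` when the normal is parallel to ``z_hat``) and
    ``v = normal x u``, both rotated by ``in_plane_rotation`` degrees about
    the normal.  Output rows run along ``v`` and columns along ``u``, with
    the centre pixel of the output at ``center``.
    """

    center: tuple[float, float, float]
    normal: tuple[float, float, float]
    in_plane_rotation: float = 0.0
    extent: tuple[int, int] = (64, 64)
    sample_spacing_um: float = 1.0

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ParameterError("plane normal must be non-degenerate")
        if abs(norm - 1.0) > 1e-9:
            n = n / norm
        self.normal = tuple(n)
        if self.extent[0] < 1 or self.extent[1] < 1:
            raise ParameterError("plane extent must be at least 1x1")
        if self.sample_spacing_um <= 0:
            raise ParameterError("sample_spacing_um must be positive")

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the in-plane unit axes (u, v) after in-plane rotation."""
        n = np.asarray(self.normal)
        u = np.cross(n, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-9:
            u = np.array([1.0, 0.0, 0.0])
        u = u / np.linalg.norm(u)
        v = np.cross(n, u)
        theta = np.deg2rad(self.in_plane_rotation)
        u_rot = np.cos(theta) * u + np.sin(theta) * v
        v_rot = -np.sin(theta) * u + np.cos(theta) * v
        return u_rot, v_rot

    def to_text(self) -> str:
        return (
            f"center = {self.center[0]} {self.center[1]} {self.center[2]}\n"
            f"normal = {self.normal[0]} {self.normal[1]} {self.normal[2]}\n"
            f"in_plane_rotation = {self.in_plane_rotation}\n"
            f"extent = {self.extent[0]} {self.extent[1]}\n"
            f"sample_spacing_um = {self.sample_spacing_um}\n"
        )

    @classmethod
    def from_text(cls, text: str) -> "PlaneSpec":
        kv: dict[str, list[float]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = [float(tok) for tok in value.split()]
        return cls(
            center=tuple(kv["center"]),
            normal=tuple(kv["normal"]),
            in_plane_rotation=kv.get("in_plane_rotation", [0.0])[0],
            extent=(int(kv["extent"][0]), int(kv["extent"][1])),
            sample_spacing_um=kv.get("sample_spacing_um", [1.0])[0],
        )


@dataclass
class BinaryMask:
    """Boolean pixel mask plus the intensity threshold that produced it."""

    pixels: np.ndarray
    threshold_used: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise FormatError("mask must be 2D")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}
_PNG_SUFFIXES = {".png"}


def read_image(path: str | Path, format: str | None = None) -> RasterImage:
    """Read an 8/16-bit TIFF or PNG into a :class:`RasterImage`.

    16-bit data is preserved without rescaling.  A 4th (alpha) channel is
    dropped with a logged warning; any other channel count is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("tif", "tiff"):
        arr = tifffile.imread(str(path))
    elif fmt == "png":
        with _PILImage.open(path) as im:
            arr = np.asarray(im)
    else:
        raise FormatError(f"unsupported image format: {fmt}")
    if arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("dropping alpha channel of %s", path)
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 2:  # grey + alpha
        logger.warning("dropping alpha channel of %s", path)
        arr = arr[:, :, 0]
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise FormatError(f"unsupported channel count {arr.shape[2]} in {path}")
    if arr.ndim not in (2, 3):
        raise FormatError(f"unsupported image dimensionality {arr.ndim} in {path}")
    bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    return RasterImage(arr.astype(np.float64), bit_depth=bit_depth)


def write_image(img: RasterImage, path: str | Path) -> None:
    """Write a :class:`RasterImage` to TIFF or PNG (suffix decides)."""
    path = Path(path)
    arr = img.as_dtype()
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(str(path), arr)
    elif path.suffix.lower() in _PNG_SUFFIXES:
        if arr.dtype == np.uint16 and arr.ndim == 3:
            raise FormatError("16-bit colour PNG is not supported; use TIFF")
        _PILImage.fromarray(arr).save(path)  # uint16 -> 16-bit grey PNG
    else:
        raise FormatError(f"unsupported output format: {path.suffix}")


def read_volume(path: str | Path) -> VolumeImage:
    """Read a volume from a multi-page TIFF or a raw file with text sidecar.

    For raw input, ``<path>.meta`` holds ``key = value`` lines with keys
    ``shape`` (nz ny nx), ``dtype`` (e.g. uint16), ``voxel_size_um`` and
    optionally ``origin`` and ``byte_order`` (little|big).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(str(path))
        if arr.ndim != 3:
            raise FormatError(f"expected multi-page TIFF volume, got shape {arr.shape}")
        bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
        return VolumeImage(arr.astype(np.float64), bit_depth=bit_depth)
    meta_path = path.with_suffix(path.suffix + ".meta")
    if not meta_path.exists():
        raise IOError(f"raw volume sidecar not found: {meta_path}")
    meta: dict[str, str] = {}
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    shape = tuple(int(tok) for tok in meta["shape"].split())
    dtype = np.dtype(meta.get("dtype", "uint16"))
    if meta.get("byte_order", "little") == "big":
        dtype = dtype.newbyteorder(">")
    arr = np.fromfile(path, dtype=dtype).reshape(shape)
    origin = tuple(float(tok) for tok in meta.get("origin", "0 0 0").split())
    return VolumeImage(
        arr.astype(np.float64),
        voxel_size_um=float(meta.get("voxel_size_um", 1.0)),
        origin=origin,
        bit_depth=16 if dtype.itemsize >= 2 else 8,
    )


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF."""
    path = Path(path)
    dtype = np.uint8 if vol.bit_depth == 8 else np.uint16
    arr = np.clip(np.rint(vol.voxels), 0, (1 << vol.bit_depth) - 1).astype(dtype)
    tifffile.imwrite(str(path), arr)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def to_grey(img: RasterImage, mode: str = "average") -> RasterImage:
    """Reduce to a single channel.

    ``mode`` is either ``"average"`` (arithmetic channel mean, rounded
    half-up to the integer grid) or ``"channel:<i>"`` selecting channel i.
    The shorthands ``r``/``g``/``b`` map to channels 0/1/2.
    """
    if img.n_channels == 1:
        return img.copy()
    shorthand = {"r": 0, "g": 1, "b": 2, "red": 0, "green": 1, "blue": 2}
    if mode in shorthand:
        mode = f"channel:{shorthand[mode]}"
    if mode == "average":
        grey = np.floor(img.pixels.mean(axis=2) + 0.5)  # round half-up
    elif mode.startswith("channel:"):
        try:
            index = int(mode.split(":", 1)[1])
        except ValueError as exc:
            raise ParameterError(f"malformed channel mode {mode!r}") from exc
        grey = img.channel(index).copy()
    else:
        raise ParameterError(f"unknown grey-conversion mode {mode!r}")
    return RasterImage(grey, img.bit_depth, img.pixel_size_um, ("grey",))


def invert(img: RasterImage) -> RasterImage:
    """Map every value v to ``(2**bit_depth - 1) - v`` per channel."""
    return RasterImage(
        img.max_value - img.pixels, img.bit_depth, img.pixel_size_um, img.channel_names
    )


def downscale(img: RasterImage, factor: int) -> RasterImage:
    """Area-average downscaling by an integer factor.

    Output dimensions are ``floor(dim / factor)``; each output pixel is the
    mean of the corresponding ``factor x factor`` block.  Trailing rows and
    columns that do not fill a complete block are dropped.
    """
    factor = int(factor)
    if factor < 1:
        raise ParameterError("downscale factor must be >= 1")
    if factor == 1:
        return img.copy()
    h, w = img.height // factor, img.width // factor
    if h < 1 or w < 1:
        raise ParameterError(
            f"factor {factor} larger than image dimensions {img.height}x{img.width}"
        )
    px = img.pixels[: h * factor, : w * factor, :]
    blocks = px.reshape(h, factor, w, factor, img.n_channels)
    out = blocks.mean(axis=(1, 3))
    size = None if img.pixel_size_um is None else img.pixel_size_um * factor
    return RasterImage(out, img.bit_depth, size, img.channel_names)


# ---------------------------------------------------------------------------
# virtual slicing
# ---------------------------------------------------------------------------


def extract_plane(vol: VolumeImage, plane: PlaneSpec, fill: float = 0.0) -> RasterImage:
    """Resample an oblique plane from a volume by trilinear interpolation.

    The output lattice is ``plane.extent`` pixels at
    ``plane.sample_spacing_um`` spacing, centred on ``plane.center``;
    samples outside the volume take the ``fill`` value.
    """
    u, v = plane.axes()
    nrow, ncol = plane.extent
    rows = (np.arange(nrow) - (nrow - 1) / 2.0) * plane.sample_spacing_um
    cols = (np.arange(ncol) - (ncol - 1) / 2.0) * plane.sample_spacing_um
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    # physical sample positions (x, y, z)
    pts = (
        np.asarray(plane.center)[None, None, :]
        + rr[:, :, None] * v[None, None, :]
        + cc[:, :, None] * u[None, None, :]
    )
    # physical -> voxel index (z, y, x)
    org = np.asarray(vol.origin)
    idx = (pts - org[None, None, :]) / vol.voxel_size_um
    coords = np.stack([idx[:, :, 2], idx[:, :, 1], idx[:, :, 0]])  # (z, y, x)
    out = ndimage.map_coordinates(
        vol.voxels, coords.reshape(3, -1), order=1, mode="constant", cval=fill
    ).reshape(nrow, ncol)
    return RasterImage(
        out, bit_depth=vol.bit_depth, pixel_size_um=plane.sample_spacing_um, channel_names=("grey",)
    )


# ---------------------------------------------------------------------------
# segmentation and composites
# ---------------------------------------------------------------------------


def otsu_threshold(img: RasterImage) -> BinaryMask:
    """Otsu threshold of a single-channel image.

    The threshold maximises the between-class variance of the integer
    intensity histogram; ties are broken towards the smallest threshold.
    The mask selects pixels strictly above the threshold.
    """
    values = np.rint(img.grey2d).astype(np.int64)
    vmin, vmax = int(values.min()), int(values.max())
    if vmin == vmax:
        raise DegenerateInputError("constant image has no Otsu threshold")
    hist = np.bincount((values - vmin).ravel(), minlength=vmax - vmin + 1).astype(np.float64)
    levels = np.arange(vmin, vmax + 1, dtype=np.float64)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    mu0_sum = np.cumsum(hist * levels)
    mu_total = mu0_sum[-1]
    # candidate threshold t: class 0 = values <= t, class 1 = values > t
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu0_sum / w0
        mu1 = (mu_total - mu0_sum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~valid] = -np.inf
    t = levels[int(np.argmax(between))]  # argmax returns the first (smallest) maximiser
    return BinaryMask(img.grey2d > t, threshold_used=float(t))


def checkerboard(a: RasterImage, b: RasterImage, tile_px: int) -> RasterImage:
    """Alternating-tile composite of two same-sized images; top-left tile from ``a``."""
    if (a.height, a.width) != (b.height, b.width):
        raise ParameterError("checkerboard inputs must share dimensions")
    if tile_px < 1:
        raise ParameterError("tile_px must be >= 1")
    if a.n_channels != b.n_channels:
        raise ParameterError("checkerboard inputs must share channel count")
    rows = np.arange(a.height) // tile_px
    cols = np.arange(a.width) // tile_px
    from_b = ((rows[:, None] + cols[None, :]) % 2).astype(bool)
    out = np.where(from_b[:, :, None], b.pixels, a.pixels)
    return RasterImage(out, a.bit_depth, a.pixel_size_um, a.channel_names)


def fuse_overlay(
    base: RasterImage,
    overlay_mask: BinaryMask,
    colour: tuple[float, float, float] = (255.0, 255.0, 0.0),
    alpha: float = 0.5,
) -> RasterImage:
    """Alpha-blend a pseudo-colour into the masked pixels of ``base``.

    Masked pixels become ``alpha * colour + (1 - alpha) * base``; all others
    are unchanged.  A greyscale base is promoted to RGB.
    """
    if overlay_mask.pixels.shape != (base.height, base.width):
        raise ParameterError("mask dimensions must match the base image")
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError("alpha must lie in [0, 1]")
    px = base.pixels
    if base.n_channels == 1:
        px = np.repeat(px, 3, axis=2)
    out = px.copy()
    col = np.asarray(colour, dtype=np.float64)
    m = overlay_mask.pixels
    out[m] = alpha * col[None, :] + (1.0 - alpha) * px[m]
    return RasterImage(out, base.bit_depth, base.pixel_size_um, ("R", "G", "B"))
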