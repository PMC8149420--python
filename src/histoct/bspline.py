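"""Cubic B-spline free-form deformation fields.

A :class:`BSplineField` stores a lattice of 2D control-point displacement
vectors with uniform spacing.  The dense displacement at pixel ``x`` is the
tensor-product cubic B-spline interpolation of the lattice,

    D(x) = sum_kl  beta3((x_r - o_r)/s - k) * beta3((x_c - o_c)/s - l) * c_kl

where ``beta3`` is the centred cubic B-spline kernel with support (-2, 2),
``o`` the lattice origin and ``s`` the spacing.  The canonical lattice for a
domain of H x W pixels starts at origin ``-s`` and has
``floor((dim - 1)/s) + 4`` control points per axis so that the cubic support
covers every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["BSplineField", "bspline3", "basis_matrix", "zero_field", "fit_field"]


def bspline3(t: np.ndarray) -> np.ndarray:
    """Centred cubic B-spline kernel, support (-2, 2), integral 1."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    near = t < 1.0
    far = (t >= 1.0) & (t < 2.0)
    out[near] = 2.0 / 3.0 - t[near] ** 2 + 0.5 * t[near] ** 3
    out[far] = (2.0 - t[far]) ** 3 / 6.0
    return out


def bspline3_deriv(t: np.ndarray) -> np.ndarray:
    """Derivative of the centred cubic B-spline kernel."""
    t = np.asarray(t, dtype=np.float64)
    a = np.abs(t)
    out = np.zeros_like(t)
    near = a < 1.0
    far = (a >= 1.0) & (a < 2.0)
    out[near] = -2.0 * t[near] + 1.5 * t[near] * a[near]
    out[far] = -0.5 * np.sign(t[far]) * (2.0 - a[far]) ** 2
    return out


def n_control_points(dim: int, spacing: float) -> int:
    return int(np.floor((dim - 1) / spacing)) + 4


def basis_matrix(n_pixels: int, origin: float, spacing: float, n_cp: int) -> np.ndarray:
    """Dense (n_pixels x n_cp) matrix of cubic B-spline basis weights."""
    x = np.arange(n_pixels, dtype=np.float64)
    t = (x - origin) / spacing
    return bspline3(t[:, None] - np.arange(n_cp, dtype=np.float64)[None, :])


@dataclass
class BSplineField:
    """Control-point lattice of 2D displacements over an image domain.

    ``control_points`` has shape (Kr, Kc, 2) with displacement components
    ordered (row, col) in pixels.  ``origin_px`` is the (row, col) position
    of control point (0, 0); ``domain`` the (H, W) it applies to.
    """

    control_points: np.ndarray
    spacing_px: float
    origin_px: tuple[float, float]
    domain: tuple[int, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cp = np.asarray(self.control_points, dtype=np.float64)
        if cp.ndim != 3 or cp.shape[2] != 2:
            raise ValueError(f"control_points must have shape (Kr, Kc, 2), got {cp.shape}")
        if not np.all(np.isfinite(cp)):
            raise ValueError("control-point displacements must be finite")
        self.control_points = cp
        self.domain = (int(self.domain[0]), int(self.domain[1]))
        self.origin_px = (float(self.origin_px[0]), float(self.origin_px[1]))

    # -- evaluation -----------------------------------------------------------
    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.domain
        br = basis_matrix(h, self.origin_px[0], self.spacing_px, self.control_points.shape[0])
        bc = basis_matrix(w, self.origin_px[1], self.spacing_px, self.control_points.shape[1])
        return br, bc

    def dense(self) -> np.ndarray:
        """Dense (H, W, 2) displacement field over the domain."""
        br, bc = self.basis()
        dr = br @ self.control_points[:, :, 0] @ bc.T
        dc = br @ self.control_points[:, :, 1] @ bc.T
        return np.stack([dr, dc], axis=-1)

    def at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Displacements at arbitrary (row, col) positions; shape (..., 2)."""
        rows = np.asarray(rows, dtype=np.float64)
        cols = np.asarray(cols, dtype=np.float64)
        kr, kc = self.control_points.shape[:2]
        tr = (rows.ravel()[:, None] - self.origin_px[0]) / self.spacing_px
        tc = (cols.ravel()[:, None] - self.origin_px[1]) / self.spacing_px
        wr = bspline3(tr - np.arange(kr)[None, :])
        wc = bspline3(tc - np.arange(kc)[None, :])
        dr = np.einsum("nk,kl,nl->n", wr, self.control_points[:, :, 0], wc)
        dc = np.einsum("nk,kl,nl->n", wr, self.control_points[:, :, 1], wc)
        return np.stack([dr, dc], axis=-1).reshape(rows.shape + (2,))

    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.dense(), axis=-1).max())

    # -- serialisation --------------------------------------------------------
    def to_text(self) -> str:
        kr, kc = self.control_points.shape[:2]
        lines = [
            f"lattice = {kr} {kc}",
            f"spacing_px = {self.spacing_px!r}",
            f"origin_px = {self.origin_px[0]!r} {self.origin_px[1]!r}",
            f"domain = {self.domain[0]} {self.domain[1]}",
            "displacements =",
        ]
        for k in range(kr):
            for l in range(kc):
                dr, dc = self.control_points[k, l]
                lines.append(f"{float(dr)!r} {float(dc)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "BSplineField":
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        kv: dict[str, str] = {}
        disp_start = None
        for i, ln in enumerate(lines):
            key, _, value = ln.partition("=")
            key = key.strip()
            if key == "displacements":
                disp_start = i + 1
                break
            kv[key] = value.strip()
        kr, kc = (int(tok) for tok in kv["lattice"].split())
        origin = tuple(float(tok) for tok in kv["origin_px"].split())
        domain = tuple(int(tok) for tok in kv["domain"].split())
        cp = np.array(
            [[float(tok) for tok in ln.split()] for ln in lines[disp_start : disp_start + kr * kc]]
        ).reshape(kr, kc, 2)
        return cls(cp, float(kv["spacing_px"]), origin, domain)


def zero_field(domain: tuple[int, int], spacing_px: float) -> BSplineField:
    """The identity deformation on the canonical lattice for ``domain``."""
    h, w = domain
    kr, kc = n_control_points(h, spacing_px), n_control_points(w, spacing_px)
    return BSplineField(
        np.zeros((kr, kc, 2)), spacing_px, (-spacing_px, -spacing_px), (h, w)
    )


def fit_field(dense: np.ndarray, spacing_px: float) -> BSplineField:
    """Least-squares B-spline fit of a dense (H, W, 2) displacement field.

    Solves the separable normal equations for the canonical lattice.  Exact
    whenever the dense field already lies in the spline space (e.g. when
    refining a coarser lattice whose spacing is a multiple of the target).
    """
    h, w = dense.shape[:2]
    f = zero_field((h, w), spacing_px)
    br, bc = f.basis()
    # regularised LSQ keeps corner control points (barely covered by pixels) bounded
    lam = 1e-8
    ar = br.T @ br + lam * np.eye(br.shape[1])
    ac = bc.T @ bc + lam * np.eye(bc.shape[1])
    for comp in range(2):
        rhs = br.T @ dense[:, :, comp] @ bc
        f.control_points[:, :, comp] = np.linalg.solve(ar, np.linalg.solve(ac, rhs.T).T)
    return f


def invert_dense_field(dense: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Fixed-point inverse of a dense backward displacement field.

    Finds ``Dinv`` with ``Dinv(y) = -D(y + Dinv(y))`` so that composing the
    two displacement maps returns (approximately) the identity.  Converges
    for the smooth, moderate-magnitude fields used here.
    """
    h, w = dense.shape[:2]
    rr, cc = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
    inv = np.zeros_like(dense)
    for _ in range(n_iter):
        pr = rr + inv[:, :, 0]
        pc = cc + inv[:, :, 1]
        dr = ndimage.map_coordinates(dense[:, :, 0], [pr, pc], order=1, mode="nearest")
        dc = ndimage.map_coordinates(dense[:, :, 1], [pr, pc], order=1, mode="nearest")
        inv = -np.stack([dr, dc], axis=-1)
    return inv
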