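"""Ellipsoid model of the insula in MNI millimetre space.

The insula is approximated by an axis-aligned ellipsoid

    (x - x0)^2 / a^2 + (y - y0)^2 / b^2 + (z - z0)^2 / c^2 = 1

with the centre ``(x0, y0, z0)`` in MNI coordinates (x mediolateral,
positive right; y anteroposterior, positive anterior; z superoinferior,
positive superior) and semi-axes ``(a, b, c)`` in millimetres.  The
reference right-insula model is centred at (40, 5, 5) mm with semi-axes
(12, 8, 6) mm; the left insula is its mediolateral mirror image at
(-40, 5, 5) mm.

All lengths are millimetres and all angles radians throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "MNIPoint",
    "EllipsoidModel",
    "SurfaceMesh",
    "MaskVolume",
    "make_ellipsoid",
    "default_right_insula",
    "default_left_insula",
]

#: Reference right-insula centre in MNI mm.
RIGHT_INSULA_CENTER = (40.0, 5.0, 5.0)
#: Reference semi-axes (mediolateral, anteroposterior, superoinferior) in mm.
INSULA_SEMI_AXES = (12.0, 8.0, 6.0)


class MNIPoint(NamedTuple):
    """A point in MNI millimetre coordinates."""

    x: float
    y: float
    z: float


def _as_point_array(p) -> np.ndarray:
    """Coerce a point or array of points to a float array with last dim 3."""
    arr = np.asarray(p, dtype=float)
    if arr.shape == () or arr.shape[-1] != 3:
        raise ValueError(f"expected coordinates with last dimension 3, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("coordinates must be finite")
    return arr


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated ellipsoid surface on an (nu, nv) angular grid.

    ``vertices`` is an (N, 3) array of MNI points, ``faces`` an (M, 3)
    integer array of vertex indices, ``grid_shape`` the (nu, nv) angular
    grid the vertices were sampled on.
    """

    vertices: np.ndarray
    faces: np.ndarray
    grid_shape: tuple[int, int]

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be an (M, 3) array")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass(frozen=True)
class MaskVolume:
    """Binary occupancy grid with a voxel-to-world (MNI mm) affine.

    ``data`` holds {0, 1} voxel values; ``affine`` is the 4x4 map sending
    voxel indices (i, j, k, 1) to world millimetre coordinates, RAS+
    oriented with world space interpreted as MNI.
    """

    data: np.ndarray
    affine: np.ndarray
    voxel_size: float

    def __post_init__(self):
        d = np.asarray(self.data)
        a = np.asarray(self.affine, dtype=float)
        if d.ndim != 3:
            raise ValueError("mask data must be 3-D")
        if not np.isin(d, (0, 1)).all():
            raise ValueError("mask data must be binary {0,1}")
        if a.shape != (4, 4) or not np.isfinite(np.linalg.cond(a[:3, :3])):
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "data", d.astype(np.uint8))
        object.__setattr__(self, "affine", a)

    @property
    def n_inside(self) -> int:
        return int(self.data.sum())

    def volume(self) -> float:
        """Occupied volume in mm^3 (voxel count times voxel volume)."""
        return self.n_inside * float(np.abs(np.linalg.det(self.affine[:3, :3])))

    def world_coordinates(self) -> np.ndarray:
        """World (MNI mm) coordinates of every voxel centre, shape data.shape + (3,)."""
        idx = np.stack(np.meshgrid(*map(np.arange, self.data.shape), indexing="ij"), axis=-1)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass(frozen=True)
class EllipsoidModel:
    """Axis-aligned ellipsoid in MNI mm space.

    Parameters
    ----------
    center : (x0, y0, z0) centre in MNI mm.
    semi_axes : (a, b, c) strictly positive semi-axis lengths in mm along
        the mediolateral, anteroposterior and superoinferior axes.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self):
        c = tuple(float(v) for v in self.center)
        s = tuple(float(v) for v in self.semi_axes)
        if len(c) != 3 or len(s) != 3:
            raise ValueError("center and semi_axes must each have 3 components")
        if not all(math.isfinite(v) for v in c):
            raise ValueError("center components must be finite")
        if not all(math.isfinite(v) and v > 0 for v in s):
            raise ValueError("semi-axes must be finite and strictly positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "semi_axes", s)

    # -- implicit form ---------------------------------------------------

    def implicit_value(self, p) -> float | np.ndarray:
        """Left-hand side of the ellipsoid equation at point(s) ``p``.

        0 at the centre, 1 on the surface, > 1 outside.
        """
        arr = _as_point_array(p)
        d = (arr - np.array(self.center)) / np.array(self.semi_axes)
        out = np.sum(d * d, axis=-1)
        return float(out) if out.ndim == 0 else out

    def contains(self, p) -> bool | np.ndarray:
        """Boundary-inclusive membership: implicit_value(p) <= 1."""
        out = np.asarray(self.implicit_value(p)) <= 1.0
        return bool(out) if out.ndim == 0 else out

    # -- parametric form -------------------------------------------------

    def surface_point(self, u, v) -> np.ndarray:
        """Parametric surface point for angles u in [0, 2pi], v in [0, pi].

        x = x0 + a cos(u) sin(v), y = y0 + b sin(u) sin(v), z = z0 + c cos(v).
        Angles outside the nominal ranges wrap by periodicity.
        """
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        x0, y0, z0 = self.center
        a, b, c = self.semi_axes
        pts = np.stack(
            [
                x0 + a * np.cos(u) * np.sin(v),
                y0 + b * np.sin(u) * np.sin(v),
                z0 + c * np.cos(v),
            ],
            axis=-1,
        )
        return pts

    def surface_mesh(self, nu: int = 60, nv: int = 30) -> SurfaceMesh:
        """Triangulated surface sampled on an nu x nv angular grid.

        u is sampled on [0, 2pi) (periodic, endpoint excluded), v on
        [0, pi] inclusive, so the grid carries nu*nv vertices with the
        poles duplicated along u.  Quads are split into two triangles;
        quads degenerate at the poles collapse to a single triangle.
        """
        if nu < 3 or nv < 3:
            raise ValueError("surface mesh requires nu >= 3 and nv >= 3")
        u = np.linspace(0.0, 2.0 * np.pi, nu, endpoint=False)
        v = np.linspace(0.0, np.pi, nv)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        vertices = self.surface_point(uu, vv).reshape(-1, 3)

        def vid(i: int, j: int) -> int:
            return (i % nu) * nv + j

        faces = []
        for i in range(nu):
            for j in range(nv - 1):
                q00, q01 = vid(i, j), vid(i, j + 1)
                q10, q11 = vid(i + 1, j), vid(i + 1, j + 1)
                if j == 0:  # top pole: row j is a single point
                    faces.append((q00, q01, q11))
                elif j == nv - 2:  # bottom pole
                    faces.append((q00, q10, q01))
                else:
                    faces.append((q00, q10, q11))
                    faces.append((q00, q11, q01))
        return SurfaceMesh(vertices=vertices, faces=np.array(faces, dtype=int), grid_shape=(nu, nv))

    # -- scalar summaries ------------------------------------------------

    def volume(self) -> float:
        """Analytic volume (4/3) pi a b c in mm^3."""
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    def extents(self) -> tuple[float, float, float]:
        """Full axis lengths (2a, 2b, 2c) in mm."""
        a, b, c = self.semi_axes
        return (2 * a, 2 * b, 2 * c)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box as (lower, upper) corner arrays."""
        c = np.array(self.center)
        s = np.array(self.semi_axes)
        return c - s, c + s

    def surface_area(self, p: float = 1.6075) -> float:
        """Approximate surface area (Thomsen's formula, exponent p).

        No elementary closed form exists for a general ellipsoid; the
        approximation is accurate to ~1% for all aspect ratios.
        """
        a, b, c = self.semi_axes
        ap, bp, cp = a**p, b**p, c**p
        return 4.0 * math.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p)

    # -- transforms ------------------------------------------------------

    def mirror_lr(self) -> "EllipsoidModel":
        """Mirror across the sagittal midline (negate the x centre)."""
        x0, y0, z0 = self.center
        return EllipsoidModel(center=(-x0, y0, z0), semi_axes=self.semi_axes)

    # -- voxelization ----------------------------------------------------

    def voxelize(self, voxel_size: float = 1.0) -> MaskVolume:
        """Binary mask on an isotropic grid covering the padded bounding box.

        A voxel is set iff its centre point lies inside the ellipsoid
        (boundary inclusive).  The grid spans the bounding box padded by
        one voxel on every side; the affine maps voxel indices to the MNI
        mm coordinates of voxel centres (RAS+).
        """
        if not (math.isfinite(voxel_size) and voxel_size > 0):
            raise ValueError("voxel_size must be finite and > 0")
        lo, hi = self.bounding_box()
        lo = lo - voxel_size
        hi = hi + voxel_size
        shape = np.maximum(np.ceil((hi - lo) / voxel_size), 1).astype(int)
        affine = np.eye(4)
        affine[:3, :3] *= voxel_size
        affine[:3, 3] = lo + voxel_size / 2.0  # index (0,0,0) -> first voxel centre
        axes = [lo[k] + (np.arange(shape[k]) + 0.5) * voxel_size for k in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        data = (self.implicit_value(grid) <= 1.0).astype(np.uint8)
        return MaskVolume(data=data, affine=affine, voxel_size=float(voxel_size))


def make_ellipsoid(center, semi_axes) -> EllipsoidModel:
    """Build a validated :class:`EllipsoidModel` from centre and semi-axes."""
    return EllipsoidModel(center=tuple(center), semi_axes=tuple(semi_axes))


def default_right_insula() -> EllipsoidModel:
    """Reference right-insula ellipsoid: centre (40, 5, 5), semi-axes (12, 8, 6)."""
    return EllipsoidModel(center=RIGHT_INSULA_CENTER, semi_axes=INSULA_SEMI_AXES)


def default_left_insula() -> EllipsoidModel:
    """Reference left-insula ellipsoid, the mediolateral mirror of the right."""
    return default_right_insula().mirror_lr()
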