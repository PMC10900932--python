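"""Stylized solids, cortical shells, rod-like trabecular lattices, voxelization.

Each stylized shape is an :class:`AnalyticSolid` exposing a point-membership
predicate together with closed-form (or high-accuracy numeric) volume and
surface area.  A cortical shell partitions a solid into a cortex region and
the interior spongiosa; the spongiosa is itself a same-kind solid with its
linear dimensions reduced by the (per-surface) cortical thicknesses, so shell
volumes are exact for boxes and standard stylized-phantom approximations for
curved shapes.  The trabecular microstructure is an orthogonal lattice of
cylindrical rods along the three axes with jittered spacing and lognormal
per-rod thickness, calibrated by a final uniform thickness scaling to land in
the requested BV/TV range.  Voxelization samples the membership predicates at
voxel centers.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .segment_model import (
    MicroSpec,
    SegmentSpec,
    ShapeKind,
    ShapeSpec,
    SURFACE_COUNTS,
)

# voxel labels
OUTSIDE, CORTICAL_BONE, TRABECULAR_BONE, MARROW = 0, 1, 2, 3
LABEL_NAMES = {OUTSIDE: "outside", CORTICAL_BONE: "cortical_bone",
               TRABECULAR_BONE: "trabecular_bone", MARROW: "marrow"}


@dataclass(frozen=True)
class Media:
    """A simulated medium: density (g/cm^3) and element mass fractions."""

    name: str
    density: float
    element_mass_fractions: dict[str, float]
    fraction_tol: float = 0.001

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        total = sum(self.element_mass_fractions.values())
        if abs(total - 1.0) > self.fraction_tol + 1e-9:
            raise ValueError(
                f"element mass fractions of {self.name} sum to {total:.4f}, "
                f"outside 1 +/- {self.fraction_tol}")


# ---------------------------------------------------------------------------
# analytic solids
# ---------------------------------------------------------------------------

def _ellipse_perimeter(sa: float, sb: float) -> float:
    # Ramanujan's second approximation
    h = ((sa - sb) / (sa + sb)) ** 2 if sa + sb > 0 else 0.0
    return math.pi * (sa + sb) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


class AnalyticSolid:
    """Base class: membership predicate plus analytic volume/surface."""

    kind: ShapeKind

    def contains(self, pts: np.ndarray) -> np.ndarray:  # (N,3) -> (N,) bool
        raise NotImplementedError

    @property
    def volume(self) -> float:
        raise NotImplementedError

    @property
    def surface_areas(self) -> tuple[float, ...]:
        """Per-surface areas, ordered by the shape's surface convention."""
        raise NotImplementedError

    @property
    def surface_area(self) -> float:
        return float(sum(self.surface_areas))

    @property
    def bbox_edges(self) -> tuple[float, float, float]:
        """Edges of the circumscribed axis-aligned box."""
        raise NotImplementedError

    @property
    def bbox_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        e = np.asarray(self.bbox_edges)
        return -e / 2.0, e / 2.0

    def shrunk(self, thicknesses: Sequence[float]) -> "AnalyticSolid":
        """Same-kind solid with each covered surface moved inward."""
        raise NotImplementedError

    def extended(self, pad: float) -> "AnalyticSolid":
        """Same-kind solid with every linear dimension grown by ``pad``."""
        raise NotImplementedError

    @property
    def surface_count(self) -> int:
        return SURFACE_COUNTS[self.kind]


@dataclass(frozen=True)
class Box(AnalyticSolid):
    edges: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: ShapeKind = ShapeKind.BOX

    def contains(self, pts: np.ndarray) -> np.ndarray:
        e = np.asarray(self.edges) / 2.0
        c = np.asarray(self.center)
        return np.all(np.abs(pts - c) <= e, axis=1)

    @property
    def volume(self) -> float:
        a, b, c = self.edges
        return a * b * c

    @property
    def surface_areas(self) -> tuple[float, ...]:
        a, b, c = self.edges
        return (b * c, b * c, a * c, a * c, a * b, a * b)

    @property
    def bbox_edges(self):
        return self.edges

    @property
    def bbox_bounds(self):
        e = np.asarray(self.edges)
        c = np.asarray(self.center)
        return c - e / 2.0, c + e / 2.0

    def shrunk(self, th):
        # surfaces ordered (-x, +x, -y, +y, -z, +z)
        t = np.asarray(th, dtype=float)
        a, b, c = self.edges
        new = (a - t[0] - t[1], b - t[2] - t[3], c - t[4] - t[5])
        if any(e <= 0 for e in new):
            raise ValueError("cortical shell leaves no spongiosa in the box")
        cx, cy, cz = self.center
        center = (cx + (t[0] - t[1]) / 2.0,
                  cy + (t[2] - t[3]) / 2.0,
                  cz + (t[4] - t[5]) / 2.0)
        return Box(new, center)

    def extended(self, pad):
        a, b, c = self.edges
        return Box((a + pad, b + pad, c + pad), self.center)


@dataclass(frozen=True)
class EllipticCylinder(AnalyticSolid):
    """Elliptic cylinder, full base axes a x b, height H along z."""

    a: float
    b: float
    h: float
    z0: float = 0.0
    kind: ShapeKind = ShapeKind.ELLIPTIC_CYLINDER

    def contains(self, pts):
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2] - self.z0
        return ((2 * x / self.a) ** 2 + (2 * y / self.b) ** 2 <= 1.0) & \
               (np.abs(z) <= self.h / 2.0)

    @property
    def volume(self):
        return math.pi / 4.0 * self.a * self.b * self.h

    @property
    def surface_areas(self):
        lateral = _ellipse_perimeter(self.a / 2, self.b / 2) * self.h
        base = math.pi / 4.0 * self.a * self.b
        return (lateral, base, base)  # lateral, bottom, top

    @property
    def bbox_edges(self):
        return (self.a, self.b, self.h)

    @property
    def bbox_bounds(self):
        e = np.asarray(self.bbox_edges)
        lo, hi = -e / 2.0, e / 2.0
        lo[2] += self.z0
        hi[2] += self.z0
        return lo, hi

    def shrunk(self, th):
        t_lat, t_bot, t_top = th
        a, b = self.a - 2 * t_lat, self.b - 2 * t_lat
        h = self.h - t_bot - t_top
        if a <= 0 or b <= 0 or h <= 0:
            raise ValueError("cortical shell leaves no spongiosa in the cylinder")
        return EllipticCylinder(a, b, h, self.z0 + (t_bot - t_top) / 2.0)

    def extended(self, pad):
        return EllipticCylinder(self.a + pad, self.b + pad, self.h + pad, self.z0)


@dataclass(frozen=True)
class DeformedCylinder(AnalyticSolid):
    """Ruled solid between two parallel ellipses with perpendicular major axes.

    The bottom base (z = -H/2) has full axes a (major, along x) and b (minor,
    along y); the top base has full axes c (major, along y) and d (minor,
    along x).  Cross sections interpolate linearly, giving a ruled lateral
    surface; a truncated cone is the particular case a = b, c = d.
    """

    a: float
    b: float
    c: float
    d: float
    h: float
    z0: float = 0.0
    kind: ShapeKind = ShapeKind.DEFORMED_CYLINDER

    def _semi_axes(self, z):
        u = np.clip((np.asarray(z) - self.z0 + self.h / 2.0) / self.h, 0.0, 1.0)
        sx = (1 - u) * self.a / 2 + u * self.d / 2
        sy = (1 - u) * self.b / 2 + u * self.c / 2
        return sx, sy

    def contains(self, pts):
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        sx, sy = self._semi_axes(z)
        return ((x / sx) ** 2 + (y / sy) ** 2 <= 1.0) & \
               (np.abs(z - self.z0) <= self.h / 2.0)

    @property
    def volume(self):
        # integral of pi*sx(u)*sy(u) over the height; the integrand is
        # quadratic in u so Simpson's rule is exact
        def area(u):
            sx = (1 - u) * self.a / 2 + u * self.d / 2
            sy = (1 - u) * self.b / 2 + u * self.c / 2
            return math.pi * sx * sy
        return self.h * (area(0.0) + 4 * area(0.5) + area(1.0)) / 6.0

    @property
    def surface_areas(self):
        # lateral area by slicing: perimeter times slant-corrected height step
        n = 256
        u = np.linspace(0.0, 1.0, n + 1)
        sx = (1 - u) * self.a / 2 + u * self.d / 2
        sy = (1 - u) * self.b / 2 + u * self.c / 2
        per = np.array([_ellipse_perimeter(px, py) for px, py in zip(sx, sy)])
        dz = self.h / n
        # mean radius drift per step as a slant proxy
        r = (sx + sy) / 2.0
        slant = np.sqrt(dz * dz + np.diff(r) ** 2)
        lateral = float(np.sum((per[:-1] + per[1:]) / 2.0 * slant / dz * dz))
        bottom = math.pi / 4.0 * self.a * self.b
        top = math.pi / 4.0 * self.c * self.d
        return (lateral, bottom, top)

    @property
    def bbox_edges(self):
        return (max(self.a, self.d), max(self.b, self.c), self.h)

    @property
    def bbox_bounds(self):
        e = np.asarray(self.bbox_edges)
        lo, hi = -e / 2.0, e / 2.0
        lo[2] += self.z0
        hi[2] += self.z0
        return lo, hi

    def shrunk(self, th):
        t_lat, t_bot, t_top = th
        dims = (self.a - 2 * t_lat, self.b - 2 * t_lat,
                self.c - 2 * t_lat, self.d - 2 * t_lat,
                self.h - t_bot - t_top)
        if any(v <= 0 for v in dims):
            raise ValueError("cortical shell leaves no spongiosa")
        return DeformedCylinder(*dims, self.z0 + (t_bot - t_top) / 2.0)

    def extended(self, pad):
        return DeformedCylinder(self.a + pad, self.b + pad, self.c + pad,
                                self.d + pad, self.h + pad, self.z0)


@dataclass(frozen=True)
class Ellipsoid(AnalyticSolid):
    """Ellipsoid with full axes l, m, n."""

    l: float
    m: float
    n: float
    kind: ShapeKind = ShapeKind.ELLIPSOID

    def contains(self, pts):
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        return ((2 * x / self.l) ** 2 + (2 * y / self.m) ** 2
                + (2 * z / self.n) ** 2) <= 1.0

    @property
    def volume(self):
        return math.pi / 6.0 * self.l * self.m * self.n

    @property
    def surface_areas(self):
        # Thomsen's approximation, exact for spheres
        p = 1.6075
        sa, sb, sc = self.l / 2, self.m / 2, self.n / 2
        s = ((sa ** p * sb ** p + sa ** p * sc ** p + sb ** p * sc ** p) / 3.0) ** (1 / p)
        return (4 * math.pi * s,)

    @property
    def bbox_edges(self):
        return (self.l, self.m, self.n)

    def shrunk(self, th):
        t = th[0]
        dims = (self.l - 2 * t, self.m - 2 * t, self.n - 2 * t)
        if any(v <= 0 for v in dims):
            raise ValueError("cortical shell leaves no spongiosa")
        return Ellipsoid(*dims)

    def extended(self, pad):
        return Ellipsoid(self.l + pad, self.m + pad, self.n + pad)


@dataclass(frozen=True)
class TriangularPyramid(AnalyticSolid):
    """Tetrahedron over a right-triangle base with legs a, b and height H.

    The apex sits above the base centroid.  Vertices (before centering) are
    (0,0,0), (a,0,0), (0,b,0) and (a/3, b/3, H).
    """

    a: float
    b: float
    hh: float
    kind: ShapeKind = ShapeKind.TRIANGULAR_PYRAMID

    @property
    def _vertices(self) -> np.ndarray:
        a, b, h = self.a, self.b, self.hh
        v = np.array([[0, 0, 0], [a, 0, 0], [0, b, 0], [a / 3, b / 3, h]],
                     dtype=float)
        return v - self._center

    @property
    def _center(self) -> np.ndarray:
        a, b, h = self.a, self.b, self.hh
        v = np.array([[0, 0, 0], [a, 0, 0], [0, b, 0], [a / 3, b / 3, h]],
                     dtype=float)
        return v.mean(axis=0)

    def _faces(self):
        v = self._vertices
        # face i is opposite vertex i
        idx = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
        faces = []
        for i, (p, q, r) in enumerate(idx):
            normal = np.cross(v[q] - v[p], v[r] - v[p])
            area = np.linalg.norm(normal) / 2.0
            n_hat = normal / (2.0 * area)
            # orient inward (toward the opposite vertex)
            if np.dot(v[i] - v[p], n_hat) < 0:
                n_hat = -n_hat
            faces.append((v[p], n_hat, area))
        return faces

    def contains(self, pts):
        ok = np.ones(len(pts), dtype=bool)
        for p, n_hat, _ in self._faces():
            ok &= (pts - p) @ n_hat >= -1e-12
        return ok

    @property
    def volume(self):
        return self.a * self.b * self.hh / 6.0

    @property
    def surface_areas(self):
        # ordered: base first (the face in the z=min plane), then the rest
        faces = self._faces()
        areas = [a for (_, _, a) in faces]
        return (areas[3], areas[0], areas[1], areas[2])

    @property
    def bbox_edges(self):
        return (self.a, self.b, self.hh)

    @property
    def bbox_bounds(self):
        v = self._vertices
        return v.min(axis=0), v.max(axis=0)

    @property
    def _inradius(self) -> float:
        return 3.0 * self.volume / self.surface_area

    def shrunk(self, th):
        t = set(float(x) for x in th)
        if len(t) != 1:
            raise ValueError("pyramid shells must have uniform thickness")
        t = t.pop()
        scale = 1.0 - t / self._inradius
        if scale <= 0:
            raise ValueError("cortical shell leaves no spongiosa")
        return _ScaledPyramid(self, scale)

    def extended(self, pad):
        return TriangularPyramid(self.a + pad, self.b + pad, self.hh + pad)


@dataclass(frozen=True)
class _ScaledPyramid(AnalyticSolid):
    """A pyramid uniformly inset about its incenter (shell construction)."""

    parent: TriangularPyramid
    scale: float
    kind: ShapeKind = ShapeKind.TRIANGULAR_PYRAMID

    @property
    def _incenter(self) -> np.ndarray:
        v = self.parent._vertices
        faces = self.parent._faces()
        areas = np.array([faces[i][2] for i in range(4)])
        return (areas[:, None] * v).sum(axis=0) / areas.sum()

    def contains(self, pts):
        c = self._incenter
        return self.parent.contains(c + (pts - c) / self.scale)

    @property
    def volume(self):
        return self.parent.volume * self.scale ** 3

    @property
    def surface_areas(self):
        return tuple(a * self.scale ** 2 for a in self.parent.surface_areas)

    @property
    def bbox_edges(self):
        return tuple(e * self.scale for e in self.parent.bbox_edges)

    @property
    def bbox_bounds(self):
        lo, hi = self.parent.bbox_bounds
        c = self._incenter
        return c + (lo - c) * self.scale, c + (hi - c) * self.scale

    def extended(self, pad):
        raise NotImplementedError


@dataclass(frozen=True)
class Tube(AnalyticSolid):
    """Region between two nested circular cylinders (inner/outer radius, H)."""

    r_in: float
    r_out: float
    h: float
    z0: float = 0.0
    kind: ShapeKind = ShapeKind.TUBE

    def contains(self, pts):
        r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        return (r2 >= self.r_in ** 2) & (r2 <= self.r_out ** 2) & \
               (np.abs(pts[:, 2] - self.z0) <= self.h / 2.0)

    @property
    def volume(self):
        return math.pi * (self.r_out ** 2 - self.r_in ** 2) * self.h

    @property
    def surface_areas(self):
        outer = 2 * math.pi * self.r_out * self.h
        inner = 2 * math.pi * self.r_in * self.h
        base = math.pi * (self.r_out ** 2 - self.r_in ** 2)
        return (outer, inner, base, base)  # outer lat, inner lat, bottom, top

    @property
    def bbox_edges(self):
        return (2 * self.r_out, 2 * self.r_out, self.h)

    @property
    def bbox_bounds(self):
        e = np.asarray(self.bbox_edges)
        lo, hi = -e / 2.0, e / 2.0
        lo[2] += self.z0
        hi[2] += self.z0
        return lo, hi

    def shrunk(self, th):
        t_out, t_in, t_bot, t_top = th
        r_out = self.r_out - t_out
        r_in = self.r_in + t_in
        h = self.h - t_bot - t_top
        if r_out <= r_in or h <= 0:
            raise ValueError("cortical shell leaves no spongiosa in the tube")
        return Tube(r_in, r_out, h, self.z0 + (t_bot - t_top) / 2.0)

    def extended(self, pad):
        # the bore is kept; the wall grows outward and along the axis
        return Tube(self.r_in, self.r_out + pad / 2.0, self.h + pad, self.z0)


def build_solid(shape: ShapeSpec) -> AnalyticSolid:
    """Construct the analytic solid for a stylized shape specification."""
    d = shape.dims
    if shape.kind is ShapeKind.BOX:
        return Box(d)
    if shape.kind is ShapeKind.ELLIPTIC_CYLINDER:
        return EllipticCylinder(*d)
    if shape.kind is ShapeKind.DEFORMED_CYLINDER:
        return DeformedCylinder(*d)
    if shape.kind is ShapeKind.ELLIPSOID:
        return Ellipsoid(*d)
    if shape.kind is ShapeKind.TRIANGULAR_PYRAMID:
        return TriangularPyramid(*d)
    if shape.kind is ShapeKind.TUBE:
        return Tube(*d)
    raise ValueError(f"unknown shape kind {shape.kind}")


# ---------------------------------------------------------------------------
# cortical shell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionedSolid:
    """A stylized solid split into a cortical shell and interior spongiosa."""

    outer: AnalyticSolid
    spongiosa: AnalyticSolid
    thicknesses: tuple[float, ...]

    @property
    def cortex_volume(self) -> float:
        return self.outer.volume - self.spongiosa.volume

    def cortex_contains(self, pts: np.ndarray) -> np.ndarray:
        return self.outer.contains(pts) & ~self.spongiosa.contains(pts)

    def spongiosa_contains(self, pts: np.ndarray) -> np.ndarray:
        return self.spongiosa.contains(pts)


def add_cortical_shell(
    solid: AnalyticSolid,
    ct_th: float | Sequence[float],
    coverage: Sequence[bool] | None = None,
    target_mean: float | None = None,
) -> PartitionedSolid:
    """Partition a solid into cortex and spongiosa.

    ``ct_th`` is a single mean thickness or a per-surface list (the latter is
    used for the cortical-nonuniformity experiments on boxes).  When a
    per-surface list is given with ``target_mean``, the list is rescaled so
    that its mean over covered surfaces equals ``target_mean``.  Uncovered
    surfaces (``coverage`` mask False) carry no cortex.
    """
    ns = solid.surface_count
    if coverage is None:
        coverage = [True] * ns
    coverage = [bool(c) for c in coverage]
    if len(coverage) != ns:
        raise ValueError(f"coverage mask length {len(coverage)} != {ns} surfaces")

    th = np.asarray(ct_th, dtype=float)
    if th.ndim == 0:
        th = np.full(ns, float(th))
    if th.size != ns:
        raise ValueError(f"expected {ns} per-surface thicknesses, got {th.size}")
    if np.any(th < 0):
        raise ValueError("cortical thickness must be >= 0")
    if target_mean is not None:
        covered = np.asarray(coverage)
        m = th[covered].mean()
        if m > 0:
            th = th.copy()
            th[covered] *= target_mean / m
    th = np.where(coverage, th, 0.0)
    if np.all(th == 0):
        return PartitionedSolid(solid, solid, tuple(th))
    spong = solid.shrunk(th)
    return PartitionedSolid(solid, spong, tuple(th))


# ---------------------------------------------------------------------------
# trabecular lattice
# ---------------------------------------------------------------------------

class TrabecularLattice:
    """Orthogonal rod lattice: cylindrical trabeculae along the three axes.

    Rod axis positions follow a regular grid of period ``Tb.Sp + Tb.Th`` with
    Gaussian jitter of scale ``tb_sp_sd``; per-rod thickness is lognormal with
    mean ``Tb.Th`` and SD ``tb_th_sd``.  A uniform thickness scale factor
    (``scale``) calibrates the realized BV/TV.
    """

    def __init__(self, spongiosa: AnalyticSolid, micro: MicroSpec, seed: int):
        self.spongiosa = spongiosa
        self.micro = micro
        self.seed = seed
        self.scale = 1.0
        rng = np.random.default_rng(seed)
        lo, hi = spongiosa.bbox_bounds
        period = micro.tb_sp + micro.tb_th
        if period <= 0:
            raise ValueError("Tb.Sp + Tb.Th must be > 0")

        def axis_positions(axis):
            n = max(int(math.ceil((hi[axis] - lo[axis]) / period)) + 1, 1)
            base = lo[axis] + (np.arange(n) + 0.5) * period
            jitter = rng.normal(0.0, micro.tb_sp_sd, size=n)
            np.clip(jitter, -0.45 * period, 0.45 * period, out=jitter)
            return np.sort(base + jitter)

        self._pos = [axis_positions(a) for a in range(3)]  # x, y, z line grids

        def thickness(n1, n2):
            if micro.tb_th <= 0:
                return np.zeros((n1, n2))
            if micro.tb_th_sd <= 0:
                return np.full((n1, n2), micro.tb_th)
            cv = micro.tb_th_sd / micro.tb_th
            s2 = math.log(cv * cv + 1.0)
            mu = math.log(micro.tb_th) - 0.5 * s2
            return rng.lognormal(mu, math.sqrt(s2), size=(n1, n2))

        nx, ny, nz = (len(p) for p in self._pos)
        # rods run along the axis named; they are indexed by the other two
        self._th_z = thickness(nx, ny)   # rods along z at (x_i, y_j)
        self._th_x = thickness(ny, nz)   # rods along x at (y_j, z_k)
        self._th_y = thickness(nx, nz)   # rods along y at (x_i, z_k)

    def _nearest(self, axis: int, coord: np.ndarray) -> np.ndarray:
        pos = self._pos[axis]
        idx = np.searchsorted(pos, coord)
        idx = np.clip(idx, 1, len(pos) - 1)
        left = pos[idx - 1]
        right = pos[idx]
        idx = np.where(np.abs(coord - left) <= np.abs(coord - right), idx - 1, idx)
        return idx

    def bone_contains(self, pts: np.ndarray) -> np.ndarray:
        """True where a point falls inside any trabecular rod."""
        if self.micro.tb_th <= 0 or self.scale <= 0:
            return np.zeros(len(pts), dtype=bool)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        ix, iy, iz = (self._nearest(a, c) for a, c in ((0, x), (1, y), (2, z)))
        px, py, pz = self._pos[0][ix], self._pos[1][iy], self._pos[2][iz]
        s = self.scale
        in_z = (x - px) ** 2 + (y - py) ** 2 <= (s * self._th_z[ix, iy] / 2) ** 2
        in_x = (y - py) ** 2 + (z - pz) ** 2 <= (s * self._th_x[iy, iz] / 2) ** 2
        in_y = (x - px) ** 2 + (z - pz) ** 2 <= (s * self._th_y[ix, iz] / 2) ** 2
        return in_z | in_x | in_y

    def realized_bvtv(self, n_points: int = 120_000, seed: int | None = None) -> float:
        """Monte Carlo estimate of the bone volume fraction inside spongiosa."""
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        lo, hi = self.spongiosa.bbox_bounds
        pts = rng.uniform(lo, hi, size=(n_points, 3))
        inside = self.spongiosa.contains(pts)
        pts = pts[inside]
        if len(pts) == 0:
            raise RuntimeError("no sample points fell inside the spongiosa")
        return float(np.mean(self.bone_contains(pts)))


def generate_trabecular_lattice(
    spongiosa: AnalyticSolid,
    micro: MicroSpec,
    seed: int,
    max_iter: int = 25,
    n_calib: int = 120_000,
) -> TrabecularLattice:
    """Generate a rod lattice whose realized BV/TV lands inside ``bvtv_range``.

    The per-rod thickness field is drawn once; a uniform thickness scaling is
    then adjusted iteratively (BV/TV scales roughly with the squared rod
    thickness) until the Monte Carlo estimate of the realized bone fraction
    falls inside the admissible range.
    """
    lat = TrabecularLattice(spongiosa, micro, seed)
    lo, hi = micro.bvtv_range
    if micro.bvtv <= 0 or hi <= 0:
        lat.scale = 0.0
        return lat
    target = micro.bvtv
    for it in range(max_iter):
        got = lat.realized_bvtv(n_points=n_calib)
        if lo <= got <= hi:
            return lat
        if got <= 0:
            lat.scale *= 2.0
            continue
        lat.scale *= math.sqrt(target / got)
        if lat.scale > 50:
            break
    raise RuntimeError(
        f"trabecular lattice could not reach BV/TV range [{lo}, {hi}] "
        f"with Tb.Th={micro.tb_th}, Tb.Sp={micro.tb_sp}")


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

@dataclass
class VoxelPhantom:
    """Labeled 3-D voxel grid of a bone-segment phantom."""

    resolution: float
    grid: np.ndarray  # uint8, labels OUTSIDE..MARROW
    origin: tuple[float, float, float]
    seed: int | None = None
    source: str | None = None

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")

    @property
    def voxel_volume(self) -> float:
        return self.resolution ** 3

    def counts(self) -> dict[int, int]:
        labels, n = np.unique(self.grid, return_counts=True)
        out = {int(k): 0 for k in LABEL_NAMES}
        out.update({int(k): int(v) for k, v in zip(labels, n)})
        return out

    def volumes(self) -> dict[str, float]:
        return {LABEL_NAMES[k]: v * self.voxel_volume
                for k, v in self.counts().items()}


class VoxelBudgetError(RuntimeError):
    pass


def voxelize(
    partition: PartitionedSolid,
    resolution: float,
    lattice: TrabecularLattice | None = None,
    seed: int | None = None,
    max_voxels: int = 60_000_000,
) -> VoxelPhantom:
    """Voxelize a partitioned solid by center-point membership sampling.

    Labels: outside, cortical bone, trabecular bone (where a lattice is
    supplied), marrow.  Emits a warning when the resolution exceeds 0.75 x
    Tb.Th, the coarsest grid that leaves dose factors unbiased.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if lattice is not None and lattice.micro.tb_th > 0 \
            and resolution > 0.75 * lattice.micro.tb_th + 1e-12:
        warnings.warn(
            f"voxel resolution {resolution:g} cm exceeds 0.75 x Tb.Th "
            f"({0.75 * lattice.micro.tb_th:g} cm); dose factors may be biased",
            stacklevel=2)
    lo, hi = partition.outer.bbox_bounds
    n = np.maximum(np.ceil((hi - lo) / resolution - 1e-9).astype(int), 1)
    if int(np.prod(n)) > max_voxels:
        raise VoxelBudgetError(
            f"grid of {int(np.prod(n)):,} voxels exceeds the budget of "
            f"{max_voxels:,}; coarsen the resolution or raise max_voxels")
    xs = lo[0] + (np.arange(n[0]) + 0.5) * resolution
    ys = lo[1] + (np.arange(n[1]) + 0.5) * resolution
    zs = lo[2] + (np.arange(n[2]) + 0.5) * resolution

    grid = np.zeros(tuple(n), dtype=np.uint8)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    flat_xy = np.column_stack([xx.ravel(), yy.ravel()])
    for k, z in enumerate(zs):  # slice-by-slice keeps memory flat
        pts = np.column_stack([flat_xy, np.full(len(flat_xy), z)])
        inside = partition.outer.contains(pts)
        spong = partition.spongiosa_contains(pts)
        labels = np.zeros(len(pts), dtype=np.uint8)
        labels[inside & ~spong] = CORTICAL_BONE
        labels[spong] = MARROW
        if lattice is not None and np.any(spong):
            bone = np.zeros(len(pts), dtype=bool)
            bone[spong] = lattice.bone_contains(pts[spong])
            labels[bone] = TRABECULAR_BONE
        grid[:, :, k] = labels.reshape(n[0], n[1])
    return VoxelPhantom(resolution=resolution, grid=grid, origin=tuple(lo),
                        seed=seed if seed is not None
                        else (lattice.seed if lattice else None))


# ---------------------------------------------------------------------------
# derived geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DerivedGeometry:
    """Volumes, surfaces and masses derived from a phantom or partition.

    ``v_s`` spongiosa volume (cm^3); ``ss`` spongiosa surface area (cm^2);
    ``v_tbv``/``v_bmv``/``v_cbv`` trabecular bone, marrow and cortical bone
    volumes; masses in g; ``circumscribed_box`` edges in cm.
    """

    v_s: float
    ss: float
    v_tbv: float
    v_bmv: float
    v_cbv: float
    m_tbv: float
    m_bmv: float
    m_cbv: float
    circumscribed_box: tuple[float, float, float]

    def __post_init__(self):
        if min(self.v_s, self.ss, self.v_tbv, self.v_bmv, self.v_cbv) < -1e-9:
            raise ValueError("geometry quantities must be nonnegative")


def _voxel_spongiosa_surface(grid: np.ndarray, resolution: float) -> float:
    spong = (grid == TRABECULAR_BONE) | (grid == MARROW)
    faces = 0
    for axis in range(3):
        d = np.diff(spong.astype(np.int8), axis=axis)
        faces += int(np.count_nonzero(d))
        # boundary of the array counts as an interface where spongiosa touches it
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = 0
        sl_hi[axis] = -1
        faces += int(np.count_nonzero(spong[tuple(sl_lo)]))
        faces += int(np.count_nonzero(spong[tuple(sl_hi)]))
    return faces * resolution ** 2


def derive_geometry(
    obj: PartitionedSolid | VoxelPhantom,
    media_bone: Media,
    media_marrow: Media,
    bvtv: float | None = None,
) -> DerivedGeometry:
    """Compute spongiosa volume/surface, compartment volumes and masses.

    For a :class:`PartitionedSolid` the analytic spongiosa boundary is used
    and ``bvtv`` apportions the spongiosa into trabecular bone and marrow.
    For a :class:`VoxelPhantom` all quantities come from voxel counting.
    """
    if isinstance(obj, PartitionedSolid):
        if bvtv is None:
            raise ValueError("bvtv is required to split an analytic spongiosa")
        v_s = obj.spongiosa.volume
        ss = obj.spongiosa.surface_area
        v_tbv = bvtv * v_s
        v_bmv = v_s - v_tbv
        v_cbv = obj.cortex_volume
        box = obj.outer.bbox_edges
    elif isinstance(obj, VoxelPhantom):
        vol = obj.voxel_volume
        c = obj.counts()
        v_tbv = c[TRABECULAR_BONE] * vol
        v_bmv = c[MARROW] * vol
        v_s = v_tbv + v_bmv
        v_cbv = c[CORTICAL_BONE] * vol
        ss = _voxel_spongiosa_surface(obj.grid, obj.resolution)
        box = tuple(float(s * obj.resolution) for s in obj.grid.shape)
    else:
        raise TypeError(f"cannot derive geometry from {type(obj)}")
    return DerivedGeometry(
        v_s=v_s, ss=ss, v_tbv=v_tbv, v_bmv=v_bmv, v_cbv=v_cbv,
        m_tbv=v_tbv * media_bone.density,
        m_bmv=v_bmv * media_marrow.density,
        m_cbv=v_cbv * media_bone.density,
        circumscribed_box=tuple(float(e) for e in box),
    )


def export_voxels(phantom: VoxelPhantom, path_raw, path_sidecar,
                  media: dict | None = None) -> None:
    """Write the raw little-endian uint8 grid plus a JSON sidecar."""
    arr = np.ascontiguousarray(phantom.grid, dtype=np.uint8)
    with open(path_raw, "wb") as fh:
        fh.write(arr.tobytes(order="C"))
    sidecar = {
        "dims": list(arr.shape),
        "resolution_cm": phantom.resolution,
        "origin_cm": list(phantom.origin),
        "labels": {str(k): v for k, v in LABEL_NAMES.items()},
        "seed": phantom.seed,
        "order": "C",
        "dtype": "uint8",
    }
    if media:
        sidecar["media"] = media
    with open(path_sidecar, "w") as fh:
        json.dump(sidecar, fh, indent=2)
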