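"""Parametric MRI gradient-coil models and their quasi-static fields.

A whole-body gradient set consists of three axis coils wound on a common
cylindrical former.  Real winding patterns are proprietary, so this module uses
the textbook minimal windings that produce the same linear field behaviour near
isocenter:

* **Z axis** — a Maxwell pair: two counter-wound circular loops at ``z = ±L/4``
  on the former, giving a field ``B_z ∝ z`` near the origin.
* **X / Y axes** — four Golay-style saddle loops (120° arcs at two axial
  positions joined by axial return paths), giving ``B_z ∝ x`` (or ``y``).  The
  Y coil is the X coil rotated by 90° about the bore axis.

Fields are evaluated with the Biot–Savart law.  Arcs are integrated with a
midpoint rule in the arc angle (spectrally accurate for full loops), straight
segments with Gauss–Legendre quadrature; the closed form for a finite straight
wire is also provided.  Each axis coil is *calibrated*: the current that
produces a gradient of exactly 1 T/m of ``B_z`` along the coil's axis at
isocenter is stored as ``current_per_unit_gradient``, which makes a slew rate
in T/m/s directly meaningful as a current ramp.

Coordinate convention (shared by every module): bore axis = +z toward the
patient's head, isocenter at the origin, patient supine, +x toward the
patient's left, +y toward the patient's anterior.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

MU0 = 4.0e-7 * np.pi
#: minimum admissible distance from an evaluation point to the winding (m)
SINGULARITY_DISTANCE = 1.0e-6

DEFAULT_POINTS_PER_TURN = 720
MIN_POINTS_PER_TURN = 16

#: default former dimensions of the five-set catalog (m); config values, not
#: measurements of any specific scanner
DEFAULT_DIAMETERS = (0.60, 0.63, 0.66, 0.68, 0.70)
DEFAULT_LENGTHS = (1.20, 1.30, 1.40, 1.45, 1.50)


class CoilError(ValueError):
    """Invalid coil geometry or configuration."""


class SingularityError(CoilError):
    """Field requested on (or numerically on) the wire."""


class CalibrationError(CoilError):
    """Winding produces no gradient at isocenter."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise CoilError(f"expected a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class StraightSegment:
    """Straight wire from ``start`` to ``end`` carrying ``polarity*turns*I``."""

    start: tuple
    end: tuple
    polarity: int = 1
    turns: int = 1

    def __post_init__(self):
        s, e = _as_point(self.start), _as_point(self.end)
        if np.allclose(s, e):
            raise CoilError("straight segment endpoints must be distinct")
        if self.polarity not in (+1, -1):
            raise CoilError("polarity must be +1 or -1")
        if self.turns < 1:
            raise CoilError("turns must be a positive integer")
        object.__setattr__(self, "start", tuple(s))
        object.__setattr__(self, "end", tuple(e))


@dataclass(frozen=True)
class ArcSegment:
    """Circular arc in the plane through ``center`` normal to ``normal``.

    The arc is traversed from ``phi0`` to ``phi1`` (``phi1 > phi0``, span in
    (0, 2π]); a reversed sense of circulation is expressed with
    ``polarity = -1``.  Angles are measured in the plane basis (u, v) obtained
    by orthonormalising the global x axis against ``normal``.
    """

    center: tuple
    radius: float
    normal: tuple = (0.0, 0.0, 1.0)
    phi0: float = 0.0
    phi1: float = 2.0 * np.pi
    polarity: int = 1
    turns: int = 1

    def __post_init__(self):
        if self.radius <= 0:
            raise CoilError("arc radius must be positive")
        span = self.phi1 - self.phi0
        if not (0.0 < span <= 2.0 * np.pi + 1e-12):
            raise CoilError("arc span must lie in (0, 2*pi]")
        if self.polarity not in (+1, -1):
            raise CoilError("polarity must be +1 or -1")
        if self.turns < 1:
            raise CoilError("turns must be a positive integer")
        n = _as_point(self.normal)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise CoilError("arc normal must be nonzero")
        object.__setattr__(self, "center", tuple(_as_point(self.center)))
        object.__setattr__(self, "normal", tuple(n / nn))

    @property
    def span(self) -> float:
        return self.phi1 - self.phi0

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane orthonormal basis (u, v) with u ⟂ normal."""
        n = np.asarray(self.normal)
        seed = np.array([1.0, 0.0, 0.0])
        if abs(n @ seed) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        u = seed - (seed @ n) * n
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def point(self, phi) -> np.ndarray:
        u, v = self.basis()
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        c = np.asarray(self.center)
        return c + self.radius * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)


WireSegment = StraightSegment | ArcSegment

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _segment_quadrature(seg: WireSegment, points_per_turn: int):
    """Source points and weighted dl vectors (including polarity*turns)."""
    if points_per_turn < MIN_POINTS_PER_TURN:
        raise CoilError(
            f"quadrature resolution must be >= {MIN_POINTS_PER_TURN} points per turn"
        )
    scale = seg.polarity * seg.turns
    if isinstance(seg, StraightSegment):
        s, e = np.asarray(seg.start), np.asarray(seg.end)
        t = 0.5 * (_GL_NODES + 1.0)
        src = s + t[:, None] * (e - s)
        dl = (0.5 * _GL_WEIGHTS)[:, None] * (e - s) * scale
        return src, dl
    # arc: midpoint rule in phi
    n = max(MIN_POINTS_PER_TURN, int(np.ceil(points_per_turn * seg.span / (2 * np.pi))))
    h = seg.span / n
    phi = seg.phi0 + (np.arange(n) + 0.5) * h
    u, v = seg.basis()
    src = seg.point(phi)
    tangent = -np.sin(phi)[:, None] * u + np.cos(phi)[:, None] * v
    dl = seg.radius * h * tangent * scale
    return src, dl


def _pair_distances_sq(p, src):
    """|p_i − s_m|² via the expanded product (runs as a BLAS matmul)."""
    d2 = p @ (-2.0 * src.T)
    d2 += np.einsum("ij,ij->i", p, p)[:, None]
    d2 += np.einsum("mj,mj->m", src, src)[None, :]
    np.maximum(d2, 0.0, out=d2)
    return d2


def _singularity_thresholds_sq(dl):
    """Per-node squared exclusion radius: a point closer to a quadrature node
    than half that node's weight length is (numerically) on the wire."""
    half_dl = 0.5 * np.linalg.norm(dl, axis=1)
    return np.maximum(SINGULARITY_DISTANCE, half_dl)[None, :] ** 2


def _biot_savart(src, dl, points, current, singular_check=True):
    """μ0 I/4π Σ dl × r / |r|³ at ``points``.

    Uses dl × (p − s) = −p × dl + dl × s so the quadrature sum reduces to two
    matrix products against the 1/r³ weight matrix.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty_like(points)
    cross_ds = np.cross(dl, src)
    thr2 = _singularity_thresholds_sq(dl) if singular_check else None
    chunk = max(1, int(2e7 / max(len(src), 1)))
    for i in range(0, len(points), chunk):
        p = points[i : i + chunk]
        d2 = _pair_distances_sq(p, src)
        if thr2 is not None and d2.size and (d2 < thr2).any():
            raise SingularityError("evaluation point lies on the winding")
        w = d2 ** -0.5
        w *= w * w
        out[i : i + chunk] = -np.cross(p, w @ dl) - w @ cross_ds
    return out * (MU0 * current / (4 * np.pi))


def _vector_potential(src, dl, points, current, singular_check=True):
    """μ0 I/4π Σ dl / |r| at ``points`` (weight matrix times dl)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty_like(points)
    thr2 = _singularity_thresholds_sq(dl) if singular_check else None
    chunk = max(1, int(2e7 / max(len(src), 1)))
    for i in range(0, len(points), chunk):
        p = points[i : i + chunk]
        d2 = _pair_distances_sq(p, src)
        if thr2 is not None and d2.size and (d2 < thr2).any():
            raise SingularityError("evaluation point lies on the winding")
        out[i : i + chunk] = (d2 ** -0.5) @ dl
    return out * (MU0 * current / (4 * np.pi))


def segment_b_field(point, segment: WireSegment, current: float) -> np.ndarray:
    """Magnetic field (T) of a single wire segment at one point.

    Straight segments use the closed-form finite-wire expression; arcs are
    integrated numerically.
    """
    p = _as_point(point)
    if isinstance(segment, StraightSegment):
        s, e = np.asarray(segment.start), np.asarray(segment.end)
        u = e - s
        ulen = np.linalg.norm(u)
        uhat = u / ulen
        r1, r2 = p - s, p - e
        d_vec = r1 - (r1 @ uhat) * uhat
        d = np.linalg.norm(d_vec)
        if d < SINGULARITY_DISTANCE and (-ulen <= -(r1 @ uhat) <= 2 * ulen):
            raise SingularityError("evaluation point lies on the wire")
        if d < SINGULARITY_DISTANCE:
            return np.zeros(3)
        cos1 = (uhat @ r1) / np.linalg.norm(r1)
        cos2 = (uhat @ r2) / np.linalg.norm(r2)
        mag = MU0 * current * segment.polarity * segment.turns / (4 * np.pi * d)
        return mag * (cos1 - cos2) * np.cross(uhat, d_vec / d)
    src, dl = _segment_quadrature(segment, DEFAULT_POINTS_PER_TURN)
    return _biot_savart(src, dl, p, current)[0]


@lru_cache(maxsize=64)
def _coil_quadrature(segments: tuple, points_per_turn: int):
    srcs, dls = [], []
    for seg in segments:
        s, d = _segment_quadrature(seg, points_per_turn)
        srcs.append(s)
        dls.append(d)
    return np.vstack(srcs), np.vstack(dls)


@dataclass(frozen=True)
class AxisCoil:
    """One axis coil: a set of wire segments plus its calibrated drive current.

    ``current_per_unit_gradient`` (A per T/m) is ``None`` until
    :func:`calibrate_gradient_efficiency` has been applied.
    """

    axis: str
    segments: tuple
    current_per_unit_gradient: float | None = None

    def __post_init__(self):
        if self.axis not in ("X", "Y", "Z"):
            raise CoilError("axis must be 'X', 'Y' or 'Z'")
        if not self.segments:
            raise CoilError("coil needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    def _quadrature(self, points_per_turn=DEFAULT_POINTS_PER_TURN):
        return _coil_quadrature(self.segments, points_per_turn)

    def b_field(self, points, current: float,
                points_per_turn: int = DEFAULT_POINTS_PER_TURN) -> np.ndarray:
        """B (T) at ``points`` for drive ``current`` (A); linear in current."""
        src, dl = self._quadrature(points_per_turn)
        return _biot_savart(src, dl, points, current)

    def vector_potential(self, points, current: float,
                         points_per_turn: int = DEFAULT_POINTS_PER_TURN) -> np.ndarray:
        """A (T·m) at ``points`` for drive ``current`` (A); linear in current."""
        src, dl = self._quadrature(points_per_turn)
        return _vector_potential(src, dl, points, current)

    @property
    def axis_direction(self) -> np.ndarray:
        return {"X": np.array([1.0, 0, 0]),
                "Y": np.array([0, 1.0, 0]),
                "Z": np.array([0, 0, 1.0])}[self.axis]


def central_gradient(coil: AxisCoil, current: float = 1.0, h: float = 1.0e-3) -> float:
    """dB_z/du at isocenter along the coil's axis (5-point central difference)."""
    u = coil.axis_direction
    pts = np.array([-2, -1, 1, 2])[:, None] * h * u
    bz = coil.b_field(pts, current)[:, 2]
    return (bz[0] - 8 * bz[1] + 8 * bz[2] - bz[3]) / (12 * h)


def calibrate_gradient_efficiency(coil: AxisCoil) -> AxisCoil:
    """Return the coil with current_per_unit_gradient set so that the central
    gradient of B_z along its axis is exactly 1 T/m.  Idempotent."""
    g = central_gradient(coil, current=1.0)
    if abs(g) < 1e-12:
        raise CalibrationError(
            f"{coil.axis} winding produces no central gradient (degenerate)"
        )
    return replace(coil, current_per_unit_gradient=1.0 / g)


# ---------------------------------------------------------------------------
# winding constructors

def maxwell_pair(diameter: float, length: float) -> AxisCoil:
    """Z-axis coil: counter-wound loop pair at z = ±length/4 on the former."""
    a, d = diameter / 2.0, length / 4.0
    segs = (
        ArcSegment(center=(0, 0, +d), radius=a, polarity=+1),
        ArcSegment(center=(0, 0, -d), radius=a, polarity=-1),
    )
    return AxisCoil(axis="Z", segments=segs)


def _saddle_loop(a: float, z1: float, z2: float, phi_c: float, pol: int):
    """One closed saddle: arcs at z1 and z2 (signed) joined by axial wires."""
    p0, p1 = phi_c - np.pi / 3, phi_c + np.pi / 3

    def cyl(phi, z):
        return (a * np.cos(phi), a * np.sin(phi), z)

    return (
        ArcSegment(center=(0, 0, z1), radius=a, phi0=p0, phi1=p1, polarity=pol),
        StraightSegment(start=cyl(p1, z1), end=cyl(p1, z2), polarity=pol),
        ArcSegment(center=(0, 0, z2), radius=a, phi0=p0, phi1=p1, polarity=-pol),
        StraightSegment(start=cyl(p0, z2), end=cyl(p0, z1), polarity=pol),
    )


def golay_saddle_coil(diameter: float, length: float, axis: str = "X") -> AxisCoil:
    """Transverse coil: four 120° saddle loops on the former.

    Inner arcs at ±0.39·a (classic Golay proportion), outer arcs at ±0.45·L so
    the winding uses the former's length.  The Y coil is the X coil rotated
    90° about the bore axis.
    """
    a = diameter / 2.0
    z1, z2 = 0.39 * a, 0.45 * length
    if z2 <= z1:
        raise CoilError("former too short for the saddle winding")
    phi_c = {"X": 0.0, "Y": np.pi / 2}[axis]
    segs = []
    for zs in (+1, -1):
        for dphi, pol in ((0.0, +1), (np.pi, -1)):
            segs.extend(_saddle_loop(a, zs * z1, zs * z2, phi_c + dphi, pol))
    return AxisCoil(axis=axis, segments=tuple(segs))


@dataclass(frozen=True)
class GradientCoilSet:
    """Three calibrated axis coils on one cylindrical former."""

    set_id: str
    coil_diameter: float
    coil_length: float
    x_coil: AxisCoil
    y_coil: AxisCoil
    z_coil: AxisCoil

    def coil(self, axis: str) -> AxisCoil:
        return {"X": self.x_coil, "Y": self.y_coil, "Z": self.z_coil}[axis]


def build_coil_set(set_id: str, diameter: float, length: float) -> GradientCoilSet:
    if diameter <= 0 or length <= 0:
        raise CoilError("coil diameter and length must be positive")
    if diameter <= 0.5 or length <= 0.8:
        raise CoilError(
            "whole-body former expected: diameter > 0.5 m and length > 0.8 m"
        )
    x = calibrate_gradient_efficiency(golay_saddle_coil(diameter, length, "X"))
    y = calibrate_gradient_efficiency(golay_saddle_coil(diameter, length, "Y"))
    z = calibrate_gradient_efficiency(maxwell_pair(diameter, length))
    return GradientCoilSet(set_id, diameter, length, x, y, z)


def build_coil_catalog(pairs: Sequence[tuple[float, float]] | None = None
                       ) -> list[GradientCoilSet]:
    """Build the catalog of gradient coil sets (default: five whole-body sets).

    ``pairs`` is a list of (diameter, length) tuples in meters; pairs must be
    pairwise distinct.  Deterministic — no randomness is involved.
    """
    if pairs is None:
        pairs = list(zip(DEFAULT_DIAMETERS, DEFAULT_LENGTHS))
    if len(set(pairs)) != len(pairs):
        raise CoilError("duplicate (diameter, length) pair in coil catalog")
    return [
        build_coil_set(f"set{i+1:02d}", d, l) for i, (d, l) in enumerate(pairs)
    ]


def catalog_to_dicts(catalog: Iterable[GradientCoilSet]) -> list[dict]:
    """Serializable catalog description (windings rebuild deterministically)."""
    return [
        {"set_id": s.set_id, "coil_diameter": float(s.coil_diameter),
         "coil_length": float(s.coil_length),
         "calibrated_current_A_per_T_per_m": {
             "X": float(s.x_coil.current_per_unit_gradient),
             "Y": float(s.y_coil.current_per_unit_gradient),
             "Z": float(s.z_coil.current_per_unit_gradient)}}
        for s in catalog
    ]


def catalog_from_dicts(docs: Iterable[dict]) -> list[GradientCoilSet]:
    seen = []
    out = []
    for d in docs:
        key = (d["coil_diameter"], d["coil_length"])
        if key in seen:
            raise CoilError("duplicate (diameter, length) pair in coil catalog")
        seen.append(key)
        out.append(build_coil_set(d["set_id"], *key))
    return out
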