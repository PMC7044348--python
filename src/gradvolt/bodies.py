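"""Parametric homogeneous body models, voxelization and scan positioning.

Anatomical surface meshes are replaced by a stack of analytic solids (head
ellipsoid, neck / torso / pelvis elliptic cylinders, two leg cylinders) whose
axial proportions are fixed fractions of standing height and whose lateral
semi-axes share a single girth factor.  The girth factor is solved so that the
voxelized body volume matches ``mass / 1050 kg·m⁻³`` (soft-tissue density),
which is what the induced-field physics actually sees; the interior is a
homogeneous conductor.

Body frame: origin at the top of the head, +z toward the feet, +x toward the
patient's left, +y anterior.  Scanner frame: +z toward the head, isocenter at
origin.  A scan landmark ``LM`` (m below the top of the head) places the body
so that the point at depth LM sits on the isocenter plane, i.e.
``z_scanner = LM − z_body`` with x and y unchanged — changing the landmark
changes only a z offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

TISSUE_DENSITY = 1050.0  # kg/m^3
DEFAULT_CONDUCTIVITY = 0.35  # S/m, average soft tissue

#: scan landmark grid: isocenter positions below the top of the head (m)
DEFAULT_LANDMARKS = tuple(round(0.1 * k, 3) for k in range(12))


class BodyError(ValueError):
    """Invalid body-model parameters."""


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple
    semi_axes: tuple  # (ax, ay, az)

    def contains(self, pts, margin: float = 0.0):
        c = np.asarray(self.center)
        s = np.maximum(np.asarray(self.semi_axes) - margin, 1e-9)
        q = (np.atleast_2d(pts) - c) / s
        return np.einsum("ij,ij->i", q, q) <= 1.0

    @property
    def volume(self):
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semi_axes))


@dataclass(frozen=True)
class EllipticCylinder:
    """Axis along z; ``z_range`` = (z_top, z_bottom) in body frame."""

    center_xy: tuple
    semi_xy: tuple
    z_range: tuple

    def contains(self, pts, margin: float = 0.0):
        pts = np.atleast_2d(pts)
        c = np.asarray(self.center_xy)
        s = np.maximum(np.asarray(self.semi_xy) - margin, 1e-9)
        q = (pts[:, :2] - c) / s
        in_xy = np.einsum("ij,ij->i", q, q) <= 1.0
        z0, z1 = self.z_range
        return in_xy & (pts[:, 2] >= z0 + margin) & (pts[:, 2] <= z1 - margin)

    @property
    def volume(self):
        z0, z1 = self.z_range
        return np.pi * float(np.prod(self.semi_xy)) * (z1 - z0)


Primitive = Ellipsoid | EllipticCylinder


@dataclass(frozen=True)
class BodyModel:
    """Homogeneous parametric conductor with named primitive solids."""

    name: str
    height: float
    mass: float
    primitives: dict
    girth: float  # lateral scale factor actually applied
    conductivity: float = DEFAULT_CONDUCTIVITY

    def contains(self, pts, margin: float = 0.0):
        pts = np.atleast_2d(pts)
        inside = np.zeros(len(pts), dtype=bool)
        for p in self.primitives.values():
            inside |= p.contains(pts, margin=margin)
        return inside

    def bounding_box(self):
        los, his = [], []
        for p in self.primitives.values():
            if isinstance(p, Ellipsoid):
                c, s = np.asarray(p.center), np.asarray(p.semi_axes)
                los.append(c - s)
                his.append(c + s)
            else:
                c, s = np.asarray(p.center_xy), np.asarray(p.semi_xy)
                los.append(np.r_[c - s, p.z_range[0]])
                his.append(np.r_[c + s, p.z_range[1]])
        return np.min(los, axis=0), np.max(his, axis=0)


def _build_primitives(height: float, girth: float) -> dict:
    """Primitive stack for a given height and lateral girth factor.

    Axial fractions (of height): head 0–0.13, neck 0.11–0.175, torso
    0.155–0.485, pelvis 0.465–0.58, legs 0.57–1.0; adjacent solids overlap by
    ≥0.02·h so the union stays connected on coarse voxelizations and under
    the safety-margin erosion used by the trajectory generator.
    """
    h, s = height, girth
    leg_off = 0.085 * h * s
    return {
        "head": Ellipsoid(center=(0, 0, 0.065 * h),
                          semi_axes=(0.09 * h * s, 0.09 * h * s, 0.065 * h)),
        "neck": EllipticCylinder(center_xy=(0, 0),
                                 semi_xy=(0.045 * h * s, 0.045 * h * s),
                                 z_range=(0.11 * h, 0.175 * h)),
        "torso": EllipticCylinder(center_xy=(0, 0),
                                  semi_xy=(0.15 * h * s, 0.105 * h * s),
                                  z_range=(0.155 * h, 0.485 * h)),
        "pelvis": EllipticCylinder(center_xy=(0, 0),
                                   semi_xy=(0.16 * h * s, 0.115 * h * s),
                                   z_range=(0.465 * h, 0.58 * h)),
        "leg_left": EllipticCylinder(center_xy=(+leg_off, 0),
                                     semi_xy=(0.07 * h * s, 0.07 * h * s),
                                     z_range=(0.57 * h, 1.0 * h)),
        "leg_right": EllipticCylinder(center_xy=(-leg_off, 0),
                                      semi_xy=(0.07 * h * s, 0.07 * h * s),
                                      z_range=(0.57 * h, 1.0 * h)),
    }


def _union_volume(prims: dict, spacing: float = 0.01) -> float:
    pts, _ = _grid_points(prims, spacing)
    inside = np.zeros(len(pts), dtype=bool)
    for p in prims.values():
        inside |= p.contains(pts)
    return inside.sum() * spacing**3


def _grid_points(prims, spacing):
    los, his = [], []
    body = BodyModel("tmp", 1.0, 1.0, prims, 1.0)
    lo, hi = body.bounding_box()
    lo -= spacing
    hi += spacing
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    ax = [lo[i] + spacing * np.arange(shape[i]) for i in range(3)]
    g = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([a.ravel() for a in g], axis=1)
    return pts, (lo, shape)


def build_body_model(name: str, height: float, mass: float,
                     conductivity: float = DEFAULT_CONDUCTIVITY) -> BodyModel:
    """Build a parametric body of the given standing height (m) and mass (kg).

    The lateral girth factor is iterated (fixed point on a 1 cm voxel volume
    estimate) until the body's volume matches ``mass / 1050`` kg·m⁻³.
    Deterministic: the same inputs always yield identical primitives.
    """
    if not (1.4 <= height <= 2.1):
        raise BodyError(f"height {height} m outside the supported 1.4–2.1 m range")
    if not (40.0 <= mass <= 200.0):
        raise BodyError(f"mass {mass} kg outside the supported 40–200 kg range")
    v_target = mass / TISSUE_DENSITY
    # analytic first guess from the primitive volume sum (ignores overlaps)
    base = _build_primitives(height, 1.0)
    v_base = sum(p.volume for p in base.values())
    girth = float(np.sqrt(v_target / v_base))
    for _ in range(3):
        v = _union_volume(_build_primitives(height, girth))
        girth *= float(np.sqrt(v_target / v))
    return BodyModel(name, height, mass, _build_primitives(height, girth),
                     girth, conductivity)


#: default six-body catalog: five adults with masses ~60–80 kg plus one heavy
#: adult ~40 kg above the next heaviest, to probe generalization to an
#: under-represented habitus
DEFAULT_BODY_PARAMS = (
    ("reference_male", 1.77, 72.0),
    ("reference_female", 1.63, 58.0),
    ("female_overweight", 1.63, 69.0),
    ("female_obese", 1.63, 80.0),
    ("senior_male", 1.73, 62.0),
    ("heavy_male", 1.68, 120.0),
)


def build_default_bodies() -> list[BodyModel]:
    return [build_body_model(n, h, m) for n, h, m in DEFAULT_BODY_PARAMS]


def heaviest_body(bodies) -> BodyModel:
    return max(bodies, key=lambda b: b.mass)


# ---------------------------------------------------------------------------
# voxelization

@dataclass(frozen=True)
class VoxelGrid:
    """Regular cell-centered grid with an inside mask, in the body frame.

    ``inside_mask`` marks voxels whose centers lie inside the body.
    ``fraction`` holds the subvoxel volume fraction occupied by the body
    (1 deep inside, 0 outside, intermediate in cut cells); the induced-field
    solver uses it as the conductivity indicator.  ``fraction`` may be ``None``
    for purely geometric uses, in which case the solver falls back to the
    binary mask.
    """

    spacing: float
    origin: tuple  # center of voxel (0,0,0)
    shape: tuple
    inside_mask: np.ndarray = field(repr=False, compare=False)
    fraction: np.ndarray | None = field(default=None, repr=False, compare=False)

    def axes(self):
        o = np.asarray(self.origin)
        return [o[i] + self.spacing * np.arange(self.shape[i]) for i in range(3)]

    def centers(self, mask_only: bool = True) -> np.ndarray:
        ax = self.axes()
        g = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([a.ravel() for a in g], axis=1)
        if mask_only:
            return pts[self.inside_mask.ravel()]
        return pts

    @property
    def n_inside(self) -> int:
        return int(self.inside_mask.sum())

    def boundary_faces(self):
        """Faces between an inside voxel and an outside voxel.

        Returns ``(cell_index_3d (M,3), normal (M,3))`` with outward unit
        normals in the body frame.
        """
        m = self.inside_mask
        cells, normals = [], []
        for axis in range(3):
            for side in (+1, -1):
                shifted = np.roll(m, -side, axis=axis)
                # np.roll wraps, but the mask has a ≥1-voxel outside margin
                bdry = m & ~shifted
                idx = np.argwhere(bdry)
                n = np.zeros((len(idx), 3))
                n[:, axis] = side
                cells.append(idx)
                normals.append(n)
        return np.vstack(cells), np.vstack(normals)


def _volume_fractions(body: BodyModel, pts: np.ndarray, spacing: float,
                      sub: int = 3) -> np.ndarray:
    """Subvoxel inside fraction per cell (``sub``³ samples in cut cells)."""
    half_diag = 0.5 * np.sqrt(3.0) * spacing
    frac = np.zeros(len(pts))
    sure_in = body.contains(pts, margin=half_diag)
    maybe = body.contains(pts, margin=-2.0 * half_diag)
    frac[sure_in] = 1.0
    mixed = maybe & ~sure_in
    if mixed.any():
        off = spacing * ((np.arange(sub) + 0.5) / sub - 0.5)
        mpts = pts[mixed]
        cnt = np.zeros(len(mpts))
        for dx in off:
            for dy in off:
                for dz in off:
                    cnt += body.contains(mpts + np.array([dx, dy, dz]))
        frac[mixed] = cnt / sub**3
    return frac


def voxelize_body(body: BodyModel, spacing: float) -> VoxelGrid:
    """Cell-centered voxelization of the primitive union with a ≥1-voxel
    outside margin on every face, including subvoxel volume fractions."""
    if not (0.005 <= spacing <= 0.05):
        raise BodyError("voxel spacing must lie in [0.005, 0.05] m")
    if not body.primitives:
        raise BodyError("body has no primitives")
    lo, hi = body.bounding_box()
    origin = lo - 2 * spacing  # ≥1-voxel margin; centers at origin + k*spacing
    shape = tuple(np.ceil((hi - origin) / spacing).astype(int) + 3)
    ax = [origin[i] + spacing * np.arange(shape[i]) for i in range(3)]
    g = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([a.ravel() for a in g], axis=1)
    mask = body.contains(pts).reshape(shape)
    if not mask.any():
        raise BodyError("voxelization produced an empty mask")
    frac = _volume_fractions(body, pts, spacing).reshape(shape)
    return VoxelGrid(spacing, tuple(origin), shape, mask, frac)


def connected_components(grid: VoxelGrid) -> int:
    _, n = ndimage.label(grid.inside_mask)
    return n


def voxel_volume(grid: VoxelGrid) -> float:
    return grid.n_inside * grid.spacing**3


# ---------------------------------------------------------------------------
# scan positioning

@dataclass(frozen=True)
class LandmarkTransform:
    """Body→scanner map for a scan landmark: ``z_s = lm − z_b``, x/y unchanged.

    The z axis reverses between frames (body +z toward the feet, scanner +z
    toward the head), so vector *components* map with a z sign flip.
    """

    landmark: float

    def to_scanner(self, pts_body) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pts_body, dtype=float)).copy()
        p[:, 2] = self.landmark - p[:, 2]
        return p

    def to_body(self, pts_scanner) -> np.ndarray:
        return self.to_scanner(pts_scanner)  # involution

    def direction_to_scanner(self, vec) -> np.ndarray:
        v = np.atleast_2d(np.asarray(vec, dtype=float)).copy()
        v[:, 2] = -v[:, 2]
        return v


def position_at_landmark(body: BodyModel, lm: float) -> LandmarkTransform:
    """Rigid placement of the body so that the point ``lm`` meters below the
    top of the head lies on the isocenter plane."""
    if not (0.0 <= lm <= body.height):
        raise BodyError(f"landmark {lm} outside [0, height={body.height}]")
    return LandmarkTransform(float(lm))


def landmark_grid(body: BodyModel, landmarks=DEFAULT_LANDMARKS) -> list[float]:
    """Landmark values for a body (clamped to its height)."""
    return [min(float(lm), body.height) for lm in landmarks]
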