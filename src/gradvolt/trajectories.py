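"""Synthetic DBS lead/extension routing trajectories inside parametric bodies.

A deep-brain-stimulation system runs from an intracranial electrode, through a
burr hole in the skull (where surplus lead is wound into strain-relief loops),
behind the ear and down one side of the neck, to the implanted neurostimulator
(INS) pocket — pectoral or abdominal — where surplus extension is coiled
behind the device.  This module emulates that routing as a smooth 3-D polyline
in the body frame:

1. anatomical waypoints (electrode → burr hole → mastoid → neck → pocket) are
   placed from the body's primitive dimensions and the implant configuration;
2. replicate variability is modelled as Gaussian jitter of the interior
   waypoints (default σ = 8 mm laterally), smoothed and projected back inside
   the body with a safety margin;
3. surplus length is wound into loops at the burr hole and at the pocket so
   the polyline arc length equals lead + extension length essentially exactly.

Trajectories sharing one (body, configuration) tuple are replicates: their
10-feature representation is identical even though their geometry (and hence
their induced voltage) differs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .bodies import BodyModel

#: admissible implant component lengths (m); configuration-extensible
LEAD_LENGTHS = (0.33, 0.40)
EXTENSION_LENGTHS = (0.40, 0.60, 0.95)

SIDES = ("left", "right")
INS_LOCATIONS = ("pectoral", "abdominal")

#: binary feature encodings (left/pectoral = 0)
SIDE_CODE = {"left": 0, "right": 1}
INS_CODE = {"pectoral": 0, "abdominal": 1}

RESAMPLE_STEP = 0.005  # m
DEFAULT_JITTER_SIGMA = 0.008  # m, control-point lateral jitter
INSIDE_MARGIN = 0.012  # m, clearance kept to the body surface
LOOP_RADIUS = 0.025  # m, strain-relief loop radius
MIN_SLACK = 0.05  # m, surplus below which a routing is infeasible
#: extra surplus demanded when screening configurations, covering the path
#: lengthening that waypoint jitter can introduce in individual replicates
FEASIBILITY_MARGIN = 0.04  # m

#: sign of the x coordinate for each side (+x is the patient's left)
SIDE_SIGN = {"left": +1.0, "right": -1.0}


class TrajectoryError(ValueError):
    """Infeasible configuration or failed geometry generation."""


@dataclass(frozen=True)
class ImplantConfig:
    """Implant-related features identifying a routing configuration."""

    brain_side: str
    neck_side: str
    ins_location: str
    lead_length: float
    extension_length: float

    def __post_init__(self):
        if self.brain_side not in SIDES or self.neck_side not in SIDES:
            raise TrajectoryError("sides must be 'left' or 'right'")
        if self.ins_location not in INS_LOCATIONS:
            raise TrajectoryError("ins_location must be 'pectoral' or 'abdominal'")
        if self.lead_length <= 0 or self.extension_length <= 0:
            raise TrajectoryError("component lengths must be positive")

    @property
    def total_length(self) -> float:
        return self.lead_length + self.extension_length

    def label(self) -> str:
        return (f"{self.brain_side[0]}{self.neck_side[0]}"
                f"{self.ins_location[0]}_{int(round(self.lead_length * 100))}"
                f"_{int(round(self.extension_length * 100))}")


@dataclass(frozen=True)
class Trajectory:
    """One lead+extension routing: an ordered polyline in the body frame.

    The first point is the electrode end, the last the device (INS) end.
    """

    body_name: str
    config: ImplantConfig
    replicate_id: int
    points: np.ndarray

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def config_grid(lead_lengths=LEAD_LENGTHS,
                extension_lengths=EXTENSION_LENGTHS) -> list[ImplantConfig]:
    """The full combinatorial grid of implant configurations (48 by default)."""
    out = []
    for bs in SIDES:
        for ns in SIDES:
            for ins in INS_LOCATIONS:
                for ll in lead_lengths:
                    for el in extension_lengths:
                        out.append(ImplantConfig(bs, ns, ins, ll, el))
    return out


def stable_seed(*parts) -> int:
    """Deterministic sub-2³¹ seed derived from arbitrary labelled parts."""
    text = "|".join(str(p) for p in parts)
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# geometry helpers

def _dims(body: BodyModel):
    head = body.primitives["head"]
    neck = body.primitives["neck"]
    torso = body.primitives["torso"]
    return {
        "h": body.height,
        "head_r": np.asarray(head.semi_axes),
        "neck_r": np.asarray(neck.semi_xy),
        "torso_r": np.asarray(torso.semi_xy),
    }


def _waypoints(body: BodyModel, cfg: ImplantConfig) -> np.ndarray:
    d = _dims(body)
    h = d["h"]
    sb, sn = SIDE_SIGN[cfg.brain_side], SIDE_SIGN[cfg.neck_side]
    hr, nr, tr = d["head_r"], d["neck_r"], d["torso_r"]
    pts = [
        (sb * 0.25 * hr[0], 0.0, 0.080 * h),            # electrode, deep brain
        (sb * 0.30 * hr[0], -0.25 * hr[1], 0.040 * h),  # burr hole region
        (sn * 0.50 * hr[0], -0.30 * hr[1], 0.105 * h),  # behind the ear
        (sn * 0.40 * nr[0], -0.15 * nr[1], 0.135 * h),  # upper neck
        (sn * 0.40 * nr[0], -0.10 * nr[1], 0.165 * h),  # lower neck
        (sn * 0.30 * tr[0], 0.10 * tr[1], 0.205 * h),   # over the clavicle
    ]
    if cfg.ins_location == "pectoral":
        pts.append((sn * 0.45 * tr[0], 0.30 * tr[1], 0.25 * h))
    else:
        pts.append((sn * 0.40 * tr[0], 0.25 * tr[1], 0.33 * h))
        pts.append((sn * 0.35 * tr[0], 0.30 * tr[1], 0.45 * h))
    return np.asarray(pts)


def _densify(pts: np.ndarray, step: float) -> np.ndarray:
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / step)))
        for k in range(1, n + 1):
            out.append(a + (b - a) * k / n)
    return np.asarray(out)


def _smooth(pts: np.ndarray, passes: int = 2) -> np.ndarray:
    p = pts.copy()
    for _ in range(passes):
        p[1:-1] = 0.25 * p[:-2] + 0.5 * p[1:-1] + 0.25 * p[2:]
    return p


def _resample(pts: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(2, int(np.ceil(total / step)) + 1)
    si = np.linspace(0.0, total, n)
    return np.stack([np.interp(si, s, pts[:, k]) for k in range(3)], axis=1)


def _axis_anchor(body: BodyModel, z: float) -> np.ndarray:
    """A point well inside the body at depth z (the trunk midline)."""
    zc = float(np.clip(z, 0.05 * body.height, 0.55 * body.height))
    return np.array([0.0, 0.0, zc])


def _project_inside(body: BodyModel, pts: np.ndarray,
                    margin: float = INSIDE_MARGIN,
                    max_attempts: int = 100) -> np.ndarray:
    """Pull any point outside the margin-eroded body toward the trunk midline
    until it is safely inside."""
    out = pts.copy()
    bad = ~body.contains(out, margin=margin)
    for i in np.nonzero(bad)[0]:
        p = out[i]
        anchor = _axis_anchor(body, p[2])
        lo, hi = 0.0, 1.0
        ok = False
        for _ in range(max_attempts):
            mid = 0.5 * (lo + hi)
            cand = p + mid * (anchor - p)
            if body.contains(cand[None], margin=margin)[0]:
                hi = mid
                ok = True
            else:
                lo = mid
        if not ok:
            raise TrajectoryError(
                f"could not project point {p} inside body {body.name}")
        out[i] = p + hi * (anchor - p)
    return out


def _loop_points(center: np.ndarray, radius: float, phi0: float,
                 arc_len: float, step: float, pitch: float = 0.0015):
    """Points along a horizontal coil of given arc length starting at phi0;
    a small z pitch per turn keeps windings from coinciding."""
    if arc_len <= 0:
        return np.empty((0, 3))
    n = max(2, int(np.ceil(arc_len / step)) + 1)
    s = np.linspace(0.0, arc_len, n)[1:]
    phi = phi0 + s / radius
    z = center[2] + pitch * (s / (2 * np.pi * radius))
    return np.stack([center[0] + radius * np.cos(phi),
                     center[1] + radius * np.sin(phi), z], axis=1)


def _backbone(body: BodyModel, cfg: ImplantConfig,
              rng: np.random.Generator | None,
              jitter_sigma: float) -> np.ndarray:
    d = _dims(body)
    h = d["h"]
    sb, sn = SIDE_SIGN[cfg.brain_side], SIDE_SIGN[cfg.neck_side]
    way = _waypoints(body, cfg)
    pts = _densify(way, 0.02)
    if rng is not None and jitter_sigma > 0:
        jit = np.zeros_like(pts)
        jit[1:-1, :2] = rng.normal(scale=jitter_sigma, size=(len(pts) - 2, 2))
        pts = pts + jit
    pts = _smooth(pts)
    # keep the cranial end on the electrode hemisphere and the neck run on the
    # tunneled side (contralateral routings cross between burr hole and ear)
    head_band = pts[:, 2] <= 0.05 * h
    pts[head_band, 0] = sb * np.maximum(sb * pts[head_band, 0], 0.004)
    neck_band = (pts[:, 2] >= 0.11 * h) & (pts[:, 2] <= 0.20 * h)
    pts[neck_band, 0] = sn * np.maximum(sn * pts[neck_band, 0], 0.004)
    pts = _project_inside(body, pts)
    return _resample(pts, RESAMPLE_STEP)


def _arc_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def routing_slack(body: BodyModel, cfg: ImplantConfig) -> float:
    """Surplus length of the (jitter-free) backbone for this configuration;
    negative values mean the implant cannot reach the pocket."""
    bb = _backbone(body, cfg, rng=None, jitter_sigma=0.0)
    return cfg.total_length - _arc_length(bb)


def is_feasible(body: BodyModel, cfg: ImplantConfig) -> bool:
    return routing_slack(body, cfg) >= MIN_SLACK + FEASIBILITY_MARGIN


def build_trajectory(body: BodyModel, cfg: ImplantConfig, replicate_seed: int,
                     jitter_sigma: float = DEFAULT_JITTER_SIGMA,
                     replicate_id: int = 0) -> Trajectory:
    """Build one routing polyline; deterministic given (body, cfg, seed).

    ``replicate_seed`` drives the waypoint jitter only; the anatomical
    skeleton and the surplus-loop layout follow from body and configuration.
    """
    rng = np.random.default_rng(replicate_seed)
    pts = _backbone(body, cfg, rng, jitter_sigma)
    slack = cfg.total_length - _arc_length(pts)
    if slack < MIN_SLACK:
        raise TrajectoryError(
            f"configuration {cfg.label()} infeasible in body {body.name}: "
            f"surplus {slack * 100:.1f} cm below the {MIN_SLACK * 100:.0f} cm "
            "strain-relief minimum")

    d = _dims(body)
    h = d["h"]
    circumference = 2 * np.pi * LOOP_RADIUS
    # burr-hole strain-relief loops absorb up to two turns of surplus lead
    n_burr = min(2, int(slack // (circumference + 0.02)))
    burr_idx = int(np.argmin(np.abs(pts[:, 2] - 0.045 * h)))
    if n_burr > 0:
        center = np.array([0.0, -0.20 * d["head_r"][1], pts[burr_idx, 2]])
        entry = pts[burr_idx]
        phi0 = np.arctan2(entry[1] - center[1], entry[0] - center[0])
        start = center + LOOP_RADIUS * np.array([np.cos(phi0), np.sin(phi0), 0.0])
        loops = _loop_points(center, LOOP_RADIUS, phi0,
                             n_burr * circumference, RESAMPLE_STEP)
        pts = np.vstack([pts[:burr_idx + 1], start[None], loops,
                         start[None], pts[burr_idx + 1:]])
    # wind the remaining surplus extension behind the INS pocket
    remaining = cfg.total_length - _arc_length(pts)
    if remaining > 0:
        pocket = pts[-1]
        center = pocket + np.array([0.0, -LOOP_RADIUS, 0.0])
        phi0 = np.arctan2(pocket[1] - center[1], pocket[0] - center[0])
        coil = _loop_points(center, LOOP_RADIUS, phi0, remaining, RESAMPLE_STEP)
        pts = np.vstack([pts, coil])
    traj = Trajectory(body.name, cfg, replicate_id, pts)
    err = abs(traj.arc_length() - cfg.total_length) / cfg.total_length
    if err > 0.01:
        raise TrajectoryError(
            f"arc length off by {err * 100:.2f}% for {cfg.label()}")
    return traj


# ---------------------------------------------------------------------------
# catalog specification

@dataclass(frozen=True)
class CatalogSpec:
    """Which configurations to implant in which body, with replicate counts.

    ``entries`` is a tuple of (body_name, ImplantConfig, n_replicates).
    """

    entries: tuple
    master_seed: int

    @property
    def n_trajectories(self) -> int:
        return sum(n for _, _, n in self.entries)

    @property
    def n_groups(self) -> int:
        return len({(b, c) for b, c, _ in self.entries})

    def bodies(self) -> list[str]:
        seen = []
        for b, _, _ in self.entries:
            if b not in seen:
                seen.append(b)
        return seen


def default_catalog_spec(bodies, master_seed: int = 0,
                         n_trajectories: int = 3007,
                         n_groups: int = 177) -> CatalogSpec:
    """Allocate configurations and replicates across the body catalog.

    Groups are drawn per body from the feasible part of the 48-configuration
    grid by seeded choice (30 per body for the first bodies, 29 for the rest,
    when the default 177 groups are spread over 6 bodies).  Replicates are
    spread as evenly as possible: with the defaults, 175 groups carry 17
    replicates and 2 carry 16, totalling 3007 trajectories.
    """
    bodies = list(bodies)
    if n_groups < len(bodies):
        raise TrajectoryError("need at least one configuration per body")
    base, extra = divmod(n_groups, len(bodies))
    per_body = [base + (1 if i < extra else 0) for i in range(len(bodies))]
    grid = config_grid()
    entries = []
    groups = []
    for body, want in zip(bodies, per_body):
        feasible = [c for c in grid if is_feasible(body, c)]
        if len(feasible) < want:
            raise TrajectoryError(
                f"body {body.name} admits only {len(feasible)} feasible "
                f"configurations, {want} requested")
        rng = np.random.default_rng(stable_seed(master_seed, "configs", body.name))
        idx = rng.choice(len(feasible), size=want, replace=False)
        groups.extend((body.name, feasible[i]) for i in sorted(idx))
    base_rep, extra_rep = divmod(n_trajectories, n_groups)
    if base_rep < 1:
        raise TrajectoryError("fewer trajectories than groups requested")
    for gi, (bname, cfg) in enumerate(groups):
        entries.append((bname, cfg, base_rep + (1 if gi < extra_rep else 0)))
    spec = CatalogSpec(tuple(entries), master_seed)
    assert spec.n_trajectories == n_trajectories and spec.n_groups == n_groups
    return spec


def reduced_catalog_spec(bodies, master_seed: int = 0,
                         n_trajectories: int = 600,
                         n_groups: int = 177) -> CatalogSpec:
    """Same group structure as the default catalog but with few replicates;
    used for desk-scale dataset production."""
    return default_catalog_spec(bodies, master_seed,
                                n_trajectories=n_trajectories,
                                n_groups=n_groups)


def build_catalog(bodies, spec: CatalogSpec,
                  jitter_sigma: float = DEFAULT_JITTER_SIGMA) -> list[Trajectory]:
    """Materialize every trajectory of ``spec``; deterministic given its
    master seed."""
    by_name = {b.name: b for b in bodies}
    out = []
    for bname, cfg, n_rep in spec.entries:
        if bname not in by_name:
            raise TrajectoryError(f"spec references unknown body {bname}")
        body = by_name[bname]
        for rep in range(n_rep):
            seed = stable_seed(spec.master_seed, bname, cfg.label(), rep)
            out.append(build_trajectory(body, cfg, seed,
                                        jitter_sigma=jitter_sigma,
                                        replicate_id=rep))
    return out


def write_polylines(trajectories, path) -> None:
    """Store trajectory polylines in HDF5, one dataset per trajectory."""
    import h5py
    with h5py.File(path, "w") as f:
        for t in trajectories:
            key = f"{t.body_name}/{t.config.label()}/rep{t.replicate_id:03d}"
            f.create_dataset(key, data=t.points, compression="gzip")


def read_polylines(path, bodies) -> list[Trajectory]:
    """Rebuild Trajectory objects from an HDF5 polyline file."""
    import h5py
    out = []
    with h5py.File(path, "r") as f:
        for bname in f:
            for label in f[bname]:
                bs, ns, ins = label[0], label[1], label[2]
                ll_cm, el_cm = label.split("_")[1:]
                cfg = ImplantConfig(
                    {"l": "left", "r": "right"}[bs],
                    {"l": "left", "r": "right"}[ns],
                    {"p": "pectoral", "a": "abdominal"}[ins],
                    int(ll_cm) / 100.0, int(el_cm) / 100.0)
                for rep in f[bname][label]:
                    out.append(Trajectory(bname, cfg, int(rep[3:]),
                                          f[bname][label][rep][()]))
    return out


def catalog_manifest(spec: CatalogSpec) -> "pandas.DataFrame":
    """One row per trajectory: body, configuration fields, replicate, seed."""
    import pandas as pd
    rows = []
    for bname, cfg, n_rep in spec.entries:
        for rep in range(n_rep):
            rows.append({
                "body": bname, "brain_side": cfg.brain_side,
                "neck_side": cfg.neck_side, "ins_location": cfg.ins_location,
                "lead_len_m": cfg.lead_length, "ext_len_m": cfg.extension_length,
                "replicate_id": rep,
                "seed": stable_seed(spec.master_seed, bname, cfg.label(), rep),
            })
    return pd.DataFrame(rows)
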