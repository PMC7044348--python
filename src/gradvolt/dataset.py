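"""Gradient-induced voltage computation and dataset assembly.

The voltage induced between the electrode and the neurostimulator enclosure is
the line integral of the tangential induced E-field along the implant path,

    V = ∫₀ᴸ E · dl,

evaluated per gradient axis at unit slew rate and combined conservatively in a
sum-of-magnitude fashion at the scanner's maximum slew rate (default
200 T/m/s), which models all three axes slewing simultaneously:

    V_total = slew × (|V_x| + |V_y| + |V_z|).

Each voltage observation is described by ten features — subject height and
mass, the three binary implant-placement choices, lead and extension length,
scan landmark, and gradient-coil diameter and length.  The *extended* table
holds one row per (trajectory × coil set × landmark); replicate trajectories
share a feature tuple, and averaging them produces the *condensed* table used
for surrogate training.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .bodies import BodyModel, position_at_landmark
from .coils import GradientCoilSet
from .efield import EFieldMap
from .trajectories import (INS_CODE, SIDE_CODE, CatalogSpec, ImplantConfig,
                           Trajectory)

DEFAULT_SLEW = 200.0  # T/m/s
MAX_SEGMENT = 0.005  # m, polyline resampling step before integration

#: feature column order of the CSV schema (Table-style 10-feature vector)
FEATURE_COLUMNS = [
    "height", "mass_100kg", "brain", "neck", "ins",
    "lead_len_m", "ext_len_m", "lm_m", "coil_diam_m", "coil_len_m",
]
META_COLUMNS = ["body", "config", "replicate_id", "set_id"]
CSV_FLOAT_FORMAT = "%.9g"


class DatasetError(ValueError):
    """Geometry or bookkeeping error while assembling the dataset."""


def combine_axes(vx: float, vy: float, vz: float,
                 slew: float = DEFAULT_SLEW) -> float:
    """Sum-of-magnitude combination of per-axis voltages at a slew rate."""
    if slew <= 0:
        raise DatasetError("slew rate must be positive")
    return slew * (abs(vx) + abs(vy) + abs(vz))


def resample_polyline(points: np.ndarray, step: float = MAX_SEGMENT) -> np.ndarray:
    """Resample a polyline to segments of at most ``step`` length."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(2, int(np.ceil(total / step)) + 1)
    si = np.linspace(0.0, total, n)
    return np.stack([np.interp(si, s, points[:, k]) for k in range(3)], axis=1)


def _check_near_mask(grid, points: np.ndarray):
    """Allow points at most ~1 voxel outside the inside mask (surface
    voxelization jitter); anything farther is a geometry error."""
    dist = ndimage.distance_transform_edt(~grid.inside_mask,
                                          sampling=grid.spacing)
    o = np.asarray(grid.origin)
    idx = np.clip(np.round((points - o) / grid.spacing).astype(int), 0,
                  np.asarray(grid.shape) - 1)
    d = dist[tuple(idx.T)]
    tol = np.sqrt(3.0) * grid.spacing
    if (d > tol).any():
        worst = points[np.argmax(d)]
        raise DatasetError(
            f"trajectory point {worst} lies {d.max() * 100:.1f} cm outside the "
            "field-map mask (beyond the 1-voxel clamp tolerance)")


def tangential_voltage(efield: EFieldMap, trajectory, transform=None) -> float:
    """Signed line integral of E·dl along the trajectory, electrode→device.

    ``efield`` is a per-unit-slew map on the trajectory's body grid; the
    result is in V per (T/m/s).  Midpoint rule with trilinear interpolation
    after resampling the polyline to ≤5 mm segments; field values outside the
    mask use the nearest inside voxel (≤1 voxel clamp).
    """
    pts_body = trajectory.points if isinstance(trajectory, Trajectory) else trajectory
    pts_body = resample_polyline(np.asarray(pts_body, dtype=float))
    _check_near_mask(efield.grid, pts_body)
    if transform is None:
        transform = efield.transform
    mids_body = 0.5 * (pts_body[:-1] + pts_body[1:])
    e_mid = efield.values_at(mids_body)  # scanner-frame components
    seg_body = np.diff(pts_body, axis=0)
    if transform is not None:
        seg = transform.direction_to_scanner(seg_body)
    else:
        seg = seg_body
    return float(np.einsum("ij,ij->", e_mid, seg))


def extract_features(body: BodyModel, cfg: ImplantConfig,
                     coil_set: GradientCoilSet, lm: float) -> dict:
    """The 10-feature representation of one voltage observation.

    Units follow the dataset schema: lengths in meters, mass in 100 kg units;
    binaries encode left/pectoral as 0 and right/abdominal as 1.
    """
    return {
        "height": float(body.height),
        "mass_100kg": float(body.mass) / 100.0,
        "brain": SIDE_CODE[cfg.brain_side],
        "neck": SIDE_CODE[cfg.neck_side],
        "ins": INS_CODE[cfg.ins_location],
        "lead_len_m": float(cfg.lead_length),
        "ext_len_m": float(cfg.extension_length),
        "lm_m": float(lm),
        "coil_diam_m": float(coil_set.coil_diameter),
        "coil_len_m": float(coil_set.coil_length),
    }


def enumerate_extended(trajectories, coil_sets, landmarks, field_cache,
                       bodies, slew: float = DEFAULT_SLEW) -> pd.DataFrame:
    """Assemble the extended voltage table.

    One row per (trajectory × coil set × landmark), ordered by (body, config,
    replicate, set, landmark).  ``field_cache`` must provide
    ``get(body_name, set_id, axis, landmark) -> EFieldMap`` for every tuple.
    """
    by_name = {b.name: b for b in bodies}
    trajs = sorted(trajectories,
                   key=lambda t: (t.body_name, t.config.label(), t.replicate_id))
    rows = []
    for cs in coil_sets:
        for lm in landmarks:
            per_body = {}
            for t in trajs:
                body = by_name[t.body_name]
                if t.body_name not in per_body:
                    try:
                        per_body[t.body_name] = {
                            ax: field_cache.get(t.body_name, cs.set_id, ax, lm)
                            for ax in "XYZ"}
                    except KeyError as exc:
                        raise DatasetError(
                            f"field cache missing entry for "
                            f"(body={t.body_name}, set={cs.set_id}, "
                            f"landmark={lm}): {exc}") from None
                maps = per_body[t.body_name]
                tr = position_at_landmark(body, min(lm, body.height))
                v = {ax: tangential_voltage(maps[ax], t, tr) for ax in "XYZ"}
                rec = extract_features(body, t.config, cs, lm)
                rec.update({
                    "body": t.body_name, "config": t.config.label(),
                    "replicate_id": t.replicate_id, "set_id": cs.set_id,
                    "v_x": v["X"], "v_y": v["Y"], "v_z": v["Z"],
                    "v_total_V": combine_axes(v["X"], v["Y"], v["Z"], slew),
                })
                rows.append(rec)
    df = pd.DataFrame(rows)
    df = df.sort_values(["body", "config", "replicate_id", "set_id", "lm_m"],
                        kind="stable").reset_index(drop=True)
    return df


def condense(extended: pd.DataFrame) -> pd.DataFrame:
    """Average replicate rows sharing an identical 10-feature tuple.

    Returns one row per distinct feature tuple with the group-mean voltage and
    the number of replicates averaged; input order of first occurrence is
    preserved.
    """
    if extended.empty:
        raise DatasetError("extended table is empty")
    agg = {"v_total_V": ("v_total_V", "mean"),
           "n_replicates": ("v_total_V", "size")}
    keep = [c for c in META_COLUMNS if c in extended.columns
            and c != "replicate_id"]
    for c in keep:
        agg[c] = (c, "first")
    out = (extended.groupby(FEATURE_COLUMNS, sort=False, as_index=False)
           .agg(**agg))
    return out[FEATURE_COLUMNS + ["v_total_V", "n_replicates"] + keep]


def dataset_structure(spec: CatalogSpec, n_coil_sets: int,
                      n_landmarks: int) -> dict:
    """Counting-only enumeration of the dataset a catalog spec generates.

    Row counts follow from the spec's group/replicate structure without
    building any geometry or solving any field, since the feature tuple of a
    row depends only on (body, configuration, coil set, landmark).
    """
    n_bodies = len(spec.bodies())
    return {
        "bodies": n_bodies,
        "coil_sets": n_coil_sets,
        "landmarks": n_landmarks,
        "trajectories": spec.n_trajectories,
        "groups": spec.n_groups,
        "volumetric_solves": n_bodies * n_coil_sets * 3 * n_landmarks,
        "extended_rows": spec.n_trajectories * n_coil_sets * n_landmarks,
        "condensed_rows": spec.n_groups * n_coil_sets * n_landmarks,
    }


# ---------------------------------------------------------------------------
# CSV round-trip (schema fixed for reproducibility)

def write_table(df: pd.DataFrame, path, extra_columns=()) -> None:
    cols = FEATURE_COLUMNS + ["v_total_V"] + list(extra_columns)
    cols += [c for c in META_COLUMNS if c in df.columns]
    if "n_replicates" in df.columns and "n_replicates" not in cols:
        cols.insert(cols.index("v_total_V") + 1, "n_replicates")
    df.to_csv(path, index=False, columns=[c for c in cols if c in df.columns],
              float_format=CSV_FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"table at {path} lacks feature columns {missing}")
    return df
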