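"""HDF5 cache of induced E-field maps.

One group per (body, coil set, axis, landmark) holding the grid metadata, the
inside mask and the filled E array (float32).  The file-level attribute
``config_hash`` ties the cache to the solver configuration that produced it;
a mismatching hash invalidates every entry.
"""

from __future__ import annotations

import numpy as np

from .bodies import VoxelGrid, position_at_landmark
from .efield import EFieldMap


def _key(body: str, set_id: str, axis: str, lm: float) -> str:
    return f"{body}/{set_id}/{axis}/lm{int(round(lm * 1000)):04d}"


class FieldCache:
    """Read/write access to cached per-unit-slew E-field maps."""

    def __init__(self, path, mode: str = "a", config_hash: str = ""):
        import os

        import h5py
        try:
            self.f = h5py.File(path, mode)
        except OSError:
            if mode == "r":
                raise
            # corrupt cache (e.g. an interrupted writer): start afresh
            os.unlink(path)
            self.f = h5py.File(path, mode)
        if mode != "r":
            stored = self.f.attrs.get("config_hash", "")
            if stored and config_hash and stored != config_hash:
                # stale cache: drop every entry
                for k in list(self.f.keys()):
                    del self.f[k]
            if stored != config_hash:  # avoid rewrites that dirty the file
                self.f.attrs["config_hash"] = config_hash
        self.config_hash = str(self.f.attrs.get("config_hash", ""))

    def close(self):
        self.f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def has(self, body: str, set_id: str, axis: str, lm: float) -> bool:
        return _key(body, set_id, axis, lm) in self.f

    def put(self, body: str, emap: EFieldMap, set_id: str) -> None:
        key = _key(body, set_id, emap.axis, emap.landmark)
        if key in self.f:
            del self.f[key]
        grp = self.f.create_group(key)
        g = emap.grid
        grp.attrs["spacing"] = g.spacing
        grp.attrs["origin"] = np.asarray(g.origin)
        grp.attrs["landmark"] = emap.landmark
        grp.attrs["axis"] = emap.axis
        grp.attrs["residual"] = emap.residual
        grp.create_dataset("mask", data=g.inside_mask, compression="gzip")
        grp.create_dataset("E", data=emap.E.astype(np.float32),
                           compression="gzip")

    def get(self, body: str, set_id: str, axis: str, lm: float,
            body_model=None) -> EFieldMap:
        key = _key(body, set_id, axis, lm)
        if key not in self.f:
            raise KeyError(key)
        grp = self.f[key]
        mask = grp["mask"][()]
        grid = VoxelGrid(float(grp.attrs["spacing"]),
                         tuple(grp.attrs["origin"]), mask.shape, mask)
        transform = None
        if body_model is not None:
            transform = position_at_landmark(body_model,
                                             float(grp.attrs["landmark"]))
        return EFieldMap(grid, str(grp.attrs["axis"]),
                         float(grp.attrs["landmark"]),
                         grp["E"][()].astype(float), transform,
                         residual=float(grp.attrs["residual"]))


class MemoryFieldCache:
    """Dict-backed cache with the same interface (used by tests and by the
    pipeline when no cache file is wanted)."""

    def __init__(self):
        self.maps: dict = {}

    def has(self, body, set_id, axis, lm) -> bool:
        return (body, set_id, axis, round(lm, 6)) in self.maps

    def put(self, body, emap: EFieldMap, set_id) -> None:
        self.maps[(body, set_id, emap.axis, round(emap.landmark, 6))] = emap

    def get(self, body, set_id, axis, lm, body_model=None) -> EFieldMap:
        return self.maps[(body, set_id, axis, round(lm, 6))]
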