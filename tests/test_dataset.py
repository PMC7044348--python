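"""Voltage line integrals, axis combination, features and table assembly."""

import numpy as np
import pandas as pd
import pytest

from gradvolt.bodies import position_at_landmark, voxelize_body
from gradvolt.dataset import (FEATURE_COLUMNS, DatasetError, combine_axes,
                              condense, dataset_structure, enumerate_extended,
                              extract_features, read_table,
                              tangential_voltage, write_table)
from gradvolt.efield import EFieldMap, sphere_efield_exact
from gradvolt.trajectories import ImplantConfig, default_catalog_spec
from tests.conftest import sphere_body

DBDT = (0.0, 0.0, 1.0)


def field_map_from_function(grid, fn):
    """Synthetic E-field map built from an analytic field function."""
    ax = grid.axes()
    g = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([a.ravel() for a in g], axis=1)
    E = fn(pts).reshape(grid.shape + (3,))
    return EFieldMap(grid, "Z", 0.0, E)


@pytest.fixture(scope="module")
def sphere_grid():
    return voxelize_body(sphere_body(0.15), 0.01)


class TestTangentialVoltage:
    def test_uniform_field_straight_path(self, sphere_grid):
        emap = field_map_from_function(
            sphere_grid, lambda p: np.tile([1.0, 0.0, 0.0], (len(p), 1)))
        v = tangential_voltage(emap, np.array([[0.0, 0, 0], [0.1, 0, 0]]))
        assert v == pytest.approx(0.1, abs=1e-12)

    def test_uniform_field_closed_path_is_zero(self, sphere_grid):
        emap = field_map_from_function(
            sphere_grid, lambda p: np.tile([1.0, 0.5, -0.2], (len(p), 1)))
        s = 0.05
        square = np.array([[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0],
                           [0, 0, 0]], dtype=float)
        assert abs(tangential_voltage(emap, square)) < 1e-12

    def test_semicircle_in_sphere_oracle_field(self, sphere_grid):
        emap = field_map_from_function(
            sphere_grid, lambda p: sphere_efield_exact(p, DBDT))
        th = np.linspace(0.0, np.pi, 100)
        arc = np.stack([0.1 * np.cos(th), 0.1 * np.sin(th),
                        np.zeros_like(th)], axis=1)
        v = tangential_voltage(emap, arc)
        assert v == pytest.approx(-0.5 * 0.1 * np.pi * 0.1, rel=1e-3)

    def test_reversal_flips_sign(self, sphere_grid):
        emap = field_map_from_function(
            sphere_grid, lambda p: sphere_efield_exact(p, DBDT))
        th = np.linspace(0.0, np.pi, 100)
        arc = np.stack([0.1 * np.cos(th), 0.1 * np.sin(th),
                        np.zeros_like(th)], axis=1)
        assert tangential_voltage(emap, arc[::-1]) == pytest.approx(
            -tangential_voltage(emap, arc), rel=1e-12)

    def test_point_far_outside_mask_rejected(self, sphere_grid):
        emap = field_map_from_function(
            sphere_grid, lambda p: np.zeros_like(p))
        path = np.array([[0.0, 0, 0], [0.30, 0, 0]])  # exits the sphere
        with pytest.raises(DatasetError):
            tangential_voltage(emap, path)


class TestCombineAxes:
    def test_sum_of_magnitude(self):
        assert combine_axes(2.5e-3, -1.0e-3, 0.5e-3, 200.0) == \
            pytest.approx(0.8)

    def test_zero(self):
        assert combine_axes(0.0, 0.0, 0.0) == 0.0

    def test_dominates_each_axis(self):
        rng = np.random.default_rng(0)
        for vx, vy, vz in rng.normal(size=(20, 3)) * 1e-3:
            tot = combine_axes(vx, vy, vz, 200.0)
            assert tot >= 200.0 * max(abs(vx), abs(vy), abs(vz))
            assert tot >= 0.0

    def test_bad_slew_rejected(self):
        with pytest.raises(DatasetError):
            combine_axes(1.0, 1.0, 1.0, slew=0.0)


class TestFeatures:
    def test_units_and_encoding(self, default_bodies, coil_set):
        body = [b for b in default_bodies if b.mass == 120.0][0]
        cfg = ImplantConfig("right", "left", "abdominal", 0.40, 0.60)
        f = extract_features(body, cfg, coil_set, 0.3)
        assert list(f) == FEATURE_COLUMNS
        assert f["mass_100kg"] == pytest.approx(1.20)
        assert f["height"] == body.height
        assert (f["brain"], f["neck"], f["ins"]) == (1, 0, 1)
        assert f["coil_diam_m"] == coil_set.coil_diameter

    def test_replicates_share_features(self, reference_body, coil_set):
        cfg = ImplantConfig("left", "left", "pectoral", 0.33, 0.95)
        f1 = extract_features(reference_body, cfg, coil_set, 0.5)
        f2 = extract_features(reference_body, cfg, coil_set, 0.5)
        assert f1 == f2

    def test_coil_set_changes_only_coil_features(self, reference_body):
        from gradvolt.coils import build_coil_set
        cfg = ImplantConfig("left", "left", "pectoral", 0.33, 0.95)
        a = extract_features(reference_body, cfg,
                             build_coil_set("a", 0.60, 1.20), 0.2)
        b = extract_features(reference_body, cfg,
                             build_coil_set("b", 0.70, 1.50), 0.2)
        diff = {k for k in a if a[k] != b[k]}
        assert diff == {"coil_diam_m", "coil_len_m"}


class TestCondense:
    def test_toy_group_means(self):
        rows = []
        for tag, v in zip("AABB", [1.0, 3.0, 2.0, 2.0]):
            f = dict.fromkeys(FEATURE_COLUMNS, 0.0)
            f["lm_m"] = 0.0 if tag == "A" else 0.1
            f["v_total_V"] = v
            rows.append(f)
        out = condense(pd.DataFrame(rows))
        assert len(out) == 2
        np.testing.assert_allclose(out["v_total_V"], [2.0, 2.0])
        np.testing.assert_array_equal(out["n_replicates"], [2, 2])

    def test_distinct_tuples_identity(self):
        rows = []
        for i in range(5):
            f = dict.fromkeys(FEATURE_COLUMNS, 0.0)
            f["lm_m"] = 0.1 * i
            f["v_total_V"] = float(i)
            rows.append(f)
        out = condense(pd.DataFrame(rows))
        np.testing.assert_allclose(out["v_total_V"], np.arange(5.0))
        assert (out["n_replicates"] == 1).all()

    def test_replicate_weighted_mean_is_conserved(self, synthetic_tables):
        condensed, extended = synthetic_tables
        lhs = np.average(condensed["v_total_V"],
                         weights=condensed["n_replicates"])
        assert lhs == pytest.approx(extended["v_total_V"].mean())
        assert condensed["n_replicates"].sum() == len(extended)

    def test_empty_rejected(self):
        with pytest.raises(DatasetError):
            condense(pd.DataFrame())


class TestStructure:
    def test_default_configuration_counts(self, default_bodies):
        spec = default_catalog_spec(default_bodies, master_seed=0)
        s = dataset_structure(spec, n_coil_sets=5, n_landmarks=12)
        assert s["volumetric_solves"] == 1080
        assert s["extended_rows"] == 180_420
        assert s["condensed_rows"] == 10_620
        assert s["trajectories"] == 3007 and s["groups"] == 177

    def test_small_structure(self, default_bodies):
        body = default_bodies[0]
        spec = default_catalog_spec([body], master_seed=0, n_trajectories=2,
                                    n_groups=1)
        s = dataset_structure(spec, n_coil_sets=1, n_landmarks=3)
        assert s["extended_rows"] == 6
        assert s["volumetric_solves"] == 9


class TestEnumerateExtended:
    def test_missing_cache_entry_names_tuple(self, reference_body, coil_set):
        from gradvolt.cache import MemoryFieldCache
        from gradvolt.trajectories import build_trajectory
        cfg = ImplantConfig("left", "left", "pectoral", 0.40, 0.60)
        traj = build_trajectory(reference_body, cfg, 0)
        with pytest.raises(DatasetError, match="set01"):
            enumerate_extended([traj], [coil_set], [0.0], MemoryFieldCache(),
                               [reference_body])


def test_csv_roundtrip(tmp_path, synthetic_tables):
    condensed, _ = synthetic_tables
    p = tmp_path / "c.csv"
    write_table(condensed, p)
    back = read_table(p)
    assert list(back.columns[:10]) == FEATURE_COLUMNS
    np.testing.assert_allclose(back["v_total_V"], condensed["v_total_V"],
                               rtol=1e-8)
    with pytest.raises(DatasetError):
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        read_table(bad)
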