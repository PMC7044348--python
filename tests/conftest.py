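import numpy as np
import pytest

from gradvolt.bodies import BodyModel, Ellipsoid, build_default_bodies, voxelize_body
from gradvolt.coils import build_coil_set


def sphere_body(radius: float, center=(0.0, 0.0, 0.0)) -> BodyModel:
    """A spherical homogeneous conductor as a one-primitive body (synthetic
    geometry for the analytic-oracle tests)."""
    return BodyModel("sphere", 1.5, 60.0,
                     {"sphere": Ellipsoid(center, (radius,) * 3)}, 1.0)


@pytest.fixture(scope="session")
def coil_set():
    """One calibrated whole-body gradient coil set."""
    return build_coil_set("set01", 0.66, 1.40)


@pytest.fixture(scope="session")
def default_bodies():
    return build_default_bodies()


@pytest.fixture(scope="session")
def reference_body(default_bodies):
    return default_bodies[0]


@pytest.fixture(scope="session")
def reference_grid_2cm(reference_body):
    return voxelize_body(reference_body, 0.02)


@pytest.fixture(scope="session")
def synthetic_tables():
    """Small synthetic condensed/extended tables with a known smooth
    feature→voltage law, for ML-layer tests that need no field physics."""
    rng = np.random.default_rng(42)
    import pandas as pd
    # five ordinary adults plus one heavy outlier ("b6"), so leave-one-out
    # folds interpolate except for the heavy body, which extrapolates in mass
    bodies = [("b1", 1.77, 0.72), ("b2", 1.63, 0.58), ("b3", 1.63, 0.80),
              ("b4", 1.73, 0.62), ("b5", 1.68, 0.69), ("b6", 1.68, 1.20)]
    rows = []
    for body, h, m in bodies:
        for brain in (0, 1):
            for ins in (0, 1):
                for lm in (0.0, 0.15, 0.3, 0.45, 0.6, 0.75, 0.9, 1.05):
                    for ll, el in ((0.33, 0.6), (0.4, 0.95)):
                        base = (0.4 + 0.5 * m + 0.5 * ins + 0.3 * el
                                + 0.4 * np.sin(4.0 * lm) + 0.1 * brain)
                        for rep in range(3):
                            rows.append({
                                "body": body, "height": h, "mass_100kg": m,
                                "brain": brain, "neck": brain, "ins": ins,
                                "lead_len_m": ll, "ext_len_m": el, "lm_m": lm,
                                "coil_diam_m": 0.66, "coil_len_m": 1.4,
                                "replicate_id": rep,
                                "v_total_V": base + 0.05 * rng.normal(),
                            })
    extended = pd.DataFrame(rows)
    feature_cols = ["height", "mass_100kg", "brain", "neck", "ins",
                    "lead_len_m", "ext_len_m", "lm_m", "coil_diam_m",
                    "coil_len_m"]
    condensed = (extended.groupby(feature_cols, sort=False, as_index=False)
                 .agg(v_total_V=("v_total_V", "mean"),
                      n_replicates=("v_total_V", "size"),
                      body=("body", "first")))
    return condensed, extended
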