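# gradvolt

Desk-scale modelling of MRI **gradient-field induced voltages on implanted
deep-brain-stimulation (DBS) systems**, with a neural-network surrogate.

Time-varying MRI gradient fields induce electric fields in the body. Along the
elongated conductive path of a DBS implant — intracranial electrode, extension
tunneled down the neck, neurostimulator (INS) in a pectoral or abdominal
pocket — those fields produce an extrinsic potential between the electrodes
and the device enclosure that can cause unintended stimulation or device
malfunction. Device safety assessments therefore need clinically relevant
induced-voltage exposure levels, which are expensive to obtain because each
new anatomy and implant routing requires fresh electromagnetic simulation.
`gradvolt` implements that simulation chain on fast parametric models and
trains a regression surrogate that predicts voltages from ten easily
identifiable features in milliseconds.

## What it computes

For each gradient axis the induced voltage is the tangential line integral of
the induced E-field along the implant path of length *L*,

    V_axis = ∫₀ᴸ E⃗ · dl⃗,      E⃗ = −∂A⃗/∂t − ∇φ,

where A⃗ is the coil's vector potential and φ solves a Laplace problem with a
no-current boundary condition on the body surface (magneto-quasi-static
approximation; the solution is independent of the homogeneous tissue
conductivity). Axis contributions are combined conservatively, modelling all
three axes slewing simultaneously at the scanner's maximum slew rate
(200 T/m/s by default):

    V_total = slew × (|V_X| + |V_Y| + |V_Z|).

The pipeline stages are:

1. **coils** — parametric X/Y/Z gradient windings (Maxwell pair, Golay
   saddles) on five whole-body formers, calibrated to 1 T/m at isocenter;
2. **bodies** — six homogeneous parametric bodies (head/neck/torso/pelvis/leg
   solids) matched to height and mass, positioned at 12 scan landmarks;
3. **efield** — a volume-fraction finite-volume solver for the induced field
   per axis at unit slew rate, cached in HDF5;
4. **trajectories** — seeded, clinically plausible lead+extension routings
   (3007 in 177 implant-configuration groups at full scale), with replicate
   variability;
5. **dataset** — the *extended* table (one voltage per trajectory × coil set ×
   landmark; 180,420 rows at full scale) and the *condensed* table obtained by
   averaging replicates that share a 10-feature tuple (10,620 rows);
6. **surrogate / evaluation** — a two-hidden-layer neural network
   (10→25→120→1, leaky ReLU, Adam, batch 32, 300 epochs) plus SVM/forest/
   boosting baselines, scored by R², MSE and median absolute error under
   leave-one-body-model-out cross-validation. The fold-wise maximum MSE/MAE
   serves as the conservative prediction uncertainty of the final model.

The ten features: subject height (m) and mass (100 kg units); brain
hemisphere, neck side and INS location (binary); lead and extension length
(m); scan landmark (m below the top of the head); coil diameter and length (m).

## Worked example

```python
from gradvolt import (build_coil_catalog, build_body_model, voxelize_body,
                      position_at_landmark, solve_induced_efield,
                      build_trajectory, ImplantConfig, tangential_voltage,
                      combine_axes)

coil_set = build_coil_catalog([(0.66, 1.40)])[0]          # 0.66 m bore former
body = build_body_model("reference_male", height=1.77, mass=72.0)
grid = voxelize_body(body, spacing=0.02)
placement = position_at_landmark(body, lm=0.3)            # chest scan

cfg = ImplantConfig(brain_side="left", neck_side="left",
                    ins_location="pectoral", lead_length=0.40,
                    extension_length=0.60)
lead = build_trajectory(body, cfg, replicate_seed=7)

v = {}
for axis in "XYZ":
    emap = solve_induced_efield(grid, coil_set.coil(axis), placement)
    v[axis] = tangential_voltage(emap, lead)              # V per (T/m/s)
print(combine_axes(v["X"], v["Y"], v["Z"], slew=200.0))
```

This prints per-axis voltages of −0.000715, 0.000491 and −0.000563 V per unit
slew rate and a combined `0.354 V` at 200 T/m/s — the conservative exposure
level for this subject, implant routing and scan position. Dataset-level runs
go through the CLI:

```bash
gradvolt run-all --scale reduced --seed 1 --out out/   # 600-trajectory study
gradvolt predict --model out/surrogate_nn.joblib \
                 --features my_features.csv --out predictions.csv
```

The `reduced` study (six bodies, two coil sets, 12 landmarks, 2 cm grid)
takes a few minutes on one CPU; its `evaluation.json` reports per-body
cross-validation folds. With seed 1 the held-out heavy body is the clear
outlier (R² 0.75, MSE 55.7 mV, MAE 179.5 mV against R² ≥ 0.93, MSE ≤ 10.4 mV
for the other five folds), illustrating how surrogate accuracy degrades for
anatomies unlike anything in training. MSE is reported as V² × 1000 ("mV"
convention); MAE is the median absolute error in mV.

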