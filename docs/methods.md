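# Methods

This note documents the physical models, numerical choices and known
limitations of the `gradvolt` pipeline.

## Quasi-static induction model

Gradient switching frequencies (≲10 kHz) put the problem deep in the
magneto-quasi-static regime: displacement currents and wave propagation are
negligible, and the induced field in a conductor is `E = −∂A/∂t − ∇φ`. The
windings are closed loops, so A is divergence-free (Coulomb gauge) and charge
conservation in a homogeneous conductor reduces to a Laplace problem for φ
with the no-current condition `n·(∂A/∂t + ∇φ) = 0` on the surface. Two
consequences shape the package:

* **Conductivity independence.** For a homogeneous body the boundary-value
  problem never involves σ, so the induced E-field (and every voltage derived
  from it) is identical for any σ > 0. `BodyModel.conductivity`
  (default 0.35 S/m, average soft tissue) is carried as metadata only; users
  should not interpret voltage results as σ-sensitive.
* **Linearity.** E scales exactly with slew rate and coil current. All maps
  are therefore solved once per (body, coil set, axis, landmark) at unit slew
  (1 T/m/s) and rescaled as needed.

## Gradient coil models

Real clinical winding patterns are proprietary; the package uses the textbook
minimal windings with the same near-isocenter behaviour: a counter-wound
Maxwell loop pair at z = ±L/4 for the Z axis and four 120° Golay saddle loops
(inner arcs at ±0.39·a, outer arcs at ±0.45·L, axial return paths) for X/Y,
all on the cylindrical former of each set. The five (diameter, length) pairs —
0.60–0.70 m by 1.20–1.50 m — span clinical whole-body scanners and are
configuration defaults, not measurements of specific hardware.

Fields follow from the Biot–Savart law. Arcs are integrated by a midpoint rule
in arc angle (720 points per turn by default; spectrally accurate for closed
loops — the on-axis loop test passes at 1e-6 relative with large margin),
straight segments by 48-point Gauss–Legendre quadrature, with a closed-form
finite-wire expression available as an oracle. Each axis coil is calibrated so
that a stored drive current produces exactly 1 T/m of dB_z along its axis at
isocenter (5-point finite-difference gradient, h = 1 mm); calibration is
idempotent and makes "slew rate" a direct current-ramp scale.

## Body models

Anatomical meshes are replaced by a six-solid parametric stack (head
ellipsoid; neck, torso, pelvis elliptic cylinders; two leg cylinders) whose
axial extents are fixed fractions of standing height and whose lateral
semi-axes share one girth factor. The girth factor is solved by a fixed-point
iteration so the voxelized body volume matches mass at 1050 kg/m³; the
vertical extent equals the stated height by construction. Adjacent solids
overlap by ≥ 0.02·h so the union stays connected on coarse grids and under
the 12 mm safety-margin erosion used by the trajectory generator.

The default catalog holds six adults. Five have ordinary masses (58–80 kg,
heights 1.63–1.77 m); the sixth is a 120 kg body, ~40 kg above the next
heaviest, deliberately creating the under-represented habitus against which
generalisation is judged. Scan landmarks place the body point `LM` meters
below the top of the head on the isocenter plane, for `LM` ∈ {0.0, 0.1, …,
1.1} m — 12 positions from head to thigh, which with 6 bodies, 5 coil sets
and 3 axes yields 1080 volumetric solves at full scale. The body frame
(origin at head top, +z toward the feet) maps to the scanner frame by
`z_s = LM − z_b` with x, y unchanged; varying the landmark changes only a
z-offset. Vector components transform with a z sign flip.

## Induced-field solver

The solver discretizes `∇·(σ(∇φ + ∂A/∂t)) = 0` by cell-centered finite
volumes, where σ is the *subvoxel volume fraction* of conductor in each cell
(3³ subsamples in cut cells). This diffuse-interface embedding represents the
surface normal smoothly; a plain staircase Neumann discretization was tested
first and converged too slowly (≈13% RMS error against the conducting-sphere
closed form at 1 cm, versus ≈3.3% for the volume-fraction scheme). Face
coefficients are arithmetic means of the adjacent cell fractions; ∂A/∂t at
faces is averaged from cell centers (the potential is smooth). The singular
symmetric system is solved by conjugate gradients (relative residual 1e-6,
max 20,000 iterations) after projecting the right-hand side onto the
operator's range; the gauge fixes φ to zero mean. E is reconstructed at cell
centers by central differences (one-sided at the surface) and extended
outside the mask by nearest-neighbour fill so that trilinear interpolation
near the scalp is well defined.

Verification oracles, exercised in the test suite:

* conducting sphere under uniform dB/dt (`E = −½ dB/dt × r`): RMS error
  3.7% → 3.2% → 2.6% at 2/1/0.5 cm, monotone;
* surface current leakage `|n·E|`, sampled at fixed Fibonacci points on the
  analytic sphere surface: < 5% of the mean interior field at 1 cm and
  decreasing from 2 cm to 1 cm. (Sampling at fixed surface points matters:
  staircase voxel normals make the per-voxel quantity O(1) for any solver.)
* Faraday consistency `∇×E ≈ −dB/dt` at interior voxels of a real coil solve
  (median relative error ≈0.1% at 2 cm).

Grid spacing defaults to 1 cm for full-scale production and 2 cm for the
reduced study and tests. Scan landmarks are multiples of the grid spacing, so
the coil's vector potential across all 12 landmarks of a (body, set, axis)
triple is evaluated once on a deduplicated scanner-frame lattice and sliced
per landmark (~4× saving on the dominant cost).

## Trajectory generator

A routing is built from anatomical waypoints (deep-brain electrode on the
configured hemisphere → burr hole → behind the ear → configured neck side →
INS pocket), densified, jittered, smoothed, projected inside the
margin-eroded body, and resampled at 5 mm. Surplus length is wound into
strain-relief loops (radius 2.5 cm): up to two turns at the burr hole,
the remainder coiled behind the pocket, making the polyline arc length match
lead + extension length to well within 1%. Pocket centers sit at 0.25·h
(pectoral) or 0.45·h (abdominal) below the head top, lateralised to the neck
side.

Replicate variability — the paper-level fact that the ten features cannot
distinguish routings sharing a configuration — is modelled as Gaussian jitter
(σ = 8 mm, a configuration knob) of interior waypoints. Configurations whose
jitter-free backbone leaves less than 5 cm of surplus (plus a 4 cm screening
margin covering jitter-induced lengthening) are infeasible; short
lead+extension combinations therefore cannot reach an abdominal pocket, and
the catalog draw samples only feasible configurations. The full catalog
allocates 177 (body, configuration) groups over six bodies (30/30/30/29/29/29
by seeded choice from each body's feasible grid) with replicates spread
17/16-fold to total 3007 trajectories; the reduced study keeps all 177 groups
at 3–4 replicates (600 trajectories).

## Dataset and features

Voltages are integrated by the midpoint rule on ≤5 mm segments with trilinear
field interpolation; uniform-field line integrals are exact to machine
precision, and a semicircle in the sphere-oracle field matches the analytic
azimuthal integral to 0.1%. Points marginally outside the voxel mask (scalp
voxelization jitter) are served by the nearest-inside fill up to a one-voxel
tolerance; farther excursions are errors. Per-axis voltages at unit slew are
combined as `V_total = slew × Σ|V_axis|`. The extended table carries one row
per (trajectory × coil set × landmark) in a fixed column order; condensing
averages `v_total` over identical 10-feature tuples and records the replicate
count. Binary features encode left/pectoral as 0, right/abdominal as 1; mass
is stored in 100 kg units so all features are O(1).

## Surrogate and evaluation

The default surrogate is a fully connected 10→25→120→1 network with
leaky-ReLU hidden units (slope 0.01) and a linear output, trained on z-scored
features (statistics from training rows only) with Adam (learning rate 1e-3),
batch size 32, 300 epochs, mean-squared-error loss. It is implemented
directly in numpy: weights, shuffling and updates derive from one seeded
generator, making training bit-reproducible — a property the tests assert.
The optimizer, learning rate and linear output are package choices where the
architecture description leaves them open; a leaky output activation is
available as a switch for strictly nonnegative targets. The parameter count
of the default architecture is 3,516. SVM (linear/RBF), random-forest and
gradient-boosting baselines run behind the same spec interface via
scikit-learn, with small default grids tuned by exhaustive k-fold search
(ties broken by grid order).

Metrics are R², MSE reported as V²×1000 and *median* absolute error in mV —
the "mV" convention keeps both error numbers on comparable scales for
volt-level targets. Generalisation is probed by leave-one-body-model-out
cross-validation: train on the other bodies' condensed rows, monitor per
epoch on the held-out condensed rows, score on the held-out *extended* rows,
which retain replicate variability and therefore gauge true predictive
performance. Because a production model trained on everything has no held-out
set, the fold-wise maximum MSE and MAE are attached to it as conservative
prediction uncertainty.

On the reduced study (600 trajectories, 2 coil sets, 2 cm grid, seed 1) the
heavy-body fold is the clear outlier — R² 0.75, MSE 55.7 mV, MAE 179.5 mV,
with a systematic bias — while the other five folds reach R² ≥ 0.93 and
MSE ≤ 10.4 mV. The problem sizes of the reduced study (2 coil sets, 2 cm
spacing, 600 trajectories) were chosen as the smallest configuration that
retains all six bodies, the full landmark sweep and the complete 177-group
structure.

## What the synthetic study does and does not show

The generator reproduces the *structure* of a production voltage study —
configuration counts, replicate grouping, feature scheme, landmark sweep, the
heavy-body generalisation gap — and its physics is verified against analytic
oracles. It does not emulate heterogeneous tissue conductivity, anatomical
surface detail, image-derived routing geometry, lead-internal conductor
structure, time-domain gradient waveforms, or eddy currents in the cryostat.
Absolute voltage levels are therefore indicative (sub-volt to a few volts at
200 T/m/s, with mass, abdominal placement and head/pelvis landmarks raising
exposure), and passing tests demonstrate correctness of the pipeline, not
clinical exposure values for any real scanner or patient. Hazard assessment
of real devices requires validated anatomical models and certified solvers.

## Degenerate inputs and tie-breaks

Windings with no central gradient fail calibration explicitly; evaluation
points within half a quadrature-node length of a winding raise a singularity
error. Bodies outside 1.4–2.1 m or 40–200 kg, voxel spacings outside
5–50 mm, landmarks outside [0, height], and non-finite training data are
rejected. Zero-variance targets flag R² as undefined rather than returning a
number. CG starts from zero; hyperparameter ties keep the first grid point;
grouping preserves first-occurrence order so condensed tables are stable.
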