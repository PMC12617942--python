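# Methods

This note documents the models behind `skullvibe`, the defaults and
why they were chosen, and what the synthetic test bed does and does
not establish about real specimens.

## The physical problem

A skull submerged in water and insonified by a low-frequency plane
wave responds quasi-statically as an elastic body: the acoustic
wavelength (≈1.5 m at 1 kHz in seawater) is much longer than the
specimen, so pressure differences across the skull are small and the
dominant response is structural. The tympanic bulla — a dense, stiff
ear bone hanging from the skull base on compliant pedicles — behaves
as a mass on a soft suspension and resonates within the band of
interest, moving far more than the bone it hangs from. That relative
motion ("amplification") is the proposed bone-conduction input to the
ossicular chain, and the quantity the pipeline is designed to
reproduce and score.

## Synthetic specimen

The phantom reproduces topology, not anatomy: a 24×24×48-voxel grid at
5 mm spacing (120×120×240 mm solid) containing

* a bone plate (basicranium), 20×6×40 voxels;
* two 4×4×6-voxel TPC blocks (dense, stiff) under the plate, each
  suspended on two 1×1-voxel connective-tissue pedicles two voxels
  (10 mm) long;
* an optional mandible: two bone rails joined anteriorly by symphysis
  tissue and attached to the cranium only through TMJ pads, so no
  bone-to-bone path crosses the joint;
* cranium and mandible share the bone material class but carry
  distinct region tags.

Pedicle cross-section and length were chosen once so that the bulla
swing resonance falls inside the 170–1000 Hz measurement band (it
lands near 324 Hz with natural-skull materials); the axial bulla mode
and the first plate modes also fall in or just above the band. All
dimensions are configurable, and `refine` regenerates the same world
geometry at 2×/4× resolution for convergence studies.

Sensor layout mirrors the seven-channel experimental scheme: skull
ML/AP/DV at the dorsal plate center (massless — negligible against the
skull), and per bulla an ML channel at the posterior apex (3 g sensor)
and an AP channel on the ventral keel (7.5 g sensor), each plus 3 g of
lead wire (0.25 m at 12 g/m) lumped at the attachment node. How the
lead mass should be split between sensor and skull is unknowable from
the record; the full 3 g is lumped at the sensor node.

Synthetic "experimental" FRFs are modal sums
`H(w) = sum_r (-w^2 a_r) / (w_r^2 (1 + i eta_r) - w^2)` with
log-normal multiplicative magnitude noise (default sd 1 dB), uniform
phase jitter (±0.2 rad) and a small additive complex floor
(1e-4 m/s^2/Pa) — reproducing the smooth-but-offset character of
smoothed pool measurements. The default recipe places resonance groups
at 330/650/1100 Hz with participation factors at the phantom's own
response scale (bulla peaks of a few 1e-3 m/s^2/Pa), so model-vs-
reference scores land in the moderate-agreement regime rather than
being trivially 0 or 1.

## Meshing

Each solid voxel splits into five tetrahedra (a central tet on
alternate cube corners plus four corner tets); the decomposition
mirrors with voxel parity so shared faces carry matching diagonals and
the mesh conforms exactly. Unsmoothed mesh volume therefore equals
voxel count × voxel volume to round-off.

Smoothing is Taubin's λ/μ two-step Laplacian (defaults λ=0.5,
μ=−0.53, 10 iterations, uniform weights over tet edges, interior nodes
included). On blocky voxel meshes the band-pass argument for volume
preservation fails — a lone voxel's eight corners are pure high-graph-
frequency content and would collapse — so after smoothing each
connected component is rescaled about its volume-weighted centroid to
restore its volume exactly. Smoothing aborts with the iteration index
if a tet inverts.

## Acoustic pressure stage

The total pressure around the specimen solves the heterogeneous scalar
wave equation `(1/(rho c^2)) p_tt = div((1/rho) grad p)` with solids
entering as fluid-equivalent media (their density, and bulk sound
speed `sqrt(E/rho)`): the vibration stage consumes only the surface
pressure, and this preserves the impedance-contrast structure of the
scattering problem at a fraction of the cost of coupled
elastodynamics. Coupling is strictly one-way (pressure → load); the
structure's radiation back into the water is neglected, consistent
with the two-stage design.

Numerics: centered-difference time stepping at CFL 0.5 (bound
1/sqrt(3)), **scattered-field formulation** — the simulated variable
is `p - p_inc`, driven by the incident wave's residual under the
heterogeneous *minus* the uniform-water discrete operator, which
vanishes identically away from the scatterer. In homogeneous water the
scheme therefore returns the incident wave exactly; the graded sponge
layers (8 cells, quadratic profile) only absorb the small scattered
wave. The drive ramps on over 2 periods; after 4 periods (configurable,
≥3) the field is sampled at 11 equispaced stations spanning the final
period (endpoint excluded) and projected onto cos/sin at the drive
frequency — exact for a pure harmonic. Time convention `exp(+iwt)`.

Fields are computed on a coarse 100–1000 Hz grid (step 100 Hz) and
interpolated linearly in frequency (real and imaginary parts
separately) to each sweep frequency; interpolation is exact at grid
frequencies and for fields linear in frequency, and the associated
error is itself measurable by the half-grid experiment in the test
suite. Because trilinear surface sampling and frequency interpolation
are both linear, the pipeline samples the coarse fields on the wetted
surface once and interpolates surface values — identical to
interpolating volumes first, at far lower cost.

The pipeline also offers an `incident` pressure mode (analytic plane
wave, no scattering). At phantom scale the scatterer is ~100× smaller
than the wavelength and perturbs the loading by ~1%, so trend studies
and sweeps that re-run many models default to it in the test suite;
the FDTD path is exercised separately.

## Vibration stage

Standard constant-strain (4-node) tetrahedral elasticity with
consistent mass; sensor masses lumped on the three translational DOFs
of the nearest node. A nodally-integrated stabilized element would be
needed for strongly incompressible tissue at scale; here the connective
tissue's Poisson ratio is capped at 0.49 and the phantom avoids thin
incompressible layers, keeping plain CST adequate (its mild bending
stiffness overestimate shifts pedicle resonances upward slightly — a
known, documented bias).

The suspension fixture of the experiments resonates near 0.4 Hz;
between 170 and 1000 Hz the inertial force dominates its restoring
force by >4 orders of magnitude, so no suspension stiffness is modeled
and the structure is free-free, with its 6 rigid-body modes retained
in the basis.

Modal reduction keeps every mode with natural frequency ≤ 1.5× the top
sweep frequency (cutoff 1500 Hz for the default sweep). Because each
material has its own loss factor, `sum_m (1+i eta_m) K_m` cannot be
diagonalized jointly with M; the projected stiffness blocks
`Phi^T K_m Phi` are kept per material and a dense complex system of
size n_modes is solved at each of the 416 sweep frequencies. Loss
factors therefore enter *after* projection, which the pipeline
exploits by caching modal bases keyed on geometry/stiffness/density:
damping-only factorial runs never re-solve the eigenproblem. The
eigensolver is shift-invert Lanczos at a small negative shift (the
free-free stiffness is singular) with a fixed start vector for
bit-reproducibility, and a dense solver below 600 DOF.

Pressure loads are consistent nodal forces of the traction `t = -p n`
(n outward) with linear pressure interpolation per boundary triangle:
`F_a = -(A/12)(p_1+p_2+p_3+p_a) n`. Uniform pressure on a closed
surface yields zero net force to round-off, and a linear field
reproduces the buoyancy identity `F = -grad(p) V` exactly — both are
acceptance checks.

Channel output is `-w^2 (axis · U_sensor) / p_0` in m/s^2/Pa, and
amplification is the per-frequency ratio `|H_bulla|/|H_skull|`,
averaged over left and right bullae.

## Similarity metrics

The operational definitions are frozen here because the original
metric variants are not fully recoverable from the literature trail:

* `CSAC(H1,H2) = |sum H1* H2|^2 / (sum|H1|^2 sum|H2|^2)` — the
  frequency-domain assurance criterion specialized to scalar
  per-sensor FRFs (the per-frequency spatial form degenerates to 1 for
  a single channel);
* `CSSF2 = 2 sum|H1||H2| / (sum|H1|^2 + sum|H2|^2)` — magnitude-only,
  hence independent of CSAC's phase/shape information; equals
  `2a/(1+a^2)` under uniform scaling `a`;
* `FRFSM = mean_k exp(-eps_k^2 / (2 sigma0^2))` with
  `eps_k = |dB(H1_k) - dB(H2_k)|`, default `sigma0 = 6 dB`
  (configurable; magnitudes floored at 1e-30× the pair maximum).

All three live in [0,1], are symmetric, and equal 1 on identical
inputs. Scores across the seven channels are summarized as
`(median, 2 b median|s - median|)` with b = 1.4826 (the constant that
makes the MAD a consistent sigma estimator for normal data). Optional
FRF smoothing is a centered moving average on log-magnitude and
unwrapped phase.

## Factorial studies

Two-level full factorials in standard ±1 coding, ordered by binary
counting (first factor fastest). Main effect of factor i is the mean
response difference between its high and low halves; the (i,j)
interaction is `2 mean(y x_i x_j)`, so a noiseless response
`b0 + sum b_i x_i + sum b_ij x_i x_j` is recovered exactly as `2b_i` /
`2b_ij` by orthogonality. Shipped factor sets: replica {E, rho} (±10%
around 2.095 GPa / 1008 kg/m^3) and natural skull {Esk, Etp, rhosk,
rhotp, lfs, lft} (64 runs; the loss-factor ranges are deliberately
wide and asymmetric, e.g. skull 0.2–0.45 around a nominal 0.3).
The response is the median FRFSM across sensors. No replication,
fractional designs or significance testing. The nominal skull loss
factor is genuinely contested (0.3 acoustic-regime vs 0.1 for prepared
bone); both ship as named presets and the choice is explicit.

## Material presets

Natural skull: bone rho 1100 kg/m^3, E 8 GPa, nu 0.3, eta 0.3; TPC
rho 2500, E 35 GPa, nu 0.3, eta 0.05; TMJ/pedicle tissue rho 1100,
E 0.2 GPa, nu 0.49, eta 0.1. Replica: ASA plastic throughout, rho
1008 kg/m^3 (weighed), E 2.095 GPa (mean of the two print-orientation
datasheet moduli), nu 0.3, loss tangent 0.05. Water: rho 1026 kg/m^3,
c 1507 m/s.

## Problem sizes and numerical choices

Default phantom: 5728 solid voxels → 28 640 tets, 7 752 nodes
(23 256 DOF), 29 modes below 1500 Hz (6 rigid). The refinement and
material-study tests use a reduced phantom (628 voxels) so 2× levels
and repeated eigensolves stay cheap; the acceptance script uses the
default phantom. Tolerances: rigid modes are eigenvalues below 1e-6 of
the largest computed eigenvalue; degenerate (non-positive-volume) tets
abort assembly; an exactly-resonant undamped reduced system raises
with advice to use a nonzero loss factor; amplification with a
vanishing skull response flags those bins and reports +inf.

## What the synthetic tests do and do not show

Passing this suite demonstrates that the machinery is correct: the
solvers match closed forms and independent direct solutions, the
metrics their identities, the trends (stiffness ↑ → resonances ↑ by
sqrt, density ↑ → resonances ↓, bulla amplification > 1 at the pedicle
resonance) emerge from the assembled physics. It does **not**
demonstrate anatomical fidelity: the phantom has no real skull
geometry, the synthetic reference is not a measurement, and the
fluid-equivalent acoustic treatment of bone is an approximation whose
error grows with impedance contrast and ka. Real-specimen validation
additionally contends with non-plane-wave loading in finite pools —
outside this package's scope.
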