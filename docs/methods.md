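# Methods

## Model and scope

`phasedefect` analyzes spatiotemporal excitation movies `V(x, y, t)`
(optionally `V(x, y, z, t)`, optionally with a second observable `R`) on a
regular grid, and ships the monodomain simulator that generates all of its
test scenarios. The pipeline is: movie → phase field(s) → frame-wise
detection of phase singularities (PSs), conduction block lines (CBLs) and
phase defect lines/surfaces (PDLs/PDSs) → temporal tracking → summary
statistics.

## Monodomain simulator

The tissue model is the isotropic monodomain equation

    ∂t u = P Δu + F(u),   P = diag(P11, 0, …, 0),

integrated with explicit Euler on a 5-point (2D) or 7-point (3D) Laplacian
stencil, no-flux boundaries via mirrored ghost nodes, and the stability
bound `dt < dx²/(2·dim·P11)` enforced at run start. Only the voltage-like
first variable diffuses. Stimuli are clamps of that variable over spatial
masks; an S1-S2 cross-field protocol (plane-wave S1 from one edge, premature
quadrant S2) is the standard rotor-initiation recipe.

Three reaction models are provided; their parameter sets are shipped as YAML
files under `phasedefect/params/` and loaded by `get_kinetics`:

| model  | variables | set      | units      | role |
|--------|-----------|----------|------------|------|
| `ap`   | u, v      | standard | dimensionless | circular-core spirals |
| `fk`   | u, v, w   | MLR-I / MBR | mm, ms  | linear-core rotors (2D / 3D) |
| `bocf` | u, v, w, s| EPI      | mm, ms     | human-ventricle minimal model |

Each model also carries its analysis defaults: the observable pair
(`V = u`; `R = v` for `ap`, `R = 1 − v` otherwise), the thresholds
`(V*, R*)` = (0.5, 1) / (0.5, 0.8) / (0.5, 0.2), the LAT frame interval
`dt_lat` (1 / 1.6 / 5), the CBL threshold `dt_c` (10 / 16 / 45), the
arrival-phase threshold `dphi_arr_crit` (0.7 / 2 / 0.5 rad) and timescale
`tau` (20 / 70 / 300). The resting state is an exact fixed point for `ap`
and `bocf` (the BOCF resting gate `s` is set to its sigmoid steady state);
the FK model retains an O(1e-10) residual from the tanh tail of its
slow-inward current, which we treat as zero within tolerance.

Anisotropic diffusion (fiber fields) is out of scope; the 3D slab uses
isotropic diffusion. Conduction velocities converge slowly (first order) in
`dx`: at the production resolutions the front speed is several percent below
the converged value, which is why the velocity verification (below) runs at
half the production spacing.

## Phase definitions

All phases are stored in `[-π, π)` with `NaN` for undefined pixels;
comparisons always go through the wrap `U(x) = mod(x + π, 2π) − π`, whose
boundary convention maps `π` to `−π`. The offset `b` is chosen per model so
the resting state sits at phase 0 (`b = −atan2(R_rest − R*, V_rest − V*)`).

* **Activation phase** `φ_act = U(atan2(R − R*, V − V*) + b)`; the reference
  point `(V*, R*)` must lie inside the cycle in the `(V, R)` plane (not
  checked); a pixel exactly at the reference has no polar angle → `NaN`.
* **Hilbert phase**: analytic-signal angle of the per-pixel mean-subtracted
  `V` trace, for single-observable (optical) data. Default offset `b = π`
  maps a pixel resting near its trace minimum to phase ≈ 0.
* **Arrival-time phase** `φ_arr = U(2π·tanh(3·(t − LAT)/τ))`. LAT is the
  time of the most recent upward crossing of `V*`, updated per frame
  ("newest LAT wins"); the never-activated sentinel is LAT = 0 and all valid
  LATs are positive because crossings need two frames. `τ` is the recovery
  timescale (≈ the action-potential duration, or the inverse dominant
  frequency). Freshly excited and fully recovered tissue both map to 0
  (mod 2π), so wave fronts and wave backs are invisible; a conduction block
  line, where elapsed times differ finitely, appears as a phase defect.
  Because LAT is sampled every `dt_lat`, φ_arr carries a staircase artifact
  of amplitude `2π·3·dt_lat/τ` (≈ 0.43 rad for FK defaults) — all φ_arr
  thresholds must exceed it.

Derived constructions: the wrapped forward-difference gradient
`|∇φ|` (per-axis `U(Δφ)/dx`, Euclidean norm, `NaN`-propagating); the
upstroke/downstroke phase levels φ1/φ2 as *circular* means of the phase over
pixels crossing `V*` upward/downward between consecutive frames (arithmetic
means break at the wrap; dV/dt is the causal backward difference, matching
the LAT update); wave front and wave back as the corresponding crossing
pixel sets (disjoint by construction).

The boundary-layer estimate for the thickness of a phase defect line is
`d = sqrt(D·τ) × (c1/c2)`, returned in mm for `D` in cm²/s and `τ` in ms.
The square root is required by dimensional analysis and reproduces both
worked values for the human-ventricle model (5.6 mm across fibers, 14 mm
along them at anisotropy ratio 2.5).

## Detectors

Coordinates are 0-based `(row, column[, depth])`; pixel centres at integers,
cell corners and edge midpoints at half-integers.

**Phase singularities (ring method).** Around each grid-cell corner the
cyclic *raw* phase differences of the four surrounding pixels are computed
(for the combined `2x2+4x4` variant also of the octagonal 8-pixel outer
ring: the 4×4 perimeter minus its corners). A PS is flagged iff exactly one
difference exceeds π in magnitude on the inner ring (combined: on both
rings; equal jump sign across rings is not required). Since cyclic raw
differences telescope to zero, a single super-π difference forces the
unwrapped winding sum to ∓2π, so the detector is equivalent — on fields with
one defect per cell and bounded smooth gradients — to the independent
winding-number oracle, and **chirality is defined as the winding sign**,
i.e. the *negative* of the sign of the unique super-π raw difference. A
plaquette straddling a phase defect has two super-π differences, zero
winding, and is rejected: the ring method cannot see the extended defect,
only its endpoints' winding.

**Edge detectors.** All line/surface detectors flag 4-neighbor
(6-neighbor in 3D) edges; diagonal adjacency enters only through component
connectivity (midpoints within Chebyshev distance 1, i.e. 8-/26-connectivity).

* CBL: both endpoints activated (LAT > 0) and `|ΔLAT| > dt_c`. The
  positivity conditions remove the wave front **only against never-activated
  tissue**; once re-entry re-invades previously activated tissue, the
  front-vs-previous-beat LAT jump (≈ one rotation period) is also flagged.
  All quantitative CBL analyses in this package therefore start LAT
  bookkeeping fresh at the beginning of the analyzed episode.
* PDL: `|U(φ1 − φ2)| > dphi_crit` (default 2.22 rad, the optical-mapping
  value). Thresholds ≥ π can never fire on wrapped differences and warn.
* Cosine variant: `cos(φ1 − φ2) < A`, exactly equivalent to the wrapped-jump
  rule with `dphi_crit = arccos(A)`. The published inequality has the
  opposite direction, which would flag smooth tissue; it is preserved behind
  `printed_inequality=True` for strict reproduction.
* PDS: the PDL rule over all axis-aligned edges of a volume. Restricted to a
  surface layer it coincides exactly with the 2D detector on that slice.

**PS↔PDL association.** Every flagged edge contributes both endpoint nodes
to the PDL. With PS positions at cell corners (half-integer) and nodes at
integers, the smallest realizable corner-to-node distance is √2/2 ≈ 0.707,
so a literal "< 0.5 px" rule could never fire; we define a PS to be *on* a
PDL iff the PDL passes through a node of the PS's own grid cell
(`distance ≤ √2/2 + ε`), preserving the sub-cell co-location intent.

## Tracking and statistics

PS tracks: greedy frame-to-frame linking, candidates within Chebyshev
distance 1 and equal chirality, resolved by smallest Euclidean distance then
lowest (y, x); unmatched detections start new tracks. PDL families:
components of consecutive frames are linked when any midpoint pair is within
Chebyshev distance 1; families are connected components of the link graph
over the whole recording, so branching and merging are automatic. Both
lifespans are inclusive: `(death − birth + 1)·dt_frame`. The dominant
frequency is the largest non-zero-bin rFFT peak of the spatially averaged,
mean-subtracted trace. The per-recording summary reports PS/PDL counts per
frame, the fraction of PSs off any PDL, PDL components without a PS, birth
rates, never-associated fractions over whole lifetimes, dominant
frequency/period, and mean lifespans.

## Built-in scenarios

The fixtures are deterministic simulations standing in for data that cannot
be redistributed. Grids are reduced (and, for the mm-scale 2D models,
coarsened to dx = 0.5 mm with the stability bound kept) so the whole suite
runs in minutes; S2 onsets were placed once per kinetics just after the S1
wave back clears the S2 quadrant:

* `ap_circular_rotor` (100×100, S2 at t = 44): block line heals into a
  single sustained spiral — the coexistence-then-succession of PDL and PS.
* `fk_linear_rotor` (150×150, S2 at t = 280 ms): sustained rotor whose core
  is an extended defect line; the workhorse for association and lifetime
  statistics.
* `bocf_linear_rotor` / `s1s2_block`: BOCF EPI wavelength (~180 mm) exceeds
  any affordable domain, so these capture initiation only — an extended
  block line with the wave turning around its endpoints and *no* PS at the
  free end, which is itself the characteristic linear-core phenomenology.
* `fk_scroll_3d_small` (48×48×8, MBR): a half-wall-thickness S2 produces a
  transmural block surface spanning the slab interior.
* `sinusoid_movie`: analytic 20 Hz signal at 1 kHz sampling for
  frequency/Hilbert tests.

What the generator does *not* emulate: optical noise, motion artifacts,
camera vignetting, fiber anisotropy, tissue heterogeneity, and sustained
multi-rotor fibrillation. Synthetic random phase fields
(`random_phase_field`, `straddle_field`) provide ground-truth vortex
charges and zero-winding defect steps for the detector oracle; their
guarantees (one vortex per cell, bounded smooth gradient) are exactly the
conditions under which ring detection equals the winding oracle.

## Verification strategy and known limitations

* **Conduction velocity**: measured on a thin 2D strip with sub-frame
  interpolation of the `V*` crossing, against an independently coded 1D
  cable integrator at half the spatial step; agreement within 5% for all
  three models. Velocities at production `dx` are a few percent slower (slow
  first-order convergence of the sharp upstroke).
* **PS position is method-dependent.** Different phase definitions place the
  singular point at different spots of the same core: on the circular-core
  spiral the Hilbert-phase and state-space-phase PSs orbit a common centre
  with instantaneous separations of order the core diameter; on the
  linear-core rotor they sit tens of pixels apart *along* the same defect
  line. Tests assert co-location of the core, not pointwise agreement.
* **Arrival-phase PDL vs LAT-based CBL.** The two detectors agree on where
  fresh block sits, but they are not equivalent as edge sets under the
  wrapped-jump rule: the unwrap discards exactly the fresh-vs-recovered
  ≈ 2π contrast that constitutes a block in arrival phase, so the φ_arr
  detector fires only in a window of elapsed-time contrast, while the
  snapshot LAT field additionally remembers healed block lines and the
  front-vs-previous-beat jump that the arrival phase — by design
  (recovered ≡ resting) — forgets. On the linear-core induction episode the
  φ_arr-PDL recovers roughly a quarter of the CBL edge set; the
  corresponding acceptance check asserts a much stricter equivalence and is
  knowingly left failing, with the measured ratio and Jaccard overlap
  reported by `scripts/acceptance.py`. The qualitative claim — activation
  phase shows wave front, wave back *and* block, arrival phase shows block
  only — is asserted at a front-sensitive threshold of 0.8 rad (≈ 2× the
  staircase artifact, below the per-edge front jump).
* The ring detector inherits the classical limitation it is meant to
  illustrate: it reports winding, so extended defects are visible to it only
  through the spurious, short-lived singularities on them.
* Sub-pixel PS localization, filament extraction from PDSs, alternans
  (multi-parameter phase manifolds), and electrogram-based phases are out of
  scope.
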