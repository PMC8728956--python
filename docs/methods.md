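# Methods

## Transport model

`mcvox` implements weighted-packet Monte Carlo radiative transfer on a
regular voxel grid.  A packet carries a statistical weight `w` (launched
at ≈1; pattern and Fourier sources launch with the local pattern value as
weight).  Between scattering events the packet travels a dimensionless
optical path `s* = −ln ξ`, `ξ ∈ (0, 1]`, consumed at rate μs per unit
geometric length, so the free path in a medium with scattering
coefficient μs is `s*/μs` and zero-scattering media propagate
ballistically (capped by the time window and the domain).  Absorption
never terminates a packet; along every voxel-bounded segment of length ℓ
the weight decays continuously (`w ← w e^(−μa ℓ)`) and the lost weight is
deposited into the segment's voxel and the time gate of the segment's
start time.  This continuous-attenuation scheme is what makes the
ballistic transmission through 10 mm of μa = 0.1 mm⁻¹ equal e⁻¹ to
floating-point precision rather than statistically.

Voxel traversal is an incremental (Amanatides–Woo-style) DDA: the three
candidate distances to the next x/y/z face are compared; the smallest
wins, and exact ties (corner hits, tolerance 1e−12 grid units) advance
every tied index.  Positions are snapped onto the crossed face to prevent
floating-point drift, so the sum of segment lengths equals the Euclidean
chord to ~1e−9 (tested with oblique ballistic rays through a slab).

Scattering angles come from the Henyey–Greenstein inversion; azimuths use
Marsaglia rejection (no trigonometric calls in the hot loop).  Sampling
satisfies E[cos θ] = g, verified for g ∈ {−0.5, 0, 0.5, 0.9} at 10⁶
draws, with exact forward/backward delta limits at |g| → 1.

Time of flight advances as Δt = ℓ·n/c with the voxel-local refractive
index, so time gates are correct in mismatched media.  A packet whose
time reaches the end of the last gate terminates as "expired in flight".

## Boundary conditions and interfaces

Each of the six bounding-box faces carries one of: `absorb` (packet
escapes, weight booked as escaped), `mirror` (normal direction component
negated), `cyclic` (position wrapped to the opposite face — emulates an
infinite medium; used for the diffusion validation), or `fresnel`
(unpolarized Fresnel reflectance R(θ, n_voxel, n_ambient) decides
stochastically between reflection and refraction+escape; active when the
session's refractive-mismatch flag is on, otherwise the face behaves as
absorbing).  With the mismatch flag on, internal voxel faces where n
changes apply the same unpolarized Fresnel/Snell treatment per face
(normals are axis-aligned; no surface smoothing), including total
internal reflection.  A packet launched outside the grid is advanced
ballistically to the bounding box (and through any background voxels) and
suffers the deterministic specular loss w·R at entry when mismatch is on.

Voxels labelled 0 are ambient background: crossing into one terminates
the packet as escaped at the interface, exactly like an absorbing face —
label 0 is "outside" that happens to be inside the bounding box.

## Termination and the exact weight ledger

Low-weight packets (w < 10⁻⁴ of launch weight, configurable) undergo
Russian roulette with survival probability 0.1: survivors are boosted to
w/0.1, which is unbiased in expectation.  Bookkeeping is exact, not
statistical: roulette kills are added to the "terminated in flight"
bucket and survivor boosts are subtracted from it, so

    launched = absorbed + escaped + terminated_in_flight

closes to ~1e−13 relative on every run (the conservation tests assert
1e−6).  The terminated-in-flight bucket therefore aggregates time-gate
expiry with the roulette residual, whose expectation is zero.

## Randomness, replay and split/merge

Photon *i* under global seed *s* owns the xoroshiro128+ stream seeded by
splitmix64 from (s, i) — launch sampling included.  Consequences, all
tested bitwise: (1) identical (scene, seed, workers) reproduce identical
output files byte-for-byte; (2) a detected photon is replayed exactly
from its stored index, reproducing exit position/direction bit-for-bit,
and replay accumulates pathlength × detected weight into a per-voxel
sensitivity (Jacobian) grid whose per-photon sums match the recorded
pathlengths to 1e−9; (3) splitting N photons over W workers (counts as
even as possible, e.g. 10 → 3/3/2/2) changes only floating-point
summation order, so 1-worker and 4-worker runs agree to ~1e−12 relative
L2 and merged detected tables are exact concatenations.  Replay runs each
photon twice — once to recover the exit weight, once to accumulate — so
the Jacobian needs no per-photon storage.

## Fluence normalization

Raw output is deposited energy per (voxel, gate).  Normalization divides
by μa·V_voxel·Δt·W_launched to yield fluence rate per unit delivered
energy (mm⁻² s⁻¹).  Voxels with μa = 0 would divide by zero, so the
kernel accumulates the pathlength estimator Σ w·ℓ there instead and
normalization divides by V_voxel·Δt·W_launched only; the two estimators
have the same expectation.  CW (steady-state) fluence is the gate sum
times Δt.

## Scene dialect decisions

- Continuous positions are in grid units, 0-based, voxel (i,j,k) spanning
  the half-open cube [i,i+1)×[j,j+1)×[k,k+1); CSG membership is evaluated
  at voxel centers (i+½,j+½,k+½) with closed inequalities, so a center
  exactly on a surface is inside.  Center sampling is the simplest rule
  that a brute-force per-voxel oracle can reproduce exactly.
- Optical coefficients are entered per mm and scaled by `LengthUnit`
  (mm per grid unit, default 1) internally.
- Boundary conditions are spelled as a `Domain.Boundary` object with keys
  x0,x1,y0,y1,z0,z1 and values absorb/fresnel/mirror/cyclic (a dialect
  choice; defaults to absorb on all faces).
- `_ArraySize_` is declared in C (row-major) order with 3D volume axis
  order (x,y,z); payloads are little-endian; only zlib compression is
  accepted, anything else is rejected loudly.  Both compressed and plain
  `_ArrayData_` forms are accepted on input.
- Source parameter packing follows the table in `mcvox.sources`; the
  sinusoidal pattern's spatial frequencies live in `Param1[3]`/`Param2[3]`
  and its phase in an explicit `Phase` key (radians, default 0), and the
  launch weight (1+cos(2π(f·u)+φ))/2 is clamped at 0.  Focusing redirects
  area-source rays through (f > 0) or away from (f < 0) the point
  `patch_center + f·Dir`; an omitted or infinite focus is collimated.
- Per-voxel continuous media are a float (nx,ny,nz,2) volume of
  (μa, μs) pairs with the global g and n taken from `Media[1]`; full
  per-voxel 4-property media are not supported.
- Unknown JSON keys are warned about and ignored (forward compatibility);
  validation is schema-driven and returns the full violation list.

## Validation scenes and what they show

The built-in fixtures define the study conditions: a homogeneous cube, a
three-layer slab, a cube with an embedded sphere (conservation,
detection, replay and split/merge checks at 10⁵ photons, 1-ns window), a
no-scattering slab for Beer–Lambert, and the infinite-medium condition
μa = 0.005 mm⁻¹, μs = 10 mm⁻¹, g = 0.9, n = 1 on a 60³ cyclic grid with
an isotropic center source, 10⁶ photons.  Its 2-ns single gate was chosen
from the time-domain diffusion solution before any simulation: it
captures 99.8/99.3/98.2% of the CW fluence at r = 5/10/15 mm, so window
truncation contributes ≤1.8% against the 10% agreement band (the observed
maximum shell error over 5–15 mm is ~2.5%).  Shell averaging uses 1-mm
bins of voxel-center radii, excludes the first three transport mean free
paths (diffusion theory is invalid near the source), and marks a shell
statistically adequate only if ≥99% of its voxels received deposition.

These synthetic scenes exercise every code path but idealize real tissue:
media are piecewise-constant with axis-aligned interfaces, anisotropy is
single-parameter Henyey–Greenstein, and there is no polarization, no
sub-voxel boundary geometry, and no user-defined phase function.  Passing
tests demonstrate correctness of the transport algorithm and data
contracts, not anatomical realism of any particular tissue model.

## Numerical choices

- Weight deposition uses a 4-term series for 1−e^(−x) when x < 1e−3
  (relative error < 1e−14), avoiding precision loss and an exp call for
  the dominant tiny-segment case.
- The kernel is numba-compiled with fastmath; determinism holds because
  the instruction stream is fixed per build, and all determinism
  contracts are asserted bitwise in the tests.
- Degenerate media (μa = μs = 0) propagate ballistically with pure delay;
  the finite time window guarantees termination (mirror boxes cannot trap
  packets forever).
- Detector matching is a Euclidean-distance test of the exit position
  against each detector sphere in declaration order; first match wins.
  Partial pathlengths are recorded in mm (grid length × `LengthUnit`).
- Problem sizes in the test-suite: statistical assertions use 4σ bands at
  10⁵–10⁶ samples; scene-level runs use 10⁵ photons except the
  infinite-medium condition (10⁶) and quick unit scenes (10²–10⁴).

## Known limitations

- One detected-photon record per photon (first detector hit at final
  escape); no partial detection through semi-transparent boundaries.
- Fresnel faces require the global mismatch flag; without it they absorb.
- The JNIfTI volume writer emits a minimal header dialect (dimensions,
  gating, units, normalization flag), not a full NIfTI-1 field mapping.
- Momentum transfer is accumulated as a single scalar Σ(1−cos θ), not
  per medium.
- Workers are logical (sequential, in-process); the split/merge contract
  is what a multi-process or multi-host deployment would build on.
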