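# Methods

## Model

The cercal segment is a right circular cone frustum. Defaults describe the
basal half of an adult cercus: axial length 5.2 mm, base diameter 0.54 mm,
tip diameter 0.26 mm. Its flattened (filet) representation — cut along the
medial lineage-restriction line and unrolled — is a trapezoid of height 1.7 mm
at the base tapering to 0.8 mm, consistent with the cone circumferences to
within 3% (the constructor warns, but does not fail, beyond that, so slightly
inconsistent measured geometries can still be represented). Surface
coordinates are `(axial, circum)`: axial position in mm from the base and a
signed circumferential fraction in (−1, 1], 0 on the lateral line, ±1 (one
physical line) on the medial line. The fractional distance from the medial
line used by the movement-direction field is `x = 1 − |circum|`.

Two fields define a cost over hair configurations:

**Spacing (morphogen S).** Steady-state diffusion with first-order decay from
a point source gives an exponentially decaying concentration, so a hair pair
at geodesic distance `r` contributes `exp(−r/λ)`. λ interpolates linearly
from 0.2 mm at the base to 0.4 mm at the segment end — roughly half the local
inter-hair spacing, which reproduces the observed basal-to-distal density
gradient. For a pair, λ is evaluated at the two hairs' mean axial coordinate,
which keeps the term symmetric; the field only specifies that λ varies along
the axis, and any symmetric convention agrees to first order.

**Movement direction (morphogen M).** Both restriction lines secrete the same
signal; with first-order decay the concentration is a two-source exponential
in `x`. It is min–max rescaled to `m(x) = (raw(x) − raw(1/2)) / (raw(0) −
raw(1/2))` so that `m = 1` on both lines and `m = 0` midway, and the
prescribed movement axis is `θ* = 90°·(1 − m)`, a smooth gradation from
longitudinal on the lines to transverse midway. The decay constant
`lambda_m` is expressed in fractional-distance units (default 0.25, placing
the transverse band over roughly the middle half of each compartment) and is
a configuration parameter, not a constant. High concentration thus prescribes
axes near 0°/±180°, low concentration axes near ±90°.

**Cost.** `E_i = Σ_{j≠i} exp(−r_ij/λ) + c1·(1 − a*·V_i)·|sin(θ_i − θ*)|`,
`E = Σ_i E_i`. Because |sin| is 180°-periodic, a single smooth formula covers
both the longitudinal and the transverse regime, and flipping a hair's
excitatory direction is free — the fields pattern movement planes, not
polarities. Each unordered pair appears in two `E_i`; the optimizer is
invariant to that constant factor of two, which only affects how `c1` is read
against the pair terms. `c1` multiplies the alignment term (default 10);
`a* = 0.1` discounts the alignment penalty for hairs at positive angles
(θ in (0°, 180°]) in the ventral circumferential half. Which half is ventral
is a parameter (`ventral_sign`, default +1), since the filet's orientation
convention is not fixed by the geometry.

**Search.** Greedy Monte Carlo. Initialization draws `n_hairs = 300`
positions uniformly per unit surface area (axial coordinate by inverse CDF of
the trapezoid height, circumferential fraction uniform) and directions
uniformly over (−180°, 180°]. Each of the `P = 10⁵` proposals redraws one
uniformly chosen hair's position from the same distribution (a global
redraw — the description of the algorithm gives no locality kernel) and adds
a rotation increment uniform over a full circle; a uniform increment is
distributionally identical to drawing a fresh uniform direction, so the two
readings of "randomly rotated" coincide. A move is accepted only if `E`
strictly decreases; ties are rejected. `P` counts proposals, not acceptances,
because acceptance counts vary by seed. All randomness flows from one
`numpy.random.Generator`; runs are bit-reproducible given the seed.

## Numerics

**Geodesics.** The production distance kernel is closed-form: unroll the cone
into a planar sector about its apex (a point at slant radius
`ρ = (x_apex − x)·sqrt(1 + (dr/dx)²)` and sector angle `sector_factor ×`
azimuth); the geodesic is the shorter chord over the two winding directions.
The numerical variant used by the original simulations is also provided: the
segment from `p` to `q` in (axial, unwrapped-fraction) parameter space is
split into 100 equal steps, embedded in 3-D, and chord lengths are summed,
again minimized over windings. On 200 random pairs the two agree to a worst
case of about 1e−3 relative — beyond the two-significant-digit target. The
step-refinement error is not monotone indefinitely: the polyline length
increases monotonically toward the length of the parameter-space path, which
itself exceeds the true geodesic by ~3e−4 relative, so the error falls from
coarse to moderate step counts and then plateaus at that excess. Whether the
discretization interpolates in fraction or arc-length space is not
determinable from the method description; both agree with the oracle well
inside the stated accuracy. The optimizer uses the closed form throughout:
10⁵ proposals × ~600 pair distances at 100 steps each would be three orders
of magnitude more work for no measurable difference.

**Inner loop.** The proposal loop is compiled with numba (single-threaded;
`parallel` would break seeded determinism). It duplicates the vectorized
numpy formulas, and the test suite pins the two paths together: the final
energy of every run is re-derived by full recomputation, and a 400-proposal
run on a small array is replayed move-for-move against a pure-Python loop
built from `propose` and `delta_cost_move`. Incremental energy changes
(`ΔE = Δangle + 2·Σ_j Δpair`) match brute-force recomputation to 1e−9
relative on 1000 random moves. Energies are tracked incrementally and logged
every 100 proposals; the trace is non-increasing by construction of the
acceptance rule.

**Ripley's L.** `K(s) = A·Σ_{i≠j} 1[r_ij < s] / (N(N−1))` with geodesic
distances, `A` the trapezoid area (6.5 mm²), no edge correction, and
`L = sqrt(K/π)`. Output tables carry both the window radius and the diameter
to avoid a factor-of-two trap — published curves are conventionally plotted
against diameter. Two geometric caveats bound the usable window range: the
axial ends are uncorrected (a small downward bias growing with `s`), and the
circumferential direction wraps, so once `s` exceeds about half the local
circumference (~0.6 mm) the search disc self-overlaps and even complete
spatial randomness falls well below the diagonal. Validation therefore uses
radii up to 0.75 mm (diameters to 1.5 mm): there, 50-fixture Poisson averages
stay within 10% of the diagonal, parent–offspring clusters sit clearly above
it, and optimized model output sits below it at diameters ≥ 1 mm.

**Histograms and peaks.** Direction histograms use 5° bins over
(−180°, 180°] (numpy half-open bin convention, right-closed at 180°). The
body-centric transform embeds each hair's movement direction as a unit
tangent to the cone, projects it onto the horizontal plane (the plane of the
cercus axis and both restriction lines), measures azimuth against the
unwrapped tip direction and subtracts the cercus rotation (default 30°).
Hairs whose tangent projects near-vertically (horizontal norm < 1e−6) are
excluded with a warning. On the lateral line the slant of the cone tilts the
axial tangent by ~1.5°, so the longitudinal anchors map to ≈ −31.5°/148.5°
rather than exactly −30°/150°. Peak counting smooths the circular histogram
with a centered 3-bin moving average and counts strict circular maxima with
prominence at least 5% of the hair count; both knobs are exposed because no
standard convention exists. Note that the prominence floor is deliberately
conservative: four von Mises modes of 75 hairs each at κ = 20 produce peak
bins of ~12 hairs and are *not* detected at the default floor of 15 — the
positive-control tests use either a sharper mixture (κ = 100) or an explicit
lower floor.

## Synthetic data

Three generators provide the fixtures the statistics are validated against,
all seeded and uniform-per-area in position: homogeneous Poisson (the null
for Ripley's L), parent–offspring clusters (Gaussian displacements of scale
`cluster_sd_mm`; the axial coordinate is reflected back into the segment so
the large-scale limit approaches uniformity, the circumferential coordinate
wraps), and von Mises direction mixtures (positive controls for peak
counting). These emulate only the spatial-statistical structure of hair
arrays — position and direction tables. They do not emulate measurement
error in socket positions, hair-length-dependent detection, the
clavate-patch exclusion zone near the baso-medial base, or left/right cercus
asymmetries, so tests passing on them validate the statistics and the
simulator, not agreement with any particular biological specimen.

## Design choices on open points

* The movement-field formula and the two piecewise conditions of the
  alignment cost are stated here in reconstructed form (two-source
  exponential, min–max rescaled, |sin| with θ* modulo 180°): the collapse of
  the piecewise high/low-concentration cases into one 180°-periodic formula
  is exact, and the reconstruction satisfies every qualitative constraint the
  fields must obey (exponential decay from both lines, longitudinal axes at
  high concentration, transverse at low).
* The ventral correction is applied to the alignment term only, the most
  literal reading of "reduced by 10% … for the hair deflection angle". See
  limitations below for its measured effect.
* `P` counts proposals; ties reject; relocation is a global redraw.
* Pair decay length at the pair's mean axial coordinate.
* "Positive angle" means θ ∈ (0°, 180°] in the flattened frame.
* Lengths are mm, angles degrees in (−180°, 180°], canonicalized after every
  rotation; circumferential fractions canonicalize to (−1, 1] with −1 ≡ +1.

## Known limitations

* The ventral discount as implemented biases density only weakly: as the
  search aligns hairs, the discounted alignment term vanishes, and with it
  the force that attracts hairs ventrally. Twenty-seed means of the
  ventral/dorsal ratio land near 1.02 (computed by `scripts/acceptance.py`
  and the test suite), far short of the ~1.22 measured in real cerci.
  Applying the discount to a hair's whole cost instead produces a much
  stronger, `P`-dependent excess (≈1.6 at the default `P`), overshooting the
  anatomical value; neither variant reproduces it, so the literal reading is
  kept and the discrepancy is reported rather than tuned away.
* The four characteristic body-frame direction peaks (≈ −120°, −30°, 60°,
  150°) are present in the transformed histograms, but the two longitudinal
  peaks collect only the thin bands where `m` is near 1, so their prominence
  (~5 hairs) sits below the default detection floor (15); the default
  `count_peaks` typically reports 1–2 peaks on a single default run. Any
  smooth exponential-family `m` combined with `θ* = 90°(1 − m)` has this
  property — the transverse band always dominates — so resolving it would
  require a qualitatively different (e.g. plateaued) movement field.
* No edge correction in Ripley's L; window radii above ~0.75 mm are not
  diagnostic on this geometry (see above).
* The full reaction–diffusion treatment of the morphogens, second-order
  degradation, clavate-patch exclusion, hair lengths/biomechanics and
  anisotropic-window Ripley variants are out of scope.
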