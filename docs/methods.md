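# Methods

## Mirror-symmetry density

Given a point set X on a pixel grid, the mirror-symmetry density assigns to
every grid point p the peak of its binned distance distribution to X:

    density(p) = max_b |{ q in X : bin(d(p, q)) = b }|

where d is either the Euclidean or the Manhattan grid metric and `bin`
rounds the distance to a configurable number of decimal places.  A value of
m at p means m input points are (to within the bin width) equidistant from
p — p lies on the perpendicular bisector of at least one pair when m >= 2,
and at a common center when m is large.  The continuous analogue is the
field of contour integrals of the input surface over circles centered at p;
the histogram is its discretization.  The computation is O(m·n) for m
domain pixels and n input points and is fully vectorized.

Conventions fixed across the package:

* coordinates are 0-based `(x=column, y=row)`, origin top-left;
* distances are in pixel units;
* rounding is half-away-from-zero, everywhere (distance binning, delay
  construction, midpoint rounding).  The tie rule itself is a free choice,
  but it must be *one* choice: the algorithm/network equivalence below is
  exact only because both paths share it.

### Options

| parameter | default | meaning |
|---|---|---|
| `metric` | euclidean | Manhattan keeps distances integral (digital hardware) and emphasizes horizontal/vertical/diagonal structure |
| `binning.decimals` | 1 | bin width 10^-decimals px; 0 matches whole-cycle network bins |
| `input_threshold` | 128 | strict > cutoff for point extraction from an 8-bit surface |
| `weighting` | binary | `pixel_value` accumulates source intensities instead of counts |
| `distance_limit` | none | drops contributions beyond an a-priori scale; the map is pointwise monotone non-decreasing in this limit |
| `distance_noise_sd` | none | i.i.d. Gaussian noise per point-pair distance (clamped at 0), relaxing coincidence so approximate symmetry becomes visible |

Self-distances (p coincides with an input point) contribute to the 0-bin;
this keeps the n-contributions-per-histogram invariant and cannot create
spurious maxima for non-degenerate inputs.  With `pixel_value` weighting the
weight is applied per contributing point (the algorithm iterates points,
not pairs); the pairwise average/minimum weighting described for spiking
long-run averages is not implemented.

## The spiking realization

The same map is computed by a single-layer leaky-integrate-and-fire (LIF)
network.  Input and output layers are the same grid; every input neuron i
is connected to every output neuron o through a delay line of

    L(i, o) = round(k · d(i, o)) + base        (cycles)

with speed factor k = 1 cycle/px and a base pipeline offset of 2 cycles on
every line.  All active inputs fire once, simultaneously.  A pulse injected
at cycle 0 arrives at o at cycle L(i, o), so the number of pulses arriving
at o within one clock cycle c equals the histogram count of bin c − base —
the per-cycle arrival maximum at o *is* density(o) with integer-cycle bins.
This equivalence is exact (bin-for-bin, pixel-for-pixel) and is asserted on
100 random point sets in the test suite.

The discrete accumulator update per cycle is:

    advance lines → sum arrivals → acc ← max(0, acc + A·arrivals − λ)
    → fire iff acc ≥ θ → acc ← 0 on fire

Defaults A = 1, θ = 1.5, λ = 0.5 make each output neuron a pairwise
coincidence detector with a strict same-cycle window: two simultaneous
arrivals reach 1.5 and fire; arrivals one cycle apart peak at 1.0.  An
m-fold detector uses θ = (m − 0.5)·A.  The continuous-time LIF equation
(voltage driven by input current with relaxation constant τ_m) is the model
this update discretizes; continuous integration is deliberately out of
scope.

Delay lines are realized two ways — bits marching through a shift register,
and (count, value) countdown registers — and the two representations are
tested observationally identical.  The network engine tracks in-flight
pulses as vectorized countdowns for speed.

With the 8×8 grid, Manhattan metric, k = 1 and base = 2 the network has
4096 delay lines of maximum length 14 + 2 = 16, and an input-to-output
latency of 16 plus 2 accumulation stages = 18 cycles.  The +2 base offset
is this package's reconstruction of the published maximum length (the
Manhattan diameter of an 8×8 grid alone is 14); it is configurable.

### Temporal summation caveat

A leaky accumulator whose threshold admits pair coincidence (2A − λ ≥ θ)
necessarily retains sub-threshold residue (A − λ > 0), so three or more
single arrivals in consecutive cycles can also fire a neuron.  The *firing*
set is therefore a superset of the {density ≥ 2} set in general; the two
coincide for two-point inputs (arrivals from only two lines can never chain).
The arrival-count map used for density read-out is unaffected.  This is why
the layered-composition equality below is stated for pair inputs and as a
superset property otherwise.

## Layering, feedback, and sets

Coincident output spikes form at different absolute times, so stacking
symmetry networks requires re-synchronization: a layer of slow-leak neurons
(leak_sync < λ, default 0 = perfect memory) stores each lower-layer fire
and releases all stored spikes simultaneously on a global timing pulse
(period ≥ lower-layer latency; shorter periods are rejected).  The released
set re-enters a second symmetry network (hierarchical mode) or is unioned
with the original input (recurrent mode).  Recurrent presentation k is
tested exactly equal to the k-th explicit iteration with feedback threshold
1.5 (i.e. density ≥ 2) on matched integer bins.

For two labeled sets A and B, a pseudorandom code per set perturbs
connection delays: one offset is drawn per *delay value* (not per
connection), uniform on [0, code_range] cycles, default code_range 4.
Same-set equidistant inputs share the offset and stay coincident; cross-set
pairs draw from independent codes and disperse.  Offsets are continuous
(sub-cycle): integer offsets indexed by delay value would leave a residual
1/(code_range+1) chance of accidental cross-set coincidence per pair,
whereas continuous offsets disperse with probability 1 and still cancel
exactly within a set.  The coded maps are computed by exact coincidence
counting on the perturbed arrival times; the inter-set map is the uncoded
combined map minus the intra-set map, clamped at zero (inhibitory
subtraction made deterministic).  Only pairwise set comparison is
implemented.

## Heuristic (GPU-style) variants

* **Bisector voting** — every unordered pair of above-threshold points
  increments the pixels of its rasterized perpendicular bisector.  The
  raster follows the exact bisector line through the true (possibly
  half-integer) midpoint, stepping one pixel along the dominant axis with
  nearest-pixel placement on the other; this bounds every raster pixel's
  equidistance error by |d1 − d2| ≤ 2 × 0.5 px = 1 px.  Pairs beyond the
  distance limit are skipped.
* **Randomized midpoints** — above-threshold points are scattered into a
  fixed-length slot array by K rounds of random indexing (a final
  sequential sweep fills any empty slot, guaranteeing the capacity
  invariant); N draws each pick two slots, skip identical points and
  over-limit pairs, and increment the rounded pair midpoint
  (half-away-from-zero per coordinate).  The map normalized by N converges
  to the exactly enumerable slot-multiplicity midpoint distribution; the
  suite checks total-variation distance < 0.05 at N = 10⁵.  Sequential
  semantics are the contract; the lock-free parallel variant's collision
  noise is out of scope.

The rounded midpoint can fall one pixel off the rasterized bisector when
the true midpoint is half-integer; it lies exactly on it when both midpoint
coordinates are integral (tested in both forms).

## Image pipeline

Per image: load (first channel of multi-channel inputs) → Sobel–Feldman
gradient magnitude (3×3 kernels, reflect padding; an interior step of
height h responds 4h) → threshold 128 → exact or heuristic density with a
50 px distance limit → overlay on a fixed 0–350 color scale → per-region
statistics.  Region membership is pixel-center-in-polygon (even-odd rule,
centers at integer coordinates); reported are per-region means, the pooled
mean over all regions, the image mean, and the fraction of regions (or, per
tile, whether the pooled mean) strictly exceeding the image mean.

## Synthetic data

The generators reproduce the *edge-geometry statistics* the method
consumes, not radiometry:

* outlines (circle, square, triangle, star, aircraft-like polygon, point
  pair) are binary 0/255 fields, made exactly mirror-symmetric about the
  vertical midline by construction (one half OR-ed with its reflection) and
  asserted so before any symmetry test;
* the triangle IFS applies the three half-scale vertex maps recursively
  (3^depth outlines), a multi-scale symmetry pattern for the
  distance-limit ladder (9/19/39/78 % of image size);
* synthetic tiles place non-overlapping axis-aligned bright-edged
  rectangles ("buildings", with matching closed polygon annotations) on a
  faint textured background with Poisson-placed irregular blobs
  ("clutter").  Buildings contribute many equidistant edge pairs; clutter
  few.  Defaults: 3 buildings, clutter rate 1.0 per 1000 px², 64 px tiles.

What passing tests on these fixtures do *not* show: performance on real
imagery (sensor noise, perspective, vegetation texture, building shape
diversity are not modeled), nor any specific numeric statistic on external
datasets.  The aircraft-like polygon is a synthetic stand-in constructed
for bilateral symmetry; absolute error magnitudes measured on it are not
comparable to any particular real silhouette, so the delay-noise study
asserts only the regime structure (MSE exactly 0 at sd 0; mean MSE rising
from sd 1 to sd 5).

## Problem sizes

Default test and verification sizes are chosen for sub-minute feedback:
equivalence on grids ≤ 12×12 (100 random point sets), the noise study on a
32 px outline with 20 seeds per level, the scale ladder on a 64 px depth-4
IFS, heuristic convergence at 10⁵ draws, and the tile statistic on fifty
64 px tiles at 3×10⁴ draws each.  All sizes scale up through the public
API unchanged.

## Known limitations

* Coincidence is exact-bin only: quasi-symmetry is reached through distance
  or delay noise, not through widened windows.
* Rotational, scaling and skew symmetry are out of scope.
* The physical energy bound (πħc/2d_p for array pitch d_p) is a utility
  calculation for the ultimate speed limit of any implementation; no
  hardware throughput is modeled.
* No learning; set codes are fixed per run.
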