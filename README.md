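# symspike

Mirror-symmetry density detection for 2-D raster data — computed two
provably equivalent ways: as an explicit distance-histogram algorithm, and
as a delay-encoded leaky-integrate-and-fire (LIF) spiking neural network
whose coincidence detectors read the same map out of arrival times.

**Who it is for.** People working on neuromorphic vision and symmetry
perception: the package shows, in runnable form, that a single layer of
spiking neurons with distance-proportional axonal delays is a mirror-symmetry
detector, and provides the surrounding tooling — heuristic GPU-style
variants, hierarchical and set-comparison extensions, an image pipeline,
and synthetic fixtures — to experiment with the idea without any hardware
or external data.

## The core quantity

For a point set X on a pixel grid, the symmetry density at a grid point p
is the peak of its binned distance distribution:

```
density(p) = max_b  #{ q ∈ X : bin(d(p, q)) = b }
```

Points equidistant from many input pairs (perpendicular bisectors, centers
of symmetric figures) score high.  In the spiking realization, every input
neuron connects to every output neuron through a delay line of
`round(k·d) + base` clock cycles; when all active inputs fire at once, the
largest number of pulses arriving at an output neuron within one clock
cycle equals `density` with whole-cycle bins.  The equivalence is exact and
is asserted bin-for-bin on random point sets in the test suite.

## Worked example

```python
import numpy as np
from symspike import (PointSet, DensityConfig, BinningSpec, Metric,
                      symmetry_density, build_symmetry_network,
                      run_symmetry, detect_symmetry)

# The four corners of a 9x9 grid.
pts = PointSet.from_points([(0, 0), (8, 0), (0, 8), (8, 8)])

# Explicit algorithm, whole-pixel distance bins.
dmap = symmetry_density(pts, (9, 9), DensityConfig(binning=BinningSpec(0)))
print(dmap.values.astype(int))

# Spiking network: same map from coincidence detection.
topo = build_symmetry_network(9, 9, Metric.EUCLIDEAN)
snn = detect_symmetry(run_symmetry(topo, pts))
print("identical:", np.array_equal(snn.values, dmap.values))
```

prints

```
[[2 1 1 2 2 2 1 1 2]
 [1 2 1 1 2 1 1 2 1]
 [1 1 2 1 2 1 2 1 1]
 [2 1 1 2 2 2 1 1 2]
 [2 2 2 2 4 2 2 2 2]
 [2 1 1 2 2 2 1 1 2]
 [1 1 2 1 2 1 2 1 1]
 [1 2 1 1 2 1 1 2 1]
 [2 1 1 2 2 2 1 1 2]]
identical: True
```

The center pixel scores 4 — all four corners are equidistant from it — and
the rows/columns/diagonals of pairwise bisectors score 2.  The spiking
network reproduces the map exactly.

## Command line

```bash
# make a synthetic satellite-like tile (PNG + building polygons as GeoJSON)
symspike fixtures make --kind synthetic_tile --size 64 --seed 1 --out tile.png

# run the pipeline: Sobel edges -> thresholded points -> symmetry density
symspike pipeline run --image tile.png --algorithm heuristic \
    --threshold 128 --dist-limit 50 --n 177828 --seed 1 \
    --regions tile.geojson --out results/
```

The run directory contains the density map (CSV and 16-bit PNG), an
overlay on a fixed 0–350 color scale, per-region statistics
(`region_id,region_mean,image_mean,exceeds`), and a JSON run log with the
full configuration.

## Package layout

| module | contents |
|---|---|
| `symspike.fields` | grid/point/field primitives, metrics, binning, the πħc/2d energy bound |
| `symspike.density` | the histogram algorithm: thresholds, weighting, distance limits, distance noise, iteration |
| `symspike.snn` | cycle-accurate LIF network, shift-register/countdown delay lines, delay noise |
| `symspike.sets` | synchronization layers, recurrent feedback, intra/inter-set maps via pseudorandom delay codes |
| `symspike.heuristic` | all-pairs bisector rasterization and the randomized-midpoint heuristic |
| `symspike.pipeline` | Sobel edges → density → overlays and region statistics |
| `symspike.fixtures` | outline/IFS/tile generators (all deterministic, all text-free) |

See `docs/methods.md` for the model, parameter meanings, numerical
choices, and limitations.

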