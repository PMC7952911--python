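"""Hierarchical (layered/recurrent) symmetry and intra/inter-set separation.

Layering: coincident output spikes of the base network arrive at different
absolute times depending on where they formed, so they cannot be fed
directly into a second symmetry network.  A synchronization layer of
slow-leaking neurons stores each fire and, on a global timing pulse,
releases all stored spikes simultaneously — restoring the synchronous
single-shot presentation the next network requires.  Stacking detects the
symmetry of symmetry points; feeding the released spikes back to the input
layer (an RNN) reproduces iterated application of the explicit algorithm.

Sets: to separate symmetry within a labeled set (intra-set) from symmetry
between two sets (inter-set), each set's connection delays are perturbed by
a pseudorandom code indexed by the delay value.  Equidistant points of the
same set receive identical perturbations and stay coincident; cross-set
pairs receive independent perturbations and their coincidence is dispersed.
Inter-set structure is then recovered by subtracting the intra-set map from
the combined (uncoded) map with inhibitory connections, clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import SymmetryDensityMap
from .fields import PointSet
from .snn import (
    LIFParams,
    SNNTopology,
    detect_symmetry,
    latency,
    run_symmetry,
)

__all__ = [
    "SyncLayerParams",
    "SetCode",
    "run_hierarchical",
    "run_recurrent",
    "intra_set_map",
    "inter_set_map",
]


@dataclass(frozen=True)
class SyncLayerParams:
    """Synchronization-layer neuron parameters.

    The sync layer must leak more slowly than the layer below it, so a
    stored spike survives until the timing pulse.  ``timing_period`` is the
    interval between global release pulses and must cover the lower
    network's latency; ``release_amplitude`` is the pulse each stored spike
    re-emits on release.
    """

    leak_sync: float = 0.0
    timing_period: int | None = None  # default: lower-layer latency + 1
    release_amplitude: float = 1.0

    def validated_against(self, lower: LIFParams) -> "SyncLayerParams":
        if self.leak_sync >= lower.leak:
            raise ValueError(
                "sync layer must leak more slowly than the layer below "
                f"(leak_sync={self.leak_sync} >= leak={lower.leak})")
        return self


def _fired_points(topology: SNNTopology, points: PointSet,
                  params: LIFParams, sync: SyncLayerParams) -> PointSet:
    """Run the lower network and return outputs stored by the sync layer.

    A sync neuron accumulates the lower layer's fires with a slow leak; a
    neuron holding any residual charge at the release pulse contributes a
    spike.  With the default zero sync leak this is exactly the set of
    output neurons that fired at least once within the presentation window.
    """
    sync.validated_against(params)
    period = sync.timing_period
    lat = latency(topology)
    if period is None:
        period = lat + 1
    if period < lat:
        raise ValueError(
            f"timing_period {period} below lower-layer latency {lat}: "
            "stored spikes would be released before all pulses land")
    trace = run_symmetry(topology, points, params, T=period)
    fires = trace.fires_array()  # (T, n_out) booleans
    # Sync accumulator: gains 1 per fire, leaks leak_sync per cycle after.
    T = fires.shape[0]
    cycles_left = (T - 1) - np.arange(T)[:, None]
    charge = np.maximum(0.0, 1.0 - sync.leak_sync * cycles_left)
    stored = (fires * charge).sum(axis=0) > 0.0
    idx = np.nonzero(stored)[0]
    coords = np.column_stack([idx % topology.width, idx // topology.width])
    return PointSet(coords)


def run_hierarchical(inputs: PointSet, topology: SNNTopology,
                     params: LIFParams | None = None,
                     sync: SyncLayerParams | None = None,
                     layers: int = 2) -> SymmetryDensityMap:
    """Stacked symmetry networks joined by synchronization layers.

    The lower network's fires are stored and released simultaneously into
    the next symmetry network; the top layer's coincidence map is returned
    (the symmetry points of symmetry points).
    """
    if layers < 1:
        raise ValueError("layers must be >= 1")
    params = params or LIFParams()
    sync = sync or SyncLayerParams()
    current = inputs
    for _ in range(layers - 1):
        current = _fired_points(topology, current, params, sync)
    if len(current) == 0:
        return detect_symmetry(run_symmetry(topology, current, params))
    return detect_symmetry(run_symmetry(topology, current, params))


def run_recurrent(inputs: PointSet, topology: SNNTopology, cycles: int = 1,
                  params: LIFParams | None = None,
                  sync: SyncLayerParams | None = None) -> SymmetryDensityMap:
    """Recurrent variant: released output spikes are fed back to the input.

    After each synchronized release the fired outputs are unioned with the
    original input pattern and re-presented; the k-th presentation's map is
    returned.  This reproduces iterated application of the explicit
    algorithm on the same bins.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    params = params or LIFParams()
    sync = sync or SyncLayerParams()
    current = inputs
    trace = run_symmetry(topology, current, params)
    for _ in range(cycles - 1):
        fired = _fired_points(topology, current, params, sync)
        current = inputs.union(fired)
        trace = run_symmetry(topology, current, params)
    return detect_symmetry(trace)


@dataclass(frozen=True)
class SetCode:
    """Pseudorandom per-delay-value code for one labeled set.

    One offset is drawn for each possible delay value of the topology
    (``"each distance value in the norm"``), uniformly on
    ``[0, code_range]`` in sub-cycle units.  Connections inherit the offset
    of their delay value, so equidistant same-set inputs stay exactly
    coincident while cross-set delay relationships are randomized.
    """

    seed: int
    code_range: float = 4.0

    def offsets(self, max_delay: int) -> np.ndarray:
        """Offset per delay value 0..max_delay, deterministic in the seed."""
        rng = np.random.default_rng(self.seed)
        return rng.uniform(0.0, self.code_range, size=max_delay + 1)


def _check_disjoint(setA: PointSet, setB: PointSet) -> None:
    if len(setA) == 0 or len(setB) == 0:
        return
    a = {tuple(p) for p in setA.coords}
    b = {tuple(p) for p in setB.coords}
    if a & b:
        raise ValueError(f"sets overlap at {sorted(a & b)}")


def _coded_arrivals(topology: SNNTopology, pts: PointSet,
                    offsets: np.ndarray | None) -> np.ndarray:
    """(n_points, n_out) arrival times, delay plus the delay-indexed offset."""
    idx = np.array([topology.neuron_index(int(x), int(y)) for x, y in pts.coords],
                   dtype=np.int64)
    delays = topology.delays[idx, :].astype(float)
    if offsets is not None:
        delays = delays + offsets[topology.delays[idx, :]]
    return delays


def _coincidence_map(topology: SNNTopology, arrival_blocks: list[np.ndarray]) -> SymmetryDensityMap:
    """Peak multiplicity of simultaneous arrivals per output neuron."""
    n_out = topology.n_out
    values = np.zeros(n_out)
    if arrival_blocks:
        times = np.vstack(arrival_blocks)  # (n_total, n_out)
        for o in range(n_out):
            _, counts = np.unique(times[:, o], return_counts=True)
            values[o] = counts.max() if counts.size else 0
    return SymmetryDensityMap(values.reshape(topology.height, topology.width))


def intra_set_map(setA: PointSet, setB: PointSet,
                  codes: tuple[SetCode, SetCode],
                  topology: SNNTopology,
                  params: LIFParams | None = None) -> SymmetryDensityMap:
    """Coincidence map with per-set pseudorandom delay codes applied.

    Within-set (A–A, B–B) coincidences are preserved exactly; cross-set
    (A–B) coincidences are dispersed.  With B empty the map equals the
    uncoded map for A, since a common offset per delay value cancels in
    every within-set coincidence.
    """
    _check_disjoint(setA, setB)
    codeA, codeB = codes
    md = topology.max_delay
    blocks = []
    if len(setA):
        blocks.append(_coded_arrivals(topology, setA, codeA.offsets(md)))
    if len(setB):
        blocks.append(_coded_arrivals(topology, setB, codeB.offsets(md)))
    return _coincidence_map(topology, blocks)


def union_map(setA: PointSet, setB: PointSet,
              topology: SNNTopology,
              params: LIFParams | None = None) -> SymmetryDensityMap:
    """Uncoded combined-input coincidence map (intra plus inter symmetry)."""
    blocks = []
    if len(setA):
        blocks.append(_coded_arrivals(topology, setA, None))
    if len(setB):
        blocks.append(_coded_arrivals(topology, setB, None))
    return _coincidence_map(topology, blocks)


def inter_set_map(setA: PointSet, setB: PointSet,
                  codes: tuple[SetCode, SetCode],
                  topology: SNNTopology,
                  params: LIFParams | None = None) -> SymmetryDensityMap:
    """Between-set symmetry: union map minus intra-set map, clamped at zero.

    Realizes the inhibitory connections from the intra-set network onto the
    combined network's outputs as an exact subtraction.
    """
    _check_disjoint(setA, setB)
    union = union_map(setA, setB, topology, params)
    intra = intra_set_map(setA, setB, codes, topology, params)
    return SymmetryDensityMap(np.maximum(0.0, union.values - intra.values))
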