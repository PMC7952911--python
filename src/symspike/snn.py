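"""Cycle-accurate leaky-integrate-and-fire network with delay-line coding.

Every input-grid neuron is connected to every output-grid neuron by a delay
line whose length is proportional to the grid distance between them.  When
all active inputs fire in the same cycle, the number of pulses arriving at
an output neuron within one clock cycle equals the number of inputs sharing
one binned distance to it — so a coincidence-detecting output layer computes
exactly the distance-histogram symmetry density, with whole clock cycles as
the distance bins.

The LIF accumulator follows the digital-logic discretization: each cycle
the arriving pulse amplitudes are summed into the accumulator, the leak is
subtracted, the result is clamped at zero, compared with the threshold, and
reset to zero on firing.  A threshold above a single pulse amplitude makes
each output neuron a coincidence detector.

Update order within a cycle (fixed so the two-pulse coincidence example is
exact): advance lines -> sum arrivals -> subtract leak -> clamp at 0 ->
compare with threshold -> reset on fire.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .density import SymmetryDensityMap
from .fields import Metric, PointSet, pairwise_distances, round_half_away

__all__ = [
    "LIFParams",
    "DelayLine",
    "SNNTopology",
    "SimulationTrace",
    "NetworkState",
    "build_symmetry_network",
    "latency",
    "add_delay_noise",
    "step",
    "run_symmetry",
    "detect_symmetry",
    "export_trace_csv",
]


@dataclass(frozen=True)
class LIFParams:
    """Discrete LIF neuron parameters.

    Defaults (A=1, theta=1.5, leak=0.5) give a strict one-cycle coincidence
    window for pulse pairs: two simultaneous arrivals reach 2*A - leak = 1.5
    and fire, while arrivals one cycle apart leave only A - leak = 0.5
    residual, short of threshold.  An m-fold coincidence detector uses
    theta = (m - 0.5)*A.
    """

    threshold: float = 1.5
    leak: float = 0.5
    pulse_amplitude: float = 1.0
    reset_on_fire: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= self.pulse_amplitude:
            raise ValueError("threshold must exceed a single pulse amplitude")
        if self.leak < 0:
            raise ValueError("leak must be non-negative")

    @property
    def min_coincidence(self) -> int:
        """Smallest number of simultaneous unit pulses that fires the neuron."""
        m = int(np.ceil((self.threshold + self.leak) / self.pulse_amplitude))
        return max(m, 1)


class DelayLine:
    """A fixed-latency pulse conduit of ``length`` clock cycles.

    Two observationally equivalent digital representations are provided:

    ``shift_register``
        values march through a register one slot per cycle (FIFO).
    ``countdown``
        each inserted value carries a countdown initialized to the length;
        counts decrement every cycle and the value emerges at zero.

    A value inserted at cycle t emerges from :meth:`tick` at cycle t+length
    under either representation.
    """

    def __init__(self, length: int, representation: str = "shift_register"):
        if length < 1:
            raise ValueError("delay line length must be >= 1")
        if representation not in ("shift_register", "countdown"):
            raise ValueError(f"unknown representation {representation!r}")
        self.length = int(length)
        self.representation = representation
        if representation == "shift_register":
            self._reg = deque([0.0] * self.length, maxlen=self.length)
        else:
            self._pending: list[list] = []  # [remaining, value]
        self._staged = 0.0

    def insert(self, value: float = 1.0) -> None:
        """Stage a value for entry at the next tick."""
        self._staged += value

    def tick(self) -> float:
        """Advance one clock cycle; return the value emerging (0 if none)."""
        if self.representation == "shift_register":
            out = self._reg.pop()
            self._reg.appendleft(self._staged)
            self._staged = 0.0
            return out
        out = 0.0
        survivors = []
        for item in self._pending:
            item[0] -= 1
            if item[0] == 0:
                out += item[1]
            else:
                survivors.append(item)
        self._pending = survivors
        # Staged values enter after the advance, so they first decrement on
        # the next tick and emerge exactly `length` ticks after insertion.
        if self._staged:
            self._pending.append([self.length, self._staged])
            self._staged = 0.0
        return out


@dataclass
class SNNTopology:
    """Fully connected delay-line wiring between an input and output grid.

    Delay rule: L(i, o) = round(k * distance(i, o)) + base, with the same
    half-away-from-zero rounding as distance binning, so the spiking network
    and the explicit algorithm agree bin-for-bin.  ``base`` is a fixed
    pipeline offset present on every line.
    """

    width: int
    height: int
    metric: Metric
    k: float  # cycles per pixel
    base: int  # pipeline offset, cycles
    delays: np.ndarray  # (n_in, n_out) integer line lengths

    @property
    def n_in(self) -> int:
        return self.width * self.height

    @property
    def n_out(self) -> int:
        return self.width * self.height

    @property
    def n_lines(self) -> int:
        return self.delays.size

    @property
    def max_delay(self) -> int:
        return int(self.delays.max())

    def neuron_index(self, x: int, y: int) -> int:
        return y * self.width + x


def build_symmetry_network(width: int, height: int,
                           metric: Metric = Metric.MANHATTAN,
                           k: float = 1.0, base: int = 2) -> SNNTopology:
    """Fully connect a width x height input grid to a same-size output grid."""
    if width < 1 or height < 1:
        raise ValueError("grid dimensions must be positive")
    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    grid = np.column_stack([xs.ravel(), ys.ravel()])
    dists = pairwise_distances(grid, grid, metric)
    delays = round_half_away(k * dists).astype(np.int64) + base
    return SNNTopology(width, height, metric, k, base, delays)


def latency(topology: SNNTopology, accumulation_stages: int = 2) -> int:
    """Input-to-output latency: longest line plus the accumulation stages."""
    return topology.max_delay + accumulation_stages


def add_delay_noise(topology: SNNTopology, sd: float, seed: int = 0) -> SNNTopology:
    """Perturb every line length with rounded Gaussian noise (floor: base)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return topology
    rng = np.random.default_rng(seed)
    noisy = round_half_away(topology.delays + rng.normal(0.0, sd, topology.delays.shape))
    noisy = np.maximum(noisy, topology.base).astype(np.int64)
    return SNNTopology(topology.width, topology.height, topology.metric,
                       topology.k, topology.base, noisy)


@dataclass
class SimulationTrace:
    """Per-cycle record of a network run.

    ``arrivals[t, o]`` counts pulses emerging at output neuron o in cycle t;
    ``acc`` and ``fires`` record accumulator values and firing events after
    the cycle's update; ``injections`` maps cycle -> input neuron indices.
    """

    width: int
    height: int
    arrivals: list = field(default_factory=list)   # one (n_out,) array per cycle
    acc: list = field(default_factory=list)
    fires: list = field(default_factory=list)
    injections: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.arrivals)

    def arrivals_array(self) -> np.ndarray:
        return np.array(self.arrivals) if self.arrivals else np.zeros((0, self.width * self.height))

    def fires_array(self) -> np.ndarray:
        return np.array(self.fires) if self.fires else np.zeros((0, self.width * self.height), dtype=bool)


class NetworkState:
    """Mutable simulation state: in-flight pulses, accumulators, trace.

    Pulses in flight are tracked as vectorized countdowns (one per occupied
    line), which is observationally identical to stepping every shift
    register (see :class:`DelayLine`) but lets a cycle be advanced with
    array operations.
    """

    def __init__(self, topology: SNNTopology, params: LIFParams | None = None):
        self.topology = topology
        self.params = params or LIFParams()
        self.cycle = 0
        self.acc = np.zeros(topology.n_out)
        self._pending_out = np.empty(0, dtype=np.int64)   # output index per pulse
        self._pending_left = np.empty(0, dtype=np.int64)  # cycles remaining
        self.trace = SimulationTrace(topology.width, topology.height)


def step(state: NetworkState, injected_spikes: np.ndarray | None = None) -> NetworkState:
    """Advance the network one clock cycle, injecting the given input spikes.

    ``injected_spikes`` is an array of input neuron indices that fire this
    cycle (each places one pulse on all of its outgoing lines; one pulse per
    cycle per line is enforced by single-shot injection).
    """
    topo, params = state.topology, state.params
    # (1) advance lines: a pulse inserted at cycle t emerges at cycle t+L,
    # so pulses injected below are not advanced until the next step.
    state._pending_left = state._pending_left - 1
    emerging = state._pending_left == 0
    # (2) sum arrivals
    arrivals = np.bincount(state._pending_out[emerging], minlength=topo.n_out).astype(float)
    state._pending_out = state._pending_out[~emerging]
    state._pending_left = state._pending_left[~emerging]

    if injected_spikes is not None and len(injected_spikes):
        injected_spikes = np.asarray(injected_spikes, dtype=np.int64)
        state.trace.injections[state.cycle] = injected_spikes.copy()
        # One pulse enters each line from every spiking input.
        new_out = np.tile(np.arange(topo.n_out), len(injected_spikes))
        new_left = topo.delays[injected_spikes, :].ravel()
        state._pending_out = np.concatenate([state._pending_out, new_out])
        state._pending_left = np.concatenate([state._pending_left, new_left])
    # (3) subtract leak, (4) clamp at 0
    state.acc = np.maximum(0.0, state.acc + params.pulse_amplitude * arrivals - params.leak)
    # (5) threshold, (6) reset on fire
    fires = state.acc >= params.threshold
    if params.reset_on_fire:
        state.acc = np.where(fires, 0.0, state.acc)

    state.trace.arrivals.append(arrivals)
    state.trace.acc.append(state.acc.copy())
    state.trace.fires.append(fires)
    state.cycle += 1
    return state


def run_symmetry(topology: SNNTopology, input_pattern: PointSet,
                 params: LIFParams | None = None,
                 T: int | None = None) -> SimulationTrace:
    """Present a pattern single-shot at cycle 0 and run for T cycles.

    All active input neurons fire simultaneously at cycle 0, one pulse per
    line.  T must cover the network latency so every pulse lands.
    """
    params = params or LIFParams()
    lat = latency(topology)
    if T is None:
        T = lat
    if T < lat:
        raise ValueError(f"horizon T={T} below network latency {lat}")
    state = NetworkState(topology, params)
    if len(input_pattern):
        idx = np.array([topology.neuron_index(int(x), int(y))
                        for x, y in input_pattern.coords], dtype=np.int64)
    else:
        idx = np.empty(0, dtype=np.int64)
    step(state, idx)
    for _ in range(T - 1):
        step(state)
    return state.trace


def detect_symmetry(trace: SimulationTrace) -> SymmetryDensityMap:
    """Map each output neuron to its peak single-cycle arrival count."""
    arr = trace.arrivals_array()
    if arr.shape[0] == 0:
        values = np.zeros((trace.height, trace.width))
    else:
        values = arr.max(axis=0).reshape(trace.height, trace.width)
    return SymmetryDensityMap(values)


def export_trace_csv(trace: SimulationTrace, path) -> None:
    """Event log: cycle, neuron_kind, neuron_x, neuron_y, event, value."""
    w = trace.width
    with open(path, "w") as fh:
        fh.write("cycle,neuron_kind,neuron_x,neuron_y,event,value\n")
        for cyc, idxs in sorted(trace.injections.items()):
            for i in idxs:
                fh.write(f"{cyc},input,{i % w},{i // w},inject,1\n")
        for cyc, (arr, fires) in enumerate(zip(trace.arrivals, trace.fires)):
            for o in np.nonzero(arr)[0]:
                fh.write(f"{cyc},output,{o % w},{o // w},arrive,{arr[o]:g}\n")
            for o in np.nonzero(fires)[0]:
                fh.write(f"{cyc},output,{o % w},{o // w},fire,1\n")
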