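"""Firing-rate simulation of small circuits.

Each node obeys the first-order rate equation

    dr_i/dt = (1/tau_i) * [ -r_i + g_i * phi_i( sum_j w_ji r_j + I_i(t) + b_i ) ]

with r_i the firing rate, tau_i the membrane time constant (seconds),
g_i the gain, w_ji the synaptic weight from node j to node i, I_i(t) the
external drive, b_i a baseline term and phi the activation function
(identity by default; tanh and relu available).  Integration is forward
Euler with a fixed step dt = t_max / n_steps; step inputs are applied on
the half-open interval [t_start, t_end).

The hierarchy sweep simulates a sequential chain of L feed-forward loops
(2L+1 nodes) under many independent uniform weight draws, with a step
input delivered to node 1 only, and summarizes each node's response by its
onset time and sustain metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .motifs import build_chain_template

ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "tanh": np.tanh,
    "relu": lambda x: np.maximum(x, 0.0),
}

#: Node parameters of the sequential-hierarchy sweep: uniform gain
#: g = 10^0.1 ~ 1.26, zero baseline, unit time constant, zero initial rate.
SWEEP_GAIN = 10 ** 0.1
SWEEP_TAU = 1.0
SWEEP_BASELINE = 0.0


@dataclass
class RateModelSpec:
    """Node parameters and weight matrix of a rate model.

    ``weights[j, i]`` is the synaptic weight from node j to node i
    (dimensionless); ``tau`` is in seconds.
    """

    node_ids: list
    tau: np.ndarray
    gain: np.ndarray
    baseline: np.ndarray
    weights: np.ndarray
    activation: str = "identity"
    initial_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        self.tau = np.broadcast_to(np.asarray(self.tau, float), (n,)).copy()
        self.gain = np.broadcast_to(np.asarray(self.gain, float), (n,)).copy()
        self.baseline = np.broadcast_to(np.asarray(self.baseline, float), (n,)).copy()
        self.weights = np.asarray(self.weights, float)
        if self.weights.shape != (n, n):
            raise ValueError("weights matrix must be square over node_ids")
        if (self.tau <= 0).any():
            raise ValueError("time constants must be positive")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.initial_rates is None:
            self.initial_rates = np.zeros(n)
        else:
            self.initial_rates = np.asarray(self.initial_rates, float).copy()
            if self.initial_rates.shape != (n,):
                raise ValueError("initial_rates length mismatch")

    def index(self, node_id) -> int:
        return self.node_ids.index(node_id)


@dataclass
class StepInput:
    """Rectangular external drive to one node on [t_start, t_end)."""

    node_id: object
    amplitude: float
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")


@dataclass
class Trajectory:
    """Simulated rate time courses: times (n_steps+1,), rates
    (n_steps+1, n_nodes)."""

    times: np.ndarray
    rates: np.ndarray
    node_ids: list

    def rate(self, node_id) -> np.ndarray:
        return self.rates[:, self.node_ids.index(node_id)]


@dataclass
class SweepConfig:
    """Sequential-hierarchy sweep conditions.

    Defaults follow the study conditions: chain of 3 FFLs (7 nodes), 1000
    independent weight draws from U(-1, 1), 30 s simulated in 1500 Euler
    steps, 2-s unit step input to node 1 starting at t = 2 s.
    """

    chain_length: int = 3
    n_iterations: int = 1000
    weight_low: float = -1.0
    weight_high: float = 1.0
    t_max: float = 30.0
    n_steps: int = 1500
    input_amplitude: float = 1.0
    input_start: float = 2.0
    input_end: float = 4.0
    activation: str = "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if not self.weight_low < self.weight_high:
            raise ValueError("weight_low must be below weight_high")


def simulate_rate(
    spec: RateModelSpec,
    inputs: Sequence[StepInput],
    t_max: float,
    n_steps: int,
) -> Trajectory:
    """Forward-Euler integration of the rate equations.

    dt = t_max / n_steps; the returned trajectory has n_steps+1 samples
    starting at the initial rates.  Raises on non-finite state
    (divergence), naming the offending step.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    n = len(spec.node_ids)
    dt = t_max / n_steps
    times = np.linspace(0.0, t_max, n_steps + 1)
    phi = ACTIVATIONS[spec.activation]
    idx = {node: k for k, node in enumerate(spec.node_ids)}

    drive = np.zeros((n_steps + 1, n))
    for inp in inputs:
        if inp.node_id not in idx:
            raise KeyError(f"unknown input node {inp.node_id!r}")
        mask = (times >= inp.t_start) & (times < inp.t_end)
        drive[mask, idx[inp.node_id]] += inp.amplitude

    rates = np.empty((n_steps + 1, n))
    rates[0] = spec.initial_rates
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n_steps):
            r = rates[k]
            total_in = r @ spec.weights + drive[k] + spec.baseline
            dr = (-r + spec.gain * phi(total_in)) / spec.tau
            rates[k + 1] = r + dt * dr
            if not np.isfinite(rates[k + 1]).all():
                raise RuntimeError(
                    f"rate model diverged at step {k + 1} (t={times[k + 1]:.3f} s)"
                )
    return Trajectory(times=times, rates=rates, node_ids=list(spec.node_ids))


def chain_spec(
    chain_length: int,
    weights: dict[tuple[int, int], float],
    gain: float = SWEEP_GAIN,
    tau: float = SWEEP_TAU,
    baseline: float = SWEEP_BASELINE,
    activation: str = "identity",
) -> RateModelSpec:
    """Rate-model spec on the sequential chain template with given edge
    weights (template labels 1..2L+1)."""
    template = build_chain_template(chain_length, "sequential")
    node_ids = list(template.node_ids)
    n = len(node_ids)
    w = np.zeros((n, n))
    for (u, v), weight in weights.items():
        if (u, v) not in template.edges:
            raise KeyError(f"({u},{v}) is not a template edge")
        w[node_ids.index(u), node_ids.index(v)] = weight
    return RateModelSpec(
        node_ids=node_ids,
        tau=tau,
        gain=gain,
        baseline=baseline,
        weights=w,
        activation=activation,
    )


def run_hierarchy_sweep(
    config: SweepConfig | None = None,
) -> tuple[list[dict[tuple[int, int], float]], list[Trajectory]]:
    """Simulate the sequential hierarchy under random weight draws.

    Per iteration, every template edge weight is drawn from
    U(weight_low, weight_high) on an iteration-specific substream of the
    seed; node parameters are fixed (tau=1 s, g=10^0.1, b=0, r(0)=0) and
    a step input of amplitude 1 drives node 1 on [2, 4) s.  Returns the
    drawn weight sets and the trajectories, in iteration order.
    """
    config = config or SweepConfig()
    template = build_chain_template(config.chain_length, "sequential")
    edges = sorted(template.edges)
    inputs = [
        StepInput(
            node_id=1,
            amplitude=config.input_amplitude,
            t_start=config.input_start,
            t_end=config.input_end,
        )
    ]
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_iterations)
    weight_sets = []
    trajectories = []
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        draws = rng.uniform(config.weight_low, config.weight_high, size=len(edges))
        weights = dict(zip(edges, draws.tolist()))
        spec = chain_spec(
            config.chain_length, weights, activation=config.activation
        )
        trajectories.append(
            simulate_rate(spec, inputs, t_max=config.t_max, n_steps=config.n_steps)
        )
        weight_sets.append(weights)
    return weight_sets, trajectories


def onset_time(
    trajectory: Trajectory, node_id, threshold_fraction: float = 0.05
) -> float | None:
    """First time |r(t) - r(0)| exceeds threshold_fraction * peak deviation.

    None for a flat trace.  threshold_fraction = 0 returns the first sample
    where the trace departs from r(0) at all.
    """
    r = trajectory.rate(node_id)
    dev = np.abs(r - r[0])
    peak = dev.max()
    if peak == 0:
        return None
    above = np.nonzero(dev > threshold_fraction * peak)[0]
    if above.size == 0:
        return None
    return float(trajectory.times[above[0]])


def sustain_metrics(trajectory: Trajectory, node_id) -> tuple[float, float]:
    """(time above half-peak deviation, final deviation as fraction of peak).

    Zeros for a flat trace.
    """
    r = trajectory.rate(node_id)
    dev = np.abs(r - r[0])
    peak = dev.max()
    if peak == 0:
        return 0.0, 0.0
    dt = trajectory.times[1] - trajectory.times[0]
    time_above = float((dev >= 0.5 * peak).sum() * dt)
    return time_above, float(dev[-1] / peak)
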