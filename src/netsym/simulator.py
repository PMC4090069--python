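"""Leaky integrate-and-fire network with escape noise and triplet STDP.

The case-study network: ``N`` leaky integrate-and-fire neurons, all-to-all
plastic excitatory connections (row = postsynaptic, column = presynaptic),
driven by one of two external stimulation protocols.  Weights evolve under
the triplet spike-timing-dependent plasticity rule and the symmetry measure
of the weight matrix is recorded over time: a *frequency* protocol (each
neuron driven at a different rate) pushes the network toward reciprocal,
symmetric connectivity, while a *sequential* protocol (neurons driven in a
fixed temporal order) carves one-way, asymmetric connectivity.

Model components
----------------
Membrane:  ``tau_m dV/dt = -(V - V_rest) + R I(t)``, integrated with the
exact per-step decay factor ``exp(-dt/tau_m)``; synaptic input delivers an
impulse ``J_syn * w_ij`` per presynaptic spike of neuron ``j`` (after a
one-step conduction delay), external events deliver ``J_ext`` (30 mV, enough
to force a spike from rest).  After a spike the potential resets to
``V_rest``.

Escape noise:  instead of a deterministic threshold, each step the neuron
fires with probability ``P = 1 - exp(-dt * rho(V))`` where
``rho(V) = escape_rate_scale * exp((V - V_theta)/escape_sensitivity)`` — an
exponential escape rate, negligible deep below threshold and near-certain
after an external kick.

Triplet STDP:  each neuron carries two presynaptic traces ``r1, r2`` (fast /
slow) and two postsynaptic traces ``o1, o2``; all decay exponentially and are
set on the neuron's own spikes.  When neuron ``k`` fires, its incoming
weights potentiate, ``w_kj += eta * r1_j * (A2p + A3p * o2_k^-)``, and its
outgoing weights depress, ``w_jk -= eta * o1_j * (A2m + A3m * r2_k^-)``,
where the ``^-`` traces are read *before* the increment caused by this very
spike.  Weights are clipped to ``[w_min, w_max]`` and pruned entries (mask
fixed before learning) stay zero throughout.

The amplitude constants default to the published nearest-spike triplet-model
parameter set fitted to visual-cortex data; with that set the trace update on
a spike is reset-to-1 ("nearest spike"), which is the default here (the
accumulative "+1" variant is available via ``trace_increment='add'``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from netsym.core import WeightMatrix, symmetry_measure
from netsym.null_stats import ConfigurationError, NullModelSpec
from netsym.generators import apply_pruning, random_network


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of the spiking-network case study.

    Units: time in ms, potentials in mV, rates in Hz.  Defaults follow the
    case-study parameter table (membrane and STDP constants) with the
    protocol constants documented in the methods note.
    """

    n_neurons: int = 30
    tau_m: float = 10.0           # membrane time constant (ms)
    R: float = 1.0                # membrane resistance (input already in mV)
    V_rest: float = -70.0         # resting and reset potential (mV)
    V_theta: float = -50.0        # firing threshold (mV)
    J_syn: float = 1.0            # voltage jump per presynaptic event, per unit weight (mV)
    J_ext: float = 30.0           # voltage jump per external event (mV)
    dt: float = 1.0               # time step (ms)
    delay_steps: int = 1          # synaptic conduction delay (steps)
    # escape noise: rho(V) = escape_rate_scale * exp((V - V_theta)/escape_sensitivity)
    escape_rate_scale: float = 1.0    # 1/ms
    escape_sensitivity: float = 2.0   # mV
    # triplet STDP (nearest-spike, visual-cortex parameter set)
    tau_r1: float = 16.8
    tau_r2: float = 575.0
    tau_o1: float = 33.7
    tau_o2: float = 47.0
    A2_plus: float = 4.6e-3
    A3_plus: float = 9.1e-3
    A2_minus: float = 3.0e-3
    A3_minus: float = 7.5e-9
    learning_rate: Optional[float] = None   # None -> per-protocol default
    trace_increment: str = "reset"          # "reset" (nearest-spike) | "add"
    w_min: float = 0.0
    w_max: float = 1.0
    # initial weights
    init_family: str = "uniform"            # uniform | gaussian
    init_mu: float = 0.5
    init_sigma: float = 0.1                 # variance 0.01
    prune_p: float = 0.0
    # protocol
    protocol: str = "frequency"             # frequency | sequential
    rate_min_hz: float = 15.0               # frequency protocol: slowest neuron
    rate_max_hz: float = 30.0               # frequency protocol: fastest neuron
    seq_delay_ms: float = 20.0              # sequential protocol: inter-neuron delay
    jitter_frac: float = 0.05               # jitter SD as fraction of period/delay
    duration_ms: float = 200_000.0
    record_interval_ms: float = 1000.0
    n_repeats: int = 50                     # independent repetitions of the experiment

    #: per-protocol learning-rate defaults, used when learning_rate is None
    _ETA_DEFAULTS = {"frequency": 1.0, "sequential": 0.5}

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ConfigurationError("need at least 2 neurons")
        for name in ("tau_m", "dt", "duration_ms", "record_interval_ms",
                     "tau_r1", "tau_r2", "tau_o1", "tau_o2"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.V_rest >= self.V_theta:
            raise ConfigurationError("V_rest must be below V_theta")
        if self.escape_sensitivity <= 0:
            raise ConfigurationError("escape_sensitivity must be positive")
        if self.escape_rate_scale <= 0:
            raise ConfigurationError("escape_rate_scale must be positive")
        if self.w_min >= self.w_max:
            raise ConfigurationError("w_bounds must be ordered")
        if self.trace_increment not in ("reset", "add"):
            raise ConfigurationError("trace_increment must be 'reset' or 'add'")
        if self.protocol not in ("frequency", "sequential"):
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        if self.protocol == "frequency" and not 0 < self.rate_min_hz <= self.rate_max_hz:
            raise ConfigurationError("rates must satisfy 0 < rate_min <= rate_max")
        if self.protocol == "sequential" and self.seq_delay_ms <= 0:
            raise ConfigurationError("sequential inter-neuron delay must be positive")
        if self.jitter_frac < 0:
            raise ConfigurationError("jitter_frac must be non-negative")
        if not 0.0 <= self.prune_p < 1.0:
            raise ConfigurationError("prune_p must be in [0, 1)")
        if self.delay_steps < 1:
            raise ConfigurationError("delay_steps must be at least 1")

    @property
    def eta(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return self._ETA_DEFAULTS[self.protocol]

    def init_spec(self) -> NullModelSpec:
        return NullModelSpec(
            family=self.init_family, w_min=self.w_min, w_max=self.w_max,
            mu=self.init_mu, sigma=self.init_sigma, prune_p=self.prune_p,
        )


@dataclass
class SimulationResult:
    """Trajectory of the symmetry measure plus final network state."""

    times_ms: np.ndarray            # recording times
    s_trajectory: np.ndarray        # s at each recording time
    final_weights: WeightMatrix
    initial_weights: WeightMatrix
    spike_times: List[np.ndarray]   # per neuron, ms
    seed: int
    config: SimulationConfig

    @property
    def s_initial(self) -> float:
        return float(self.s_trajectory[0])

    @property
    def s_final(self) -> float:
        return float(self.s_trajectory[-1])


def fire_probability(V: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Per-step escape-noise firing probability, nondecreasing in V."""
    rate = config.escape_rate_scale * np.exp(
        (np.asarray(V, dtype=float) - config.V_theta) / config.escape_sensitivity
    )
    return -np.expm1(-config.dt * rate)


def frequency_protocol(
    config: SimulationConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[np.ndarray]:
    """Per-neuron external event times: each neuron at its own rate.

    Rates are evenly spaced between ``rate_min_hz`` and ``rate_max_hz`` across
    neurons; events are periodic with zero-mean Gaussian jitter of standard
    deviation ``jitter_frac`` times the neuron's period.
    """
    g = rng if rng is not None else np.random.default_rng(seed)
    n = config.n_neurons
    rates = np.linspace(config.rate_min_hz, config.rate_max_hz, n)
    trains = []
    for r in rates:
        if r <= 0:
            raise ConfigurationError("rates must be positive")
        period = 1000.0 / r
        base = np.arange(period, config.duration_ms, period)
        t = base + g.normal(0.0, config.jitter_frac * period, size=base.size)
        t = np.sort(t[(t >= 0) & (t < config.duration_ms)])
        trains.append(t)
    return trains

def sequential_protocol(
    config: SimulationConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[np.ndarray]:
    """Per-neuron external event times: neurons driven in a fixed order.

    Neuron ``i`` receives events at ``i*d + c*N*d`` for cycles ``c``
    (inter-neuron delay ``d = seq_delay_ms``), jittered with SD
    ``jitter_frac * d``; every neuron gets the same number of events per
    cycle.
    """
    g = rng if rng is not None else np.random.default_rng(seed)
    n = config.n_neurons
    d = config.seq_delay_ms
    cycle = n * d
    n_cycles = int(config.duration_ms // cycle)
    trains = []
    for i in range(n):
        base = i * d + cycle * np.arange(n_cycles)
        t = base + g.normal(0.0, config.jitter_frac * d, size=base.size)
        t = np.sort(t[(t >= 0) & (t < config.duration_ms)])
        trains.append(t)
    return trains


def _external_events(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_steps, N) int array of external event counts per step."""
    if config.protocol == "frequency":
        trains = frequency_protocol(config, rng=rng)
    else:
        trains = sequential_protocol(config, rng=rng)
    n_steps = int(round(config.duration_ms / config.dt))
    ev = np.zeros((n_steps, config.n_neurons), dtype=np.int8)
    for i, t in enumerate(trains):
        steps = np.floor(t / config.dt).astype(int)
        steps = steps[(steps >= 0) & (steps < n_steps)]
        np.add.at(ev[:, i], steps, 1)
    return ev


def initial_weights(
    config: SimulationConfig, seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[WeightMatrix, np.ndarray]:
    """Initial random weights and the fixed pruning mask (True = removed)."""
    g = rng if rng is not None else np.random.default_rng(seed)
    spec = replace(config.init_spec(), prune_p=0.0)
    W = random_network(config.n_neurons, spec, rng=g)
    if config.prune_p > 0.0:
        W, mask = apply_pruning(W, config.prune_p, rng=g)
    else:
        mask = np.zeros((config.n_neurons,) * 2, dtype=bool)
        np.fill_diagonal(mask, True)
    return W, mask


def run_simulation(config: SimulationConfig, seed: int) -> SimulationResult:
    """Run the full case study for one seed and record the s trajectory.

    Step order (fixed dt): decay traces and membrane -> deliver delayed
    synaptic impulses and external events -> stochastic firing via the escape
    rate -> triplet STDP using pre-increment traces -> reset fired membranes
    and set traces.  Pruning (if any) is applied to the initial weights
    before learning and the mask is held fixed.  Fully reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    n = config.n_neurons
    dt = config.dt
    n_steps = int(round(config.duration_ms / dt))
    record_every = max(1, int(round(config.record_interval_ms / dt)))

    W0, mask = initial_weights(config, rng=rng)
    W = W0.weights.copy()
    alive = ~mask
    ext = _external_events(config, rng)

    V = np.full(n, config.V_rest)
    r1 = np.zeros(n)
    r2 = np.zeros(n)
    o1 = np.zeros(n)
    o2 = np.zeros(n)

    dm = math.exp(-dt / config.tau_m)
    d_r1 = math.exp(-dt / config.tau_r1)
    d_r2 = math.exp(-dt / config.tau_r2)
    d_o1 = math.exp(-dt / config.tau_o1)
    d_o2 = math.exp(-dt / config.tau_o2)

    eta = config.eta
    # ring buffer of recent spike vectors for the conduction delay
    buffer = [np.zeros(n, dtype=bool) for _ in range(config.delay_steps)]
    buf_pos = 0

    spike_times: List[list] = [[] for _ in range(n)]
    rec_times = [0.0]
    s_traj = [symmetry_measure(W0).s]

    for step in range(n_steps):
        # exact exponential decays
        r1 *= d_r1
        r2 *= d_r2
        o1 *= d_o1
        o2 *= d_o2
        V = config.V_rest + (V - config.V_rest) * dm
        # delayed synaptic impulses
        delayed = buffer[buf_pos]
        if delayed.any():
            V += config.J_syn * config.R * (W @ delayed)
        e = ext[step]
        if e.any():
            V += config.J_ext * config.R * e
        # escape-noise firing
        prob = fire_probability(V, config)
        spikes = rng.random(n) < prob
        if spikes.any():
            ks = np.flatnonzero(spikes)
            # STDP with pre-increment traces (read before the spike updates them)
            for k in ks:
                ltp = eta * r1 * (config.A2_plus + config.A3_plus * o2[k])
                W[k, :] += np.where(alive[k, :], ltp, 0.0)
                ltd = eta * o1 * (config.A2_minus + config.A3_minus * r2[k])
                W[:, k] -= np.where(alive[:, k], ltd, 0.0)
            np.clip(W, config.w_min, config.w_max, out=W)
            W[mask] = 0.0
            V[spikes] = config.V_rest
            if config.trace_increment == "reset":
                r1[spikes] = 1.0
                r2[spikes] = 1.0
                o1[spikes] = 1.0
                o2[spikes] = 1.0
            else:
                r1[spikes] += 1.0
                r2[spikes] += 1.0
                o1[spikes] += 1.0
                o2[spikes] += 1.0
            t_now = (step + 1) * dt
            for k in ks:
                spike_times[k].append(t_now)
        buffer[buf_pos] = spikes
        buf_pos = (buf_pos + 1) % config.delay_steps
        if (step + 1) % record_every == 0:
            rec_times.append((step + 1) * dt)
            s_traj.append(symmetry_measure(W).s)

    return SimulationResult(
        times_ms=np.asarray(rec_times),
        s_trajectory=np.asarray(s_traj),
        final_weights=WeightMatrix(weights=W.copy(), w_max=config.w_max),
        initial_weights=W0,
        spike_times=[np.asarray(t) for t in spike_times],
        seed=seed,
        config=config,
    )
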