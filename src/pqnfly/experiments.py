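"""End-to-end experiments: simulation drivers and the published analyses.

Provides the network assembly helper plus the analyses performed on the
recordings: virtual local field potentials (class-mean synaptic current),
Welch power spectra with band-limited peak extraction, tumbling-window
firing-rate time courses, the oscillation (peak-power) experiment with
LN-subclass inactivation, and the olfactory associative-learning experiment
with its success-rate readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .engine import Network, Recorder, SimulationEngine, SimulationRecording
from .presets import default_params, default_scaling
from .stimulus import (
    SIX_ODORANTS,
    ORResponseTable,
    StimulusProtocol,
    build_protocol,
    generate_synthetic_or_table,
)
from .topology import SynthTopologyConfig, generate_synthetic_topology

__all__ = [
    "LFPTrace",
    "PowerSpectrum",
    "LearningOutcome",
    "build_default_network",
    "run_simulation",
    "virtual_lfp",
    "power_spectrum",
    "firing_frequency",
    "peak_power_experiment",
    "run_learning_experiment",
    "is_trial_success",
]

#: analysis band (Hz) for oscillation peaks
PEAK_BAND = (5.0, 100.0)

#: reward follows odor onset by 3 s (odor at 300 s, reward at 304 s with the
#: 1-s presentation ending at 301 s)
REWARD_LATENCY_S = 3.0


def build_default_network(
    topo_cfg: SynthTopologyConfig | None = None,
    seed: int = 0,
    params=None,
    scaling=None,
    or_table: ORResponseTable | None = None,
    odorants=SIX_ODORANTS,
    or_sparsity: float = 0.25,
) -> Network:
    """Assemble a runnable synthetic network.

    Topology, OR tuning table and OR assignment all derive from one seeded
    generator, so the same seed yields the same circuit.  ORNs of the same
    glomerulus share a receptor (one OR per glomerulus in the synthetic
    map, mirroring the one-glomerulus-per-OR organisation).
    """
    rng = np.random.default_rng(seed)
    topo_cfg = topo_cfg or SynthTopologyConfig()
    neurons, weights = generate_synthetic_topology(topo_cfg, rng)
    if or_table is None:
        or_table = generate_synthetic_or_table(
            topo_cfg.n_glomeruli, odorants, sparsity=or_sparsity, rng=rng
        )
    # one OR per glomerulus: glomerulus i -> OR i
    gloms = neurons.df.loc[neurons.df["class"] == "ORN", "glomerulus"]
    uniq = sorted(gloms.unique())
    or_of_glom = {g: or_table.r.index[i % len(or_table.r)] for i, g in enumerate(uniq)}
    or_types = gloms.map(or_of_glom).to_numpy()
    return Network(
        neurons=neurons,
        weights=weights,
        params=params or default_params(),
        scaling=scaling or default_scaling(),
        or_table=or_table,
        or_types=or_types,
    )


def run_simulation(
    net: Network,
    protocol: StimulusProtocol,
    duration: float | None = None,
    seed: int = 0,
    inactivate=(),
    recorder: Recorder | None = None,
    reward_times=(),
    dt: float = 1e-3,
    quantizer=None,
    engine: SimulationEngine | None = None,
) -> SimulationRecording:
    """One-shot run from t = 0 (or continue a supplied engine).

    ``inactivate`` lists classes or LN subclasses whose accumulated stimulus
    input is forced to zero each step.
    """
    if engine is None:
        engine = SimulationEngine(net, dt=dt, seed=seed, quantizer=quantizer,
                                  inactivate=inactivate)
    if duration is None:
        duration = protocol.horizon - engine.t
    return engine.run(duration, protocol, recorder=recorder,
                      reward_times=reward_times)


# ---------------------------------------------------------------------------
# LFP and spectra


@dataclass
class LFPTrace:
    """Virtual LFP: the mean synaptic current over one neuron group."""

    group: str
    t: np.ndarray
    lfp: np.ndarray
    fs: float


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray
    peak_freq: float
    peak_power: float
    band: tuple[float, float] = PEAK_BAND


def virtual_lfp(rec: SimulationRecording, group: str) -> LFPTrace:
    """Mean synaptic current of a recorded class (or LN subclass)."""
    if group not in rec.lfp:
        raise KeyError(
            f"group {group!r} was not recorded; available: {sorted(rec.lfp)}"
        )
    return LFPTrace(group=group, t=rec.t, lfp=rec.lfp[group], fs=1.0 / rec.dt)


def power_spectrum(
    lfp, fs: float | None = None, band: tuple[float, float] = PEAK_BAND,
    nperseg_s: float = 1.0,
) -> PowerSpectrum:
    """Mean-removed Welch estimate with band-limited peak extraction.

    1-s Hann segments with 50% overlap resolve 20–30 Hz peaks over a 10-s
    odor window; the peak is taken over ``band`` (default 5–100 Hz).
    """
    if isinstance(lfp, LFPTrace):
        x, fs = lfp.lfp, lfp.fs
    else:
        x = np.asarray(lfp, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a plain array")
    nperseg = int(round(nperseg_s * fs))
    if len(x) < nperseg:
        raise ValueError(
            f"window of {len(x)} samples is shorter than one {nperseg}-sample segment"
        )
    freqs, power = scipy.signal.welch(
        x - x.mean(), fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    sel = (freqs >= band[0]) & (freqs <= band[1])
    k = int(np.argmax(power[sel]))
    return PowerSpectrum(
        freqs=freqs, power=power,
        peak_freq=float(freqs[sel][k]), peak_power=float(power[sel][k]),
        band=band,
    )


def firing_frequency(
    spike_times, t0: float, t1: float, window: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Firing-rate time course over tumbling windows (default 50 ms).

    Returns (window centres, rate in Hz).  ``spike_times`` may be a single
    array or a list of arrays (trials), in which case rates are averaged
    over trials.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    edges = np.arange(t0, t1 + window / 2, window)
    centres = edges[:-1] + window / 2
    trials = spike_times if isinstance(spike_times, (list, tuple)) else [spike_times]
    rates = np.zeros((len(trials), len(centres)))
    for i, st in enumerate(trials):
        counts, _ = np.histogram(np.asarray(st), bins=edges)
        rates[i] = counts / window
    return centres, rates.mean(axis=0)


# ---------------------------------------------------------------------------
# Oscillation experiment


def peak_power_experiment(
    net: Network,
    odorant: str = SIX_ODORANTS[0],
    n_repeats: int = 20,
    groups=("PN", "LN", "KC"),
    inactivate=(),
    seed: int = 0,
    warmup: float = 300.0,
    no_odor: bool = False,
    dt: float = 1e-3,
    engine_state=None,
    net_engine=None,
) -> dict[str, dict]:
    """Average band peak power of class LFPs over repeated 10-s presentations.

    A single homeostatic warm-up (protocol-1 cycling of the six-odor panel)
    is run once; every repeat branches from that state with a fresh spike
    seed and a 10-s presentation of ``odorant`` (protocol 2), or a blank
    window for the ``no_odor`` control.  Returns, per group, the mean and sd
    of peak power and the mean peak frequency.
    """
    protocol = build_protocol(2, [odorant], warmup=warmup,
                              warmup_panel=SIX_ODORANTS)
    engine = net_engine
    if engine is None:
        engine = SimulationEngine(net, dt=dt, seed=seed, inactivate=inactivate)
        engine.run(warmup, protocol)
    state = engine_state or engine.checkpoint()

    rec_sel = Recorder(lfp_groups=groups, record_spikes=False)
    onset = engine.t
    results: dict[str, dict] = {g: {"peaks": [], "freqs": []} for g in groups}
    for rep in range(n_repeats):
        engine.restore(state)
        engine.set_inactivated(inactivate)
        engine.reseed(seed + 1000 + rep)
        if no_odor:
            run_proto = StimulusProtocol(events=[], warmup=0.0, kind=2)
            run_proto.horizon = onset + 10.0
        else:
            run_proto = StimulusProtocol(
                events=[(odorant, onset, 10.0)], warmup=0.0, kind=2
            )
        rec = engine.run(10.0, run_proto, recorder=rec_sel)
        for g in groups:
            ps = power_spectrum(virtual_lfp(rec, g))
            results[g]["peaks"].append(ps.peak_power)
            results[g]["freqs"].append(ps.peak_freq)
    out = {}
    for g in groups:
        peaks = np.array(results[g]["peaks"])
        out[g] = {
            "peak_power_mean": float(peaks.mean()),
            "peak_power_sd": float(peaks.std()),
            "peak_freq_mean": float(np.mean(results[g]["freqs"])),
        }
    return out


# ---------------------------------------------------------------------------
# Associative learning


@dataclass
class LearningOutcome:
    """Result of one or more learning sets."""

    learned_odorant: str
    spike_counts: list = field(default_factory=list)  # per trial: {odor: count}
    successes: list = field(default_factory=list)
    threshold: int = 1

    @property
    def success_rate(self) -> float:
        if not self.successes:
            return float("nan")
        return float(np.mean(self.successes))


def is_trial_success(counts: dict[str, int], learned: str, threshold: int = 1) -> bool:
    """Success = the readout fired in the learned window and only there."""
    if counts[learned] < threshold:
        return False
    return all(c < threshold for od, c in counts.items() if od != learned)


def run_learning_experiment(
    net: Network,
    learned_odorant: str = SIX_ODORANTS[0],
    n_sets: int = 1,
    n_trials_per_set: int = 10,
    seed: int = 0,
    warmup: float = 300.0,
    odorants=SIX_ODORANTS,
    threshold: int = 1,
    dt: float = 1e-3,
    ltd_enabled: bool = True,
    shared_engine: SimulationEngine | None = None,
    warm_state=None,
) -> LearningOutcome:
    """Associative-learning sets: one conditioning, then randomized trials.

    Each set warms the network up under protocol-1 cycling, presents the
    target odorant for 1 s and delivers the reward 3 s after onset (LTD of
    the eligible KC>MBON-α1 synapses), then runs ``n_trials_per_set`` trials
    in which all six odors are applied sequentially in a seeded unique
    order; a trial succeeds when SMP354 spikes (>= ``threshold``) solely in
    the learned odor's window.  ``ltd_enabled=False`` runs the identical
    schedule without the reward (control).
    """
    rng = np.random.default_rng(seed)
    outcome = LearningOutcome(learned_odorant=learned_odorant, threshold=threshold)
    odorants = list(odorants)
    smp_idx = net.model_index_of("SMP354")

    for s in range(n_sets):
        engine = shared_engine
        if engine is None or s > 0:
            engine = SimulationEngine(net, dt=dt, seed=seed + 7919 * s)
            proto_w = build_protocol(1, odorants, warmup=warmup, n_cycles=0)
            engine.run(warmup, proto_w)
        elif warm_state is not None:
            engine.restore(warm_state)

        # conditioning: learned odor once, reward 3 s after onset
        t0 = engine.t
        cond = StimulusProtocol(events=[(learned_odorant, t0, 1.0)], warmup=0.0, kind=1)
        cond.horizon = t0 + 5.0
        rewards = (t0 + REWARD_LATENCY_S,) if ltd_enabled else ()
        engine.run(5.0, cond, reward_times=rewards)

        for _ in range(n_trials_per_set):
            order = list(rng.permutation(odorants))
            t_trial = engine.t
            events = [(od, t_trial + 5.0 * i, 1.0) for i, od in enumerate(order)]
            proto = StimulusProtocol(events=events, warmup=0.0, kind=1)
            proto.horizon = t_trial + 5.0 * len(order)
            rec = engine.run(5.0 * len(order), proto)
            counts = {
                od: rec.spike_counts(smp_idx, t_trial + 5.0 * i, t_trial + 5.0 * i + 1.0)
                for i, od in enumerate(order)
            }
            outcome.spike_counts.append(counts)
            outcome.successes.append(is_trial_success(counts, learned_odorant, threshold))
    return outcome
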