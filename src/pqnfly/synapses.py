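"""Kinetic synapses, weighted input accumulation, and reward-driven LTD.

Chemical synapses follow a qualitative two-state kinetic scheme: the
activation ``s`` rises toward 1 at rate ``alpha`` while the presynaptic
membrane potential is suprathreshold (``v >= 0``) and decays at rate ``beta``
otherwise.  With the default ``beta = 203.125`` the continuous-time decay
constant is ``1/beta ≈ 4.92 ms``, i.e. the ~5 ms measured for cholinergic and
GABAergic synapses in the fly; ``alpha = 250`` makes a single spike drive
``s`` to approximately 1.

Olfactory-receptor-neuron (ORN) synapses are event-driven instead: a spike
sets ``s`` to 1 instantaneously and it decays with the same ``beta``.

The input current of neuron *i* is the weight- and class-scaled sum
``I_i = sum_j w_ji s_j p_{x,y}`` where ``p_{x,y}`` scales each
(presynaptic class, postsynaptic class) pair and carries the sign of the
presynaptic transmitter (positive excitatory, negative inhibitory).

Associative learning is long-term depression (LTD) of the Kenyon-cell to
MBON-α1 synapses: a reward depresses, from 1 to 0.25, the weight of every KC
that spiked within the previous five seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ALPHA_SYN",
    "BETA_SYN",
    "LTD_WEAK_WEIGHT",
    "ELIGIBILITY_WINDOW_S",
    "SynapseBank",
    "WeightMatrix",
    "ScalingTable",
    "EligibilityBuffer",
    "step_chemical_synapse",
    "step_orn_synapse",
    "accumulate_input",
    "record_kc_spikes",
    "apply_reward",
]

ALPHA_SYN = 250.0
BETA_SYN = 203.125
LTD_WEAK_WEIGHT = 0.25
ELIGIBILITY_WINDOW_S = 5.0

#: presynaptic classes that release inhibitory transmitter
INHIBITORY_CLASSES = frozenset({"LN", "APL", "MBON_a1"})
EXCITATORY_CLASSES = frozenset({"ORN", "PN", "KC", "MBON_a3", "SMP354"})
LN_SUBCLASSES = (
    "Krasavietz_class1",
    "Krasavietz_class2",
    "NP1227_class1",
    "NP2426_class1",
)


@dataclass
class SynapseBank:
    """Synaptic activation ``s`` for one presynaptic population."""

    s: np.ndarray
    alpha_syn: float = ALPHA_SYN
    beta_syn: float = BETA_SYN
    is_orn: bool = False

    @classmethod
    def zeros(cls, n: int, is_orn: bool = False, alpha_syn: float = ALPHA_SYN,
              beta_syn: float = BETA_SYN) -> "SynapseBank":
        return cls(s=np.zeros(n), alpha_syn=alpha_syn, beta_syn=beta_syn,
                   is_orn=is_orn)


def step_chemical_synapse(bank: SynapseBank, v_pre, dt: float) -> SynapseBank:
    """Euler step of the kinetic synapse driven by presynaptic potential."""
    if bank.is_orn:
        raise ValueError("ORN banks use step_orn_synapse")
    above = np.asarray(v_pre) >= 0.0
    s = bank.s
    bank.s = np.where(
        above,
        s + dt * bank.alpha_syn * (1.0 - s),
        s - dt * bank.beta_syn * s,
    )
    return bank


def step_orn_synapse(bank: SynapseBank, spike, dt: float) -> SynapseBank:
    """Event-driven ORN synapse: a spike sets s to 1, otherwise s decays."""
    if not bank.is_orn:
        raise ValueError("chemical banks use step_chemical_synapse")
    spike = np.asarray(spike, dtype=bool)
    decayed = bank.s - dt * bank.beta_syn * bank.s
    bank.s = np.where(spike, 1.0, decayed)
    return bank


@dataclass
class ScalingTable:
    """Class-pair synaptic scaling ``p_{x,y}``.

    Signs follow transmitter polarity: positive when the presynaptic class is
    excitatory (ORN, PN, KC, MBON-α3), negative when inhibitory (LN, APL,
    MBON-α1).  The four LN subclasses share a single value keyed by ``LN``.
    """

    p: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (pre, post), val in self.p.items():
            self._check_sign(pre, val)

    @staticmethod
    def _check_sign(pre: str, val: float) -> None:
        pre_base = "LN" if pre in LN_SUBCLASSES else pre
        if pre_base in INHIBITORY_CLASSES and val > 0:
            raise ValueError(f"p for inhibitory presynaptic class {pre} must be <= 0")
        if pre_base in EXCITATORY_CLASSES and val < 0:
            raise ValueError(f"p for excitatory presynaptic class {pre} must be >= 0")

    def get(self, pre: str, post: str) -> float:
        pre_base = "LN" if pre in LN_SUBCLASSES else pre
        post_base = "LN" if post in LN_SUBCLASSES else post
        for key in ((pre, post), (pre_base, post_base)):
            if key in self.p:
                return self.p[key]
        raise KeyError(f"no scaling p for class pair ({pre}, {post})")

    def set(self, pre: str, post: str, value: float) -> None:
        self._check_sign(pre, value)
        self.p[(pre, post)] = value


@dataclass
class WeightMatrix:
    """Sparse presynaptic-by-postsynaptic weight matrix with class labels.

    Entries are binary except the plastic KC>MBON-α1 block whose entries take
    the values 1 (naive) or 0.25 (depressed).
    """

    w: sp.csr_matrix
    class_of: np.ndarray  # class label per neuron index (str array)

    @property
    def n_neurons(self) -> int:
        return self.w.shape[0]

    def classes(self) -> np.ndarray:
        return np.unique(self.class_of)

    def index_of_class(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.class_of == cls)


def accumulate_input(W: WeightMatrix, s: np.ndarray, table: ScalingTable) -> np.ndarray:
    """Weighted, class-scaled input ``I_i = sum_j w_ji s_j p_{x,y}``.

    ``s`` holds the synaptic activation of every presynaptic neuron, indexed
    like the rows of ``W.w``.  Raises ``KeyError`` when an existing edge has
    no scaling entry.
    """
    scaled = scale_weight_matrix(W, table)
    return np.asarray(scaled.T @ s).ravel()


def scale_weight_matrix(W: WeightMatrix, table: ScalingTable) -> sp.csr_matrix:
    """Fold the class-pair scaling into the sparse weights (pre x post)."""
    coo = W.w.tocoo()
    cls = W.class_of
    if coo.nnz == 0:
        return W.w.tocsr() * 0.0
    pre_cls = cls[coo.row]
    post_cls = cls[coo.col]
    # vectorize lookup over unique class pairs
    data = coo.data.astype(float).copy()
    pairs = np.char.add(np.char.add(pre_cls.astype(str), "|"), post_cls.astype(str))
    for pair in np.unique(pairs):
        pre, post = pair.split("|")
        mask = pairs == pair
        data[mask] *= table.get(pre, post)
    return sp.csr_matrix((data, (coo.row, coo.col)), shape=coo.shape)


@dataclass
class EligibilityBuffer:
    """Last spike time per KC; eligibility spans the 5 s before a reward."""

    last_spike_time: np.ndarray
    window: float = ELIGIBILITY_WINDOW_S

    @classmethod
    def empty(cls, n_kc: int, window: float = ELIGIBILITY_WINDOW_S) -> "EligibilityBuffer":
        return cls(last_spike_time=np.full(n_kc, -np.inf), window=window)

    def eligible(self, t_reward: float) -> np.ndarray:
        return (self.last_spike_time >= t_reward - self.window) & (
            self.last_spike_time <= t_reward
        )


def record_kc_spikes(buf: EligibilityBuffer, spikes, t: float) -> EligibilityBuffer:
    """Update last-spike bookkeeping for the KCs spiking at time ``t`` (s)."""
    spikes = np.asarray(spikes, dtype=bool)
    buf.last_spike_time[spikes] = t
    return buf


def apply_reward(W, buf: EligibilityBuffer, t_reward: float,
                 weak: float = LTD_WEAK_WEIGHT):
    """Depress the KC>MBON-α1 weight of every eligible KC to ``weak`` (0.25).

    Weights already depressed stay depressed (absolute assignment, idempotent
    — the hardware stores these weights in two bits).  ``W`` may be either a
    per-KC weight vector for the single MBON-α1 column, or a full
    :class:`WeightMatrix`, in which case only existing KC>MBON-α1 entries are
    touched.
    """
    eligible = buf.eligible(t_reward)
    if isinstance(W, WeightMatrix):
        kc_idx = W.index_of_class("KC")
        mbon_idx = W.index_of_class("MBON_a1")
        lil = W.w.tolil()
        for kc in kc_idx[eligible[: len(kc_idx)]]:
            for mb in mbon_idx:
                if lil[kc, mb] != 0:
                    lil[kc, mb] = weak
        W.w = lil.tocsr()
        return W
    plastic_w = np.asarray(W, dtype=float)
    plastic_w[eligible] = weak
    return plastic_w
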