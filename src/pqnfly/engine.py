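"""Vectorized network simulation engine.

All modeled neurons (everything except the ORN inputs, which are a Poisson
process) are integrated in one set of flat state arrays regardless of
variant: single-compartment neurons simply carry ``theta = k_0 = 0`` (frozen
soma) and two-compartment neurons ``epsilon = 0`` (frozen slow variable), so
one synchronous Euler update covers PNs, LN subclasses, KCs, APL, MBONs and
SMP354 alike.  Per step:

1. draw ORN spikes and update the event-driven ORN synapses,
2. accumulate the class-scaled synaptic input ``I`` (sparse matvec plus the
   plastic KC>MBON-α1 dot product), zeroing it for inactivated classes,
3. advance all neuron states (PN drive gated by the homeostatic ``u``),
4. update the chemical synapses from the freshly committed potentials and
   record KC spike times for the plasticity eligibility window.

Once per simulated second the PN homeostatic gain is adjusted.  The engine
is deterministic given the seed and supports branching from a deep-copied
checkpoint, which the experiment drivers use to share one homeostatic
warm-up across conditions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import synapses as syn
from .pqn import NumericOverflowError, PQNParameters
from .stimulus import ORResponseTable, StimulusProtocol, rate_matrix
from .synapses import EligibilityBuffer, ScalingTable, WeightMatrix
from .topology import NeuronTable

__all__ = ["Network", "Recorder", "SimulationRecording", "SimulationEngine"]

_PAR_FIELDS = (
    "tau", "phi", "epsilon", "I_b0", "k_I", "m0", "m1",
    "a_fn", "b_fn", "c_fn", "a_fp", "b_fp", "c_fp",
    "a_gn", "b_gn", "c_gn", "a_gp", "b_gp", "c_gp", "r_g",
    "a_hn", "b_hn", "c_hn", "a_hp", "b_hp", "c_hp", "r_h",
    "theta", "alpha_leak", "I_b1", "k_0", "k_r", "kappa", "F_t",
)


@dataclass
class Network:
    """Static description of a runnable network.

    ``params`` maps neuron class names (LNs by subclass) to
    :class:`~pqnfly.pqn.PQNParameters`; ``scaling`` holds the class-pair
    ``p`` values (the four LN subclasses share the ``LN`` row).
    """

    neurons: NeuronTable
    weights: WeightMatrix
    params: dict[str, PQNParameters]
    scaling: ScalingTable
    or_table: ORResponseTable
    or_types: np.ndarray  # receptor per ORN

    def __post_init__(self) -> None:
        df = self.neurons.df
        self.orn_ids = self.neurons.ids_of("ORN")
        self.model_ids = df.loc[df["class"] != "ORN", "id"].to_numpy()
        if len(self.or_types) != len(self.orn_ids):
            raise ValueError("or_types must have one receptor per ORN")
        # parameter key per modeled neuron: LNs keyed by subclass
        sub = df.loc[df["class"] != "ORN"]
        keys = sub["class"].to_numpy(dtype=object).copy()
        is_ln = keys == "LN"
        keys[is_ln] = sub.loc[sub["class"] == "LN", "ln_subclass"].to_numpy(dtype=object)
        missing = set(keys) - set(self.params)
        if missing:
            raise KeyError(f"no PQN parameters for classes {sorted(missing)}")
        self.param_key = keys
        self.model_class = sub["class"].to_numpy(dtype=object)

    def model_index_of(self, cls: str) -> np.ndarray:
        """Indices into the modeled-neuron arrays, by class or LN subclass."""
        if cls in syn.LN_SUBCLASSES:
            return np.flatnonzero(self.param_key == cls)
        return np.flatnonzero(self.model_class == cls)


class Recorder:
    """Selects what a run stores: spikes, group-mean synaptic currents, traces."""

    def __init__(self, lfp_groups=(), v_trace_classes=(), record_u: bool = False,
                 record_spikes: bool = True):
        self.lfp_groups = tuple(lfp_groups)
        self.v_trace_classes = tuple(v_trace_classes)
        self.record_u = record_u
        self.record_spikes = record_spikes


@dataclass
class SimulationRecording:
    """Time-stamped output of one run (all series share the dt grid)."""

    dt: float
    t_start: float
    n_steps: int
    spike_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    spike_neuron: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    lfp: dict = field(default_factory=dict)          # group -> mean s(t) over group
    v_traces: dict = field(default_factory=dict)     # class -> (neurons, steps) v
    vs_traces: dict = field(default_factory=dict)    # class -> somatic potential
    s_traces: dict = field(default_factory=dict)     # class -> mean synaptic current
    u_mean: np.ndarray | None = None
    seed: int | None = None

    @property
    def t(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_steps) * self.dt

    def spikes_of(self, model_index: np.ndarray) -> np.ndarray:
        """Spike times (s) of the given modeled-neuron indices."""
        mask = np.isin(self.spike_neuron, model_index)
        return self.spike_t[mask]

    def spike_counts(self, model_index: np.ndarray, t0: float, t1: float) -> int:
        times = self.spikes_of(model_index)
        return int(np.count_nonzero((times >= t0) & (times < t1)))


class SimulationEngine:
    """Stateful stepping of one network realisation."""

    def __init__(self, net: Network, dt: float = 1e-3, seed: int = 0,
                 quantizer=None, inactivate=()):
        self.net = net
        self.dt = dt
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.q = quantizer  # None = float64; else fixed-point Quantizer
        self.inactivate = tuple(inactivate)
        self.t = 0.0
        self.step_count = 0

        m = len(net.model_ids)
        self.m = m
        # per-neuron parameter arrays
        self.par = {f: np.empty(m) for f in _PAR_FIELDS}
        self.is_pn = np.zeros(m, dtype=bool)
        for key in np.unique(net.param_key):
            p = net.params[key]
            idx = np.flatnonzero(net.param_key == key)
            for f in _PAR_FIELDS:
                self.par[f][idx] = getattr(p, f)
            if p.variant == "pn":
                self.is_pn[idx] = True
        if self.q is not None:
            for f in _PAR_FIELDS:
                self.par[f] = self.q.quantize(self.par[f])

        # state
        self.v = np.zeros(m)
        self.n = np.zeros(m)
        self.qvar = np.zeros(m)
        self.v_s = np.zeros(m)
        self.u = np.zeros(m)
        self.F = np.zeros(m)
        self.spike_count_window = np.zeros(m, dtype=np.int64)
        self.s_mod = np.zeros(m)                  # chemical synapse per modeled neuron
        self.s_orn = np.zeros(len(net.orn_ids))   # event-driven ORN synapses
        self.elig = EligibilityBuffer.empty(int((net.model_class == "KC").sum()))

        self._build_accumulator()
        self._inact_idx = np.concatenate(
            [net.model_index_of(c) for c in self.inactivate]
        ) if self.inactivate else np.empty(0, dtype=np.int64)

    # -- construction -----------------------------------------------------
    def _build_accumulator(self) -> None:
        net = self.net
        n_orn = len(net.orn_ids)
        n_ids = int(net.neurons.df["id"].max()) + 1
        # global s vector order: [ORNs, modeled neurons]
        s_index = np.full(n_ids, -1, dtype=np.int64)
        s_index[net.orn_ids] = np.arange(n_orn)
        s_index[net.model_ids] = n_orn + np.arange(self.m)
        model_index = np.full(n_ids, -1, dtype=np.int64)
        model_index[net.model_ids] = np.arange(self.m)

        df = net.neurons.df
        key_of = df["class"].to_numpy(dtype=object).copy()
        is_ln = key_of == "LN"
        key_of[is_ln] = df.loc[df["class"] == "LN", "ln_subclass"].to_numpy(object)
        key_by_id = np.full(n_ids, "", dtype=object)
        key_by_id[df["id"].to_numpy()] = key_of

        coo = net.weights.w.tocoo()
        cls = net.weights.class_of
        pre_cls = cls[coo.row]
        post_cls = cls[coo.col]
        # per-edge scaling p (vectorized over unique key pairs)
        p_edge = np.empty(coo.nnz)
        pre_keys = key_by_id[coo.row]
        post_keys = key_by_id[coo.col]
        pair_tag = np.char.add(np.char.add(pre_keys.astype(str), "|"),
                               post_keys.astype(str))
        for tag in np.unique(pair_tag):
            pre_k, post_k = tag.split("|")
            p_edge[pair_tag == tag] = net.scaling.get(pre_k, post_k)

        plastic = (pre_cls == "KC") & (post_cls == "MBON_a1")
        static = ~plastic
        rows = s_index[coo.row[static]]
        cols = model_index[coo.col[static]]
        data = coo.data[static] * p_edge[static]
        self.A = sp.csr_matrix(
            (data, (cols, rows)), shape=(self.m, n_orn + self.m)
        )  # post x pre, so I = A @ s
        self._factor_orn_block(n_orn)

        # plastic KC>MBON-a1 block: per-KC weight vector (model order of KCs)
        kc_model = net.model_index_of("KC")
        self.kc_model = kc_model
        self.mbon1_model = net.model_index_of("MBON_a1")
        try:
            self.p_kc_mbon1 = net.scaling.get("KC", "MBON_a1")
        except KeyError:
            if plastic.any():
                raise
            self.p_kc_mbon1 = 0.0  # no plastic block in this network
        self.w_plastic = np.zeros(len(kc_model))
        kc_pos = np.full(self.m, -1, dtype=np.int64)
        kc_pos[kc_model] = np.arange(len(kc_model))
        for r, wv in zip(model_index[coo.row[plastic]], coo.data[plastic]):
            self.w_plastic[kc_pos[r]] = wv

    def _factor_orn_block(self, n_orn: int) -> None:
        """Factor the ORN input block through glomerulus sums when exact.

        ORN→PN and ORN→LN wiring is block-structured by glomerulus (an ORN
        drives all PNs of its glomerulus and all LNs innervating it), so
        ``A_orn @ s_orn == U @ (G @ s_orn)`` with ``G`` the glomerulus
        indicator over ORNs and ``U`` a small per-glomerulus coefficient
        matrix.  The factorisation is verified exactly against ``A_orn`` and
        skipped when the wiring does not admit it (e.g. arbitrary connectome
        exports); it only ever changes the cost, never the result.
        """
        self._orn_factor = None
        df = self.net.neurons.df
        orn = df.loc[df["class"] == "ORN"]
        gloms = orn["glomerulus"]
        if len(gloms) == 0 or gloms.isna().any():
            return
        gloms = gloms.to_numpy(object)
        uniq, g_idx = np.unique(gloms.astype(str), return_inverse=True)
        G = sp.csr_matrix(
            (np.ones(n_orn), (g_idx, np.arange(n_orn))), shape=(len(uniq), n_orn)
        )
        A_orn = self.A[:, :n_orn].tocsc()
        # candidate U from one representative ORN per glomerulus
        rep = np.array([int(np.flatnonzero(g_idx == k)[0]) for k in range(len(uniq))])
        U = sp.hstack([A_orn[:, [r]] for r in rep]).tocsr()
        if (U @ G != A_orn).nnz == 0:
            self._orn_factor = (U, G)
            self.A_model = self.A[:, n_orn:].tocsr()

    # -- checkpointing ----------------------------------------------------
    def checkpoint(self) -> dict:
        keys = ("t", "step_count", "v", "n", "qvar", "v_s", "u", "F",
                "spike_count_window", "s_mod", "s_orn", "w_plastic")
        state = {k: copy.deepcopy(getattr(self, k)) for k in keys}
        state["rng"] = copy.deepcopy(self.rng)
        state["elig"] = copy.deepcopy(self.elig)
        return state

    def restore(self, state: dict) -> None:
        for k, val in state.items():
            setattr(self, k, copy.deepcopy(val))

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)
        self.seed = seed

    def set_inactivated(self, classes=()) -> None:
        """Force the stimulus input of the given classes/subclasses to zero."""
        self.inactivate = tuple(classes)
        self._inact_idx = np.concatenate(
            [self.net.model_index_of(c) for c in self.inactivate]
        ) if self.inactivate else np.empty(0, dtype=np.int64)

    # -- stepping ----------------------------------------------------------
    def run(
        self,
        duration: float,
        protocol: StimulusProtocol,
        recorder: Recorder | None = None,
        reward_times=(),
    ) -> SimulationRecording:
        """Advance the network ``duration`` seconds under the protocol.

        ``reward_times`` trigger LTD of the plastic KC>MBON-α1 weights for
        KCs that spiked within the previous five seconds.  Runs on a
        compiled kernel when possible (float arithmetic, glomerulus-
        factorable ORN block); the pure-numpy reference path handles the
        fixed-point mode and arbitrary topologies.  Both paths implement
        the identical update order.
        """
        net, dt = self.net, self.dt
        recorder = recorder or Recorder()
        n_steps = int(round(duration / dt))
        t0 = self.t
        rec = SimulationRecording(dt=dt, t_start=t0, n_steps=n_steps, seed=self.seed)

        # spike probabilities are produced lazily per chunk: a full
        # (n_orn x n_steps) matrix for a long run would dominate memory
        def p_spike_chunk(k0: int, k1: int) -> np.ndarray:
            rates = rate_matrix(
                protocol, net.or_table, net.or_types, dt, t0 + k0 * dt, k1 - k0
            )
            return np.clip(rates * dt, 0.0, 1.0)

        groups = {
            g: self._group_index(g) for g in recorder.lfp_groups
        }
        for g in groups:
            rec.lfp[g] = np.empty(n_steps)
        traces = {}
        for cname in recorder.v_trace_classes:
            idx = self._group_index(cname)
            traces[cname] = idx
            rec.v_traces[cname] = np.empty((len(idx), n_steps))
            rec.vs_traces[cname] = np.empty((len(idx), n_steps))
            rec.s_traces[cname] = np.empty(n_steps)
        if recorder.record_u:
            rec.u_mean = np.empty(n_steps)

        if self.q is None and self._orn_factor is not None:
            return self._run_compiled(
                rec, p_spike_chunk, groups, traces, recorder, reward_times
            )
        return self._run_reference(rec, p_spike_chunk, groups, traces, recorder,
                                   reward_times)

    def _run_compiled(self, rec, p_spike_chunk, groups, traces, recorder, reward_times):
        from . import _kernel

        net, dt = self.net, self.dt
        n_steps = rec.n_steps
        t0 = rec.t_start
        m = self.m
        U, G = self._orn_factor
        # G has exactly one entry per ORN column; CSC row index = glomerulus
        glom_idx = np.asarray(G.tocsc().indices, dtype=np.int64)
        U = U.tocsr()
        Am = self.A_model

        par = self.par
        c_v = dt * par["phi"] / par["tau"]
        c_n = dt / par["tau"]
        c_q = dt * par["epsilon"] / par["tau"]
        c_vs = dt * par["theta"] / par["tau"]
        has_q = bool(np.any(par["epsilon"] != 0.0))
        has_soma = bool(np.any(par["theta"] != 0.0))
        kappa_over_tau = par["kappa"] / par["tau"]
        steps_per_second = max(int(round(1.0 / dt)), 1)

        lfp_names = list(groups)
        lfp_idx = (np.concatenate([groups[g] for g in lfp_names])
                   if lfp_names else np.empty(0, dtype=np.int64)).astype(np.int64)
        lfp_off = np.cumsum([0] + [len(groups[g]) for g in lfp_names]).astype(np.int64)
        tr_names = list(traces)
        tr_idx = (np.concatenate([traces[c] for c in tr_names])
                  if tr_names else np.empty(0, dtype=np.int64)).astype(np.int64)
        tr_off = np.cumsum([0] + [len(traces[c]) for c in tr_names]).astype(np.int64)

        lfp_out_full = np.empty((len(lfp_names), n_steps))
        v_out_full = np.empty((len(tr_idx), n_steps))
        vs_out_full = np.empty((len(tr_idx), n_steps))
        str_out_full = np.empty((len(tr_names), n_steps))
        u_out_full = np.empty(n_steps if recorder.record_u else 0)

        spike_t_chunks, spike_n_chunks = [], []
        rewards = sorted(reward_times)

        # chunk boundaries: every `chunk` steps plus one at each reward
        chunk = 1000
        cuts = set(range(0, n_steps, chunk)) | {n_steps}
        for T in rewards:
            k_apply = int(np.ceil((T - t0) / dt - 1e-9))
            cuts.add(int(np.clip(k_apply, 0, n_steps)))
        cuts = sorted(cuts)
        n_orn = len(self.s_orn)
        ri = 0

        for b in range(len(cuts) - 1):
            k0, k1 = cuts[b], cuts[b + 1]
            # rewards scheduled exactly at this boundary
            while ri < len(rewards) and int(np.clip(int(np.ceil(
                    (rewards[ri] - t0) / dt - 1e-9)), 0, n_steps)) <= k0:
                self.w_plastic = syn.apply_reward(self.w_plastic, self.elig, rewards[ri])
                ri += 1
            if k1 == k0:
                continue
            steps = k1 - k0
            rand_block = self.rng.random((steps, n_orn))
            p_block = np.ascontiguousarray(p_spike_chunk(k0, k1).T)
            spikes_out = np.zeros((steps, m), dtype=np.uint8)
            bad, t_bad = _kernel.run_block(
                steps, rand_block, p_block,
                self.s_orn, glom_idx, G.shape[0],
                U.indptr, U.indices, U.data,
                Am.indptr, Am.indices, Am.data,
                self.v, self.n, self.qvar, self.v_s, self.u,
                self.spike_count_window, self.s_mod,
                par["a_fn"], par["b_fn"], par["c_fn"],
                par["a_fp"], par["b_fp"], par["c_fp"],
                par["a_gn"], par["b_gn"], par["c_gn"],
                par["a_gp"], par["b_gp"], par["c_gp"], par["r_g"],
                par["a_hn"], par["b_hn"], par["c_hn"],
                par["a_hp"], par["b_hp"], par["c_hp"], par["r_h"],
                par["k_I"], par["m0"], par["m1"], par["I_b0"],
                c_v, c_n, c_q, c_vs,
                par["k_0"], par["alpha_leak"], par["I_b1"],
                self.is_pn, has_q, has_soma,
                self.kc_model.astype(np.int64), self.w_plastic,
                self.p_kc_mbon1, self.mbon1_model.astype(np.int64),
                self._inact_idx.astype(np.int64),
                dt * syn.ALPHA_SYN, dt * syn.BETA_SYN,
                self.elig.last_spike_time,
                t0 + k0 * dt, dt,
                self.step_count, steps_per_second,
                kappa_over_tau, par["F_t"], self.F,
                spikes_out,
                lfp_idx, lfp_off, lfp_out_full[:, k0:k1],
                tr_idx, tr_off, v_out_full[:, k0:k1], vs_out_full[:, k0:k1],
                str_out_full[:, k0:k1],
                u_out_full[k0:k1] if recorder.record_u else np.empty(0),
                recorder.record_u,
            )
            self.step_count += steps
            if bad >= 0:
                raise NumericOverflowError(
                    f"non-finite state at t={t0 + (k0 + t_bad) * dt:.3f}s, "
                    f"modeled neuron {bad} (class {self.net.model_class[bad]})"
                )
            if recorder.record_spikes:
                st, sn = np.nonzero(spikes_out)
                if len(st):
                    spike_t_chunks.append(t0 + (k0 + st + 1) * dt)
                    spike_n_chunks.append(sn.astype(np.int64))

        while ri < len(rewards):
            self.w_plastic = syn.apply_reward(self.w_plastic, self.elig, rewards[ri])
            ri += 1

        for gi, gname in enumerate(lfp_names):
            rec.lfp[gname] = lfp_out_full[gi]
        for ti, cname in enumerate(tr_names):
            lo, hi = tr_off[ti], tr_off[ti + 1]
            rec.v_traces[cname] = v_out_full[lo:hi]
            rec.vs_traces[cname] = vs_out_full[lo:hi]
            rec.s_traces[cname] = str_out_full[ti]
        if recorder.record_u:
            rec.u_mean = u_out_full
        self.t = t0 + n_steps * dt
        if spike_t_chunks:
            rec.spike_t = np.concatenate(spike_t_chunks)
            rec.spike_neuron = np.concatenate(spike_n_chunks)
        return rec

    def _run_reference(self, rec, p_spike_chunk, groups, traces, recorder, reward_times):
        net, dt = self.net, self.dt
        n_steps = rec.n_steps
        t0 = rec.t_start
        spike_t_chunks, spike_n_chunks = [], []
        rewards = sorted(reward_times)
        ri = 0
        steps_per_second = max(int(round(1.0 / dt)), 1)
        par = self.par
        quant = self.q.quantize if self.q is not None else None

        # hoisted per-neuron constants (plain Euler coefficients)
        c_v = dt * par["phi"] / par["tau"]
        c_n = dt / par["tau"]
        c_q = dt * par["epsilon"] / par["tau"]
        c_vs = dt * par["theta"] / par["tau"]
        has_q = bool(np.any(par["epsilon"] != 0.0))
        has_soma = bool(np.any(par["theta"] != 0.0))
        n_orn = len(self.s_orn)
        beta_dt = dt * syn.BETA_SYN
        alpha_dt = dt * syn.ALPHA_SYN
        factor = self._orn_factor
        A_model = getattr(self, "A_model", None)
        inact = self._inact_idx if len(self._inact_idx) else None
        check_every = steps_per_second  # overflow check once per simulated second

        for k in range(n_steps):
            t_now = t0 + k * dt
            # 1. ORN spikes and event-driven synapses
            if k % 1000 == 0:
                p_block_ref = p_spike_chunk(k, min(k + 1000, n_steps))
            orn_spk = self.rng.random(n_orn) < p_block_ref[:, k % 1000]
            self.s_orn -= beta_dt * self.s_orn
            self.s_orn[self.s_orn < 1e-12] = 0.0  # flush denormals
            self.s_orn[orn_spk] = 1.0
            if quant:
                self.s_orn = quant(self.s_orn)

            # 2. synaptic input accumulation
            if factor is not None:
                U, G = factor
                I = U @ (G @ self.s_orn) + A_model @ self.s_mod
            else:
                I = self.A @ np.concatenate([self.s_orn, self.s_mod])
            I[self.mbon1_model] += self.p_kc_mbon1 * float(
                self.w_plastic @ self.s_mod[self.kc_model]
            )
            if inact is not None:
                I[inact] = 0.0
            if quant:
                I = quant(I)

            # 3. neuron update (synchronous Euler, RHS at pre-step state)
            v, n, qv, v_s = self.v, self.n, self.qvar, self.v_s
            neg = v < 0.0
            f = np.where(neg,
                         par["a_fn"] * (v - par["b_fn"]) ** 2 + par["c_fn"],
                         par["a_fp"] * (v - par["b_fp"]) ** 2 + par["c_fp"])
            g = np.where(v < par["r_g"],
                         par["a_gn"] * (v - par["b_gn"]) ** 2 + par["c_gn"],
                         par["a_gp"] * (v - par["b_gp"]) ** 2 + par["c_gp"])
            m_in = par["k_I"] * np.clip(I, par["m0"], par["m1"])
            gate = np.where(self.is_pn, self.u, 1.0)
            rhs = f
            rhs -= n
            rhs += par["I_b0"]
            rhs += gate * m_in
            if has_q:
                h = np.where(v < par["r_h"],
                             par["a_hn"] * (v - par["b_hn"]) ** 2 + par["c_hn"],
                             par["a_hp"] * (v - par["b_hp"]) ** 2 + par["c_hp"])
                rhs -= qv
                q_new = qv + c_q * (h - qv)
            else:
                q_new = qv
            if has_soma:
                I_c = par["k_0"] * (v - v_s)
                rhs -= I_c
                vs_new = v_s + c_vs * (
                    -par["alpha_leak"] * v_s + par["I_b1"] + I_c
                )
            else:
                vs_new = v_s
            v_new = v + c_v * rhs
            n_new = n + c_n * (g - n)
            if quant:
                v_new, n_new = quant(v_new), quant(n_new)
                q_new, vs_new = quant(q_new), quant(vs_new)
            spiked = neg & (v_new >= 0.0)
            if (k + 1) % check_every == 0 and not (
                np.all(np.isfinite(v_new)) and np.all(np.isfinite(n_new))
            ):
                bad = int(np.flatnonzero(~np.isfinite(v_new + n_new))[0])
                raise NumericOverflowError(
                    f"non-finite state at t={t_now:.3f}s, modeled neuron {bad} "
                    f"(class {self.net.model_class[bad]})"
                )
            self.v, self.n, self.qvar, self.v_s = v_new, n_new, q_new, vs_new
            self.spike_count_window += spiked

            # 4. chemical synapses from the committed potential; eligibility
            above = v_new >= 0.0
            s = self.s_mod
            s_above = s[above]
            s -= beta_dt * s
            s[s < 1e-12] = 0.0  # flush denormals
            s[above] = s_above + alpha_dt * (1.0 - s_above)
            if quant:
                self.s_mod = quant(self.s_mod)
            kc_spk = spiked[self.kc_model]
            if kc_spk.any():
                self.elig.last_spike_time[kc_spk] = t_now

            # rewards (LTD) scheduled within this step
            while ri < len(rewards) and rewards[ri] <= t_now + dt:
                self.w_plastic = syn.apply_reward(self.w_plastic, self.elig, rewards[ri])
                ri += 1

            # homeostasis on 1-s tumbling windows aligned to t=0
            self.step_count += 1
            if self.step_count % steps_per_second == 0:
                self._homeostasis_update()

            # recording
            if recorder.record_spikes and spiked.any():
                idx = np.flatnonzero(spiked)
                spike_n_chunks.append(idx)
                spike_t_chunks.append(np.full(len(idx), t_now + dt))
            for gname, gidx in groups.items():
                rec.lfp[gname][k] = self.s_mod[gidx].mean()
            for cname, cidx in traces.items():
                rec.v_traces[cname][:, k] = self.v[cidx]
                rec.vs_traces[cname][:, k] = self.v_s[cidx]
                rec.s_traces[cname][k] = self.s_mod[cidx].mean()
            if recorder.record_u:
                rec.u_mean[k] = self.u[self.is_pn].mean()

        self.t = t0 + n_steps * dt
        if spike_t_chunks:
            rec.spike_t = np.concatenate(spike_t_chunks)
            rec.spike_neuron = np.concatenate(spike_n_chunks)
        return rec

    def _homeostasis_update(self) -> None:
        self.F = self.spike_count_window.astype(float)
        du = (self.par["kappa"] / self.par["tau"]) * (self.par["F_t"] - self.F)
        u = self.u + np.where(self.is_pn, du, 0.0)
        self.u = np.clip(u, 0.0, 1.0)
        if self.q is not None:
            self.u = self.q.quantize(self.u)
        self.spike_count_window[:] = 0

    def _group_index(self, name: str) -> np.ndarray:
        idx = self.net.model_index_of(name)
        if idx.size == 0:
            raise KeyError(f"no modeled neurons in group {name!r}")
        return idx
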