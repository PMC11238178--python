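"""Piecewise quadratic neuron (PQN) model.

The PQN model is a qualitative spiking-neuron model whose nullclines are built
from two parabolic branches joined continuously and smoothly at a branch point.
Because the right-hand sides contain only additions and multiplications it maps
directly onto digital arithmetic circuits; here it is integrated with explicit
Euler at a 1 ms default time step, matching a hardware pipeline that updates
every state variable once per millisecond.

Three variants are provided:

``single``
    membrane potential ``v``, recovery variable ``n`` and slow variable ``q``
    (local neurons, APL, and the downstream readout neuron SMP354);
``two_comp``
    an axonal compartment (``v``, ``n``) coupled to a passive somatic
    compartment ``v_s`` through the internal current ``I_c = k_0 (v - v_s)``
    (Kenyon cells and mushroom-body output neurons);
``pn``
    the two-compartment variant with a homeostatic gain ``u`` in [0, 1] that
    scales the transformed synaptic drive and is adjusted once per second
    toward a target firing rate ``F_t`` (projection neurons).

All quantities are abstract model units; only rates (Hz) and times (s) carry
physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "PQNParameters",
    "NeuronPopulationState",
    "derive_dependent_params",
    "eval_piecewise",
    "transform_input",
    "detect_spike",
    "step_single",
    "step_two_comp",
    "step_pn",
    "update_homeostasis",
    "simulate_trace",
    "NumericOverflowError",
]

Variant = Literal["single", "two_comp", "pn"]


class NumericOverflowError(FloatingPointError):
    """State became non-finite during integration."""


@dataclass
class PQNParameters:
    """Constants of one PQN neuron class.

    The independent nullcline coefficients describe the branch of each
    piecewise parabola left of its branch point (``v=0`` for *f*, ``r_g`` for
    *g*, ``r_h`` for *h*) plus the curvature of the right branch; the right
    branch's vertex is derived so the nullcline is C1-continuous
    (:func:`derive_dependent_params`).
    """

    # time-scale constants
    tau: float = 1.0
    phi: float = 1.0
    epsilon: float = 0.0
    # bias and input transform
    I_b0: float = 0.0
    k_I: float = 1.0
    m0: float = 0.0
    m1: float = 1.0
    # f-nullcline
    a_fn: float = 1.0
    b_fn: float = 0.0
    c_fn: float = 0.0
    a_fp: float = 1.0
    # g-nullcline
    a_gn: float = 0.0
    b_gn: float = 0.0
    c_gn: float = 0.0
    a_gp: float = 1.0
    r_g: float = 0.0
    # h-nullcline
    a_hn: float = 0.0
    b_hn: float = 0.0
    c_hn: float = 0.0
    a_hp: float = 1.0
    r_h: float = 0.0
    # two-compartment extras
    theta: float = 0.0
    alpha_leak: float = 0.0
    I_b1: float = 0.0
    k_0: float = 0.0
    k_r: float = 0.0
    # PN homeostasis extras
    kappa: float = 0.0
    F_t: float = 0.0
    variant: Variant = "single"
    # derived (filled by derive_dependent_params)
    b_fp: float = field(default=np.nan)
    c_fp: float = field(default=np.nan)
    b_gp: float = field(default=np.nan)
    c_gp: float = field(default=np.nan)
    b_hp: float = field(default=np.nan)
    c_hp: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.isnan(self.b_fp):
            derived = derive_dependent_params(self)
            for name in ("b_fp", "c_fp", "b_gp", "c_gp", "b_hp", "c_hp"):
                object.__setattr__(self, name, getattr(derived, name))

    def derived_consistent(self, atol: float = 1e-12) -> bool:
        """Check the stored derived coefficients against their formulas."""
        ref = derive_dependent_params(self)
        return all(
            abs(getattr(self, k) - getattr(ref, k)) <= atol
            for k in ("b_fp", "c_fp", "b_gp", "c_gp", "b_hp", "c_hp")
        )


def derive_dependent_params(p: PQNParameters) -> PQNParameters:
    """Fill the right-branch vertex coefficients for C1-continuous nullclines.

    For the *f* nullcline the branch point is ``v = 0``; matching value and
    slope there gives ``b_fp = a_fn b_fn / a_fp`` and
    ``c_fp = a_fn b_fn^2 + c_fn - a_fp b_fp^2``.  The *g* and *h* nullclines
    are matched the same way at ``r_g`` and ``r_h``.

    Raises
    ------
    ValueError
        if any of ``a_fp``, ``a_gp``, ``a_hp`` is zero (the formulas divide
        by them), or if ``m0 > m1``.
    """
    if p.a_fp == 0 or p.a_gp == 0 or p.a_hp == 0:
        raise ValueError("a_fp, a_gp and a_hp must be nonzero")
    if p.m0 > p.m1:
        raise ValueError(f"m0 ({p.m0}) must not exceed m1 ({p.m1})")
    b_fp = p.a_fn * p.b_fn / p.a_fp
    c_fp = p.a_fn * p.b_fn**2 + p.c_fn - p.a_fp * b_fp**2
    b_gp = p.r_g - p.a_gn * (p.r_g - p.b_gn) / p.a_gp
    c_gp = p.a_gn * (p.r_g - p.b_gn) ** 2 + p.c_gn - p.a_gp * (p.r_g - b_gp) ** 2
    b_hp = p.r_h - p.a_hn * (p.r_h - p.b_hn) / p.a_hp
    c_hp = p.a_hn * (p.r_h - p.b_hn) ** 2 + p.c_hn - p.a_hp * (p.r_h - b_hp) ** 2
    return replace(
        p, b_fp=b_fp, c_fp=c_fp, b_gp=b_gp, c_gp=c_gp, b_hp=b_hp, c_hp=c_hp
    )


def eval_piecewise(which: str, v, p: PQNParameters):
    """Evaluate nullcline function ``f``, ``g`` or ``h`` at potential ``v``.

    At the branch point the right ("≥") branch is used; continuity makes the
    choice immaterial for the value, and the derived coefficients make the
    slopes agree too.
    """
    v = np.asarray(v, dtype=float)
    if which == "f":
        r, an, bn, cn, ap, bp, cp = 0.0, p.a_fn, p.b_fn, p.c_fn, p.a_fp, p.b_fp, p.c_fp
    elif which == "g":
        r, an, bn, cn, ap, bp, cp = p.r_g, p.a_gn, p.b_gn, p.c_gn, p.a_gp, p.b_gp, p.c_gp
    elif which == "h":
        r, an, bn, cn, ap, bp, cp = p.r_h, p.a_hn, p.b_hn, p.c_hn, p.a_hp, p.b_hp, p.c_hp
    else:
        raise ValueError(f"unknown nullcline {which!r}")
    neg = an * (v - bn) ** 2 + cn
    pos = ap * (v - bp) ** 2 + cp
    out = np.where(v < r, neg, pos)
    return out if out.ndim else float(out)


def transform_input(I, p: PQNParameters):
    """Nonlinear input transform ``m(I) = k_I * clip(I, m0, m1)``.

    Scales the stimulus by ``k_I`` and clamps its dynamic range to
    ``[m0, m1]`` before scaling; monotone nondecreasing in ``I`` for
    ``k_I >= 0``.
    """
    I = np.asarray(I, dtype=float)
    out = p.k_I * np.clip(I, p.m0, p.m1)
    return out if out.ndim else float(out)


def detect_spike(v_old, v_new):
    """A spike is a negative-to-nonnegative crossing of the membrane potential."""
    return np.logical_and(np.asarray(v_old) < 0.0, np.asarray(v_new) >= 0.0)


@dataclass
class NeuronPopulationState:
    """Dynamical variables of a population sharing one parameter set.

    All state variables start at zero.  ``q`` is used only by the single-
    compartment variant, ``v_s`` only by the two-compartment ones, and
    ``u``/``F``/``spike_count_window`` only by the homeostatic PN variant.
    """

    v: np.ndarray
    n: np.ndarray
    q: np.ndarray
    v_s: np.ndarray
    u: np.ndarray
    F: np.ndarray
    spike_count_window: np.ndarray
    spiked: np.ndarray

    @classmethod
    def zeros(cls, n_neurons: int, u_init: float = 0.0) -> "NeuronPopulationState":
        z = lambda: np.zeros(n_neurons)
        st = cls(
            v=z(), n=z(), q=z(), v_s=z(), u=z(), F=z(),
            spike_count_window=np.zeros(n_neurons, dtype=np.int64),
            spiked=np.zeros(n_neurons, dtype=bool),
        )
        st.u[:] = u_init
        return st

    def _check_finite(self) -> None:
        for name in ("v", "n", "q", "v_s"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise NumericOverflowError(
                    f"non-finite {name} at neuron index {bad}"
                )


def _commit(state: NeuronPopulationState, v_new, n_new, q_new=None, vs_new=None):
    spiked = detect_spike(state.v, v_new)
    state.v = v_new
    state.n = n_new
    if q_new is not None:
        state.q = q_new
    if vs_new is not None:
        state.v_s = vs_new
    state.spiked = spiked
    state._check_finite()
    return state


def step_single(state: NeuronPopulationState, p: PQNParameters, I, dt: float):
    """One synchronous Euler step of the single-compartment variant.

    All right-hand sides are evaluated at the pre-step state so the result is
    independent of neuron ordering (the hardware updates neurons in a
    pipeline but commits synchronously).
    """
    v, n, q = state.v, state.n, state.q
    dv = (p.phi / p.tau) * (
        eval_piecewise("f", v, p) - n - q + p.I_b0 + transform_input(I, p)
    )
    dn = (1.0 / p.tau) * (eval_piecewise("g", v, p) - n)
    dq = (p.epsilon / p.tau) * (eval_piecewise("h", v, p) - q)
    st = _commit(state, v + dt * dv, n + dt * dn, q_new=q + dt * dq)
    return st, st.spiked


def step_two_comp(state: NeuronPopulationState, p: PQNParameters, I, dt: float, I_r=0.0):
    """One Euler step of the two-compartment (axon + passive soma) variant.

    The internal current ``I_c = k_0 (v - v_s)`` flows from the axonal to the
    somatic compartment; spikes are detected on the axonal ``v``.  ``I`` is
    the synaptic drive to the axonal compartment and ``I_r`` a current
    injected into the soma (used for step-response protocols).
    """
    return _step_two_comp_gated(state, p, I, dt, I_r, gate=1.0)


def step_pn(state: NeuronPopulationState, p: PQNParameters, I, dt: float, I_r=0.0):
    """Two-compartment step with the homeostatic gain gating the drive.

    The transformed synaptic input enters as ``u * m(I)``; ``u`` itself is
    changed only by :func:`update_homeostasis`, once per simulated second.
    """
    st, spiked = _step_two_comp_gated(state, p, I, dt, I_r, gate=state.u)
    st.spike_count_window = st.spike_count_window + spiked.astype(np.int64)
    return st, spiked


def _step_two_comp_gated(state, p, I, dt, I_r, gate):
    v, n, v_s = state.v, state.n, state.v_s
    I_c = p.k_0 * (v - v_s)
    dv = (p.phi / p.tau) * (
        eval_piecewise("f", v, p) - n + p.I_b0 + gate * transform_input(I, p) - I_c
    )
    dn = (1.0 / p.tau) * (eval_piecewise("g", v, p) - n)
    dvs = (p.theta / p.tau) * (-p.alpha_leak * v_s + p.I_b1 + I_c + p.k_r * np.asarray(I_r, dtype=float))
    st = _commit(state, v + dt * dv, n + dt * dn, vs_new=v_s + dt * dvs)
    return st, st.spiked


def update_homeostasis(state: NeuronPopulationState, p: PQNParameters):
    """Once-per-second homeostatic gain update for PNs.

    The firing frequency ``F`` is the spike count of the just-completed 1-s
    tumbling window; the gain moves by ``(kappa/tau) * (F_t - F)`` per second
    and is clamped to [0, 1].
    """
    state.F = state.spike_count_window.astype(float)
    u = state.u + (p.kappa / p.tau) * (p.F_t - state.F)
    state.u = np.clip(u, 0.0, 1.0)
    state.spike_count_window = np.zeros_like(state.spike_count_window)
    return state


def simulate_trace(p: PQNParameters, I_series, dt: float = 1e-3, record_n: bool = False):
    """Integrate a single neuron against an input time series.

    For the two-compartment variants the input is routed to the somatic
    injection ``I_r`` (as in a step-response recording); for the single-
    compartment variant it enters the axonal/dendritic drive ``I``.

    Returns a dict with ``t`` (s), ``v``, ``spiked`` and, when present,
    ``v_s`` (and optionally ``n``).
    """
    I_series = np.asarray(I_series, dtype=float)
    if not np.all(np.isfinite(I_series)):
        raise ValueError("input series must be finite")
    steps = len(I_series)
    state = NeuronPopulationState.zeros(1)
    v = np.empty(steps)
    v_s = np.empty(steps)
    n_tr = np.empty(steps)
    spiked = np.zeros(steps, dtype=bool)
    for k in range(steps):
        if p.variant == "single":
            state, sp = step_single(state, p, I_series[k], dt)
        elif p.variant == "two_comp":
            state, sp = step_two_comp(state, p, 0.0, dt, I_r=I_series[k])
        else:
            state, sp = step_pn(state, p, 0.0, dt, I_r=I_series[k])
        v[k] = state.v[0]
        v_s[k] = state.v_s[0]
        n_tr[k] = state.n[0]
        spiked[k] = bool(sp[0])
    out = {"t": np.arange(steps) * dt, "v": v, "spiked": spiked}
    if p.variant != "single":
        out["v_s"] = v_s
    if record_n:
        out["n"] = n_tr
    return out
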