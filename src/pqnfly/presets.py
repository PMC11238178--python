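"""Default parameter sets per neuron class and class-pair synaptic scalings.

Parameter sets fitted to whole-cell recordings of each class are not
available in machine-readable form, so the defaults here are the package's
own hand-tuned sets reproducing the documented qualitative
electrophysiology:

* PNs, KCs and MBONs are two-compartment cells (spike-generating axonal
  compartment, passive soma reached through ``I_c``), PNs additionally carry
  the once-per-second homeostatic gain ``u`` (target rate ``F_t``);
* the four LN subclasses are single-compartment Class-I-like spikers with
  graded excitability — NP2426_class1 is the strongest oscillator and
  NP1227_class1 barely participates, matching the reported inactivation
  ranking;
* APL is a slow non-spiking integrator: an almost linear leaky membrane
  (shallow parabola) whose potential crosses the synaptic release threshold
  ``v >= 0`` only a few hundred milliseconds into a strong odor response;
* SMP354 is a single-compartment spiker reading the MBON-α3/MBON-α1 balance.

All spiking classes share one excitable template — an N-shaped fast
nullcline (upward parabola for ``v < 0``, downward for ``v >= 0``) with a
rectified recovery nullcline ``g(v) = a_gp v^2`` for ``v >= 0`` — and differ
in time scales, bias and input gain.  The template rests at ``v = -1.5``,
loses its fixed points at transformed drive 0.25 (Class-I onset) and stays
Euler-stable at the 1 ms step for ``phi/tau <= 300 /s``.

Every magnitude here, and every ``p`` scaling except the documented
``p_PN_KC = 1.03125``, is a package default, overridable from YAML/JSON
(:func:`load_params_yaml`).
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .pqn import PQNParameters
from .synapses import ScalingTable

__all__ = [
    "P_PN_KC",
    "default_params",
    "default_scaling",
    "load_params_yaml",
    "dump_params_yaml",
]

#: documented PN→KC scaling (the learning-robustness sweep's centre value)
P_PN_KC = 1.03125

_SPIKER = dict(
    tau=0.008, phi=2.0, epsilon=0.0,
    I_b0=-0.25, k_I=1.0, m0=-2.0, m1=10.0,
    a_fn=1.0, b_fn=-1.0, c_fn=0.0, a_fp=-1.0,
    a_gn=0.0, b_gn=0.0, c_gn=0.0, a_gp=4.0, r_g=0.0,
    a_hn=0.0, b_hn=0.0, c_hn=0.0, a_hp=1.0, r_h=0.0,
)

_SOMA = dict(theta=1.0, alpha_leak=1.0, I_b1=0.0, k_0=0.1, k_r=1.0)


def default_params() -> dict[str, PQNParameters]:
    """Hand-tuned PQN parameter set per neuron class (LNs by subclass)."""
    pn = PQNParameters(
        **{**_SPIKER, **_SOMA, "I_b0": -0.6},
        kappa=1.6e-5, F_t=4.0,   # kappa/tau = 2e-3 per Hz·s
        variant="pn",
    )
    kc = PQNParameters(
        **{**_SPIKER, **_SOMA, "I_b0": -1.8, "m0": -2.0, "m1": 6.0},
        variant="two_comp",
    )
    mbon = PQNParameters(
        **{**_SPIKER, **_SOMA, "I_b0": -1.0, "m0": -3.0, "m1": 6.0},
        variant="two_comp",
    )
    smp = PQNParameters(
        **{**_SPIKER, "tau": 0.2, "I_b0": -0.8, "m0": -3.0, "m1": 6.0},
        variant="single",
    )
    apl = PQNParameters(
        tau=0.5, phi=1.0, epsilon=0.0,
        I_b0=-1.05, k_I=1.0, m0=0.0, m1=4.0,
        a_fn=0.05, b_fn=10.0, c_fn=-5.0, a_fp=0.05,
        a_gn=0.0, b_gn=0.0, c_gn=0.0, a_gp=1.0, r_g=50.0,
        a_hn=0.0, b_hn=0.0, c_hn=0.0, a_hp=1.0, r_h=50.0,
        variant="single",
    )

    def ln(k_I: float, I_b0: float = -1.3, tau: float = 0.018) -> PQNParameters:
        return PQNParameters(
            **{**_SPIKER, "k_I": k_I, "I_b0": I_b0, "tau": tau},
            variant="single",
        )

    return {
        "PN": pn,
        "KC": kc,
        "MBON_a1": mbon,
        "MBON_a3": replace(mbon),
        "SMP354": smp,
        "APL": apl,
        # excitability ranking drives the oscillation contributions
        "Krasavietz_class1": ln(0.65),
        "Krasavietz_class2": ln(0.55),
        "NP1227_class1": ln(0.35),
        "NP2426_class1": ln(1.45),
    }


def default_scaling() -> ScalingTable:
    """Class-pair synaptic scalings ``p_{x,y}``.

    Signs are fixed by transmitter polarity; the four LN subclasses share
    the single ``LN`` row.  Magnitudes are scaled to the class fan-ins of
    the full network (e.g. each LN pools ~1337 ORN synapses, hence the
    small ``(ORN, LN)`` entry).
    """
    return ScalingTable(p={
        ("ORN", "PN"): 0.8,
        ("ORN", "LN"): 0.012,
        ("PN", "LN"): 0.1,
        ("PN", "KC"): P_PN_KC,
        ("PN", "APL"): 0.04,
        ("LN", "PN"): -0.06,
        ("LN", "LN"): -0.02,
        ("KC", "APL"): 0.18,
        ("KC", "MBON_a1"): 0.45,
        ("KC", "MBON_a3"): 0.45,
        ("APL", "KC"): -2.5,
        ("APL", "MBON_a1"): -3.0,
        ("APL", "MBON_a3"): -3.0,
        ("MBON_a1", "SMP354"): -30.0,
        ("MBON_a3", "SMP354"): 20.0,
    })


_PQN_FIELDS = [f for f in PQNParameters.__dataclass_fields__
               if not f.startswith("b_") and not f.startswith("c_")] + [
    "b_fn", "c_fn", "b_gn", "c_gn", "b_hn", "c_hn"]


def dump_params_yaml(path, params: dict[str, PQNParameters],
                     scaling: ScalingTable | None = None) -> None:
    """Write parameter tables (and optionally p scalings) to YAML."""
    doc: dict = {"neurons": {}}
    for cls, p in params.items():
        doc["neurons"][cls] = {
            f: getattr(p, f) for f in sorted(set(_PQN_FIELDS)) if f != "variant"
        }
        doc["neurons"][cls]["variant"] = p.variant
    if scaling is not None:
        doc["scaling"] = {f"{x}>{y}": v for (x, y), v in scaling.p.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_params_yaml(path) -> tuple[dict[str, PQNParameters], ScalingTable | None]:
    """Read parameter tables keyed by neuron class name from YAML/JSON.

    Derived nullcline coefficients are recomputed, never read.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    params = {}
    for cls, fields in doc["neurons"].items():
        params[cls] = PQNParameters(**fields)
    scaling = None
    if "scaling" in doc:
        p = {}
        for key, v in doc["scaling"].items():
            x, y = key.split(">")
            p[(x, y)] = float(v)
        scaling = ScalingTable(p=p)
    return params, scaling
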