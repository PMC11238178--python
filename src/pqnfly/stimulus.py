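"""ORN firing-rate model, Poisson spike generation, and stimulus protocols.

An ORN expressing receptor *i* fires during odorant *j* at

    r = c * k_j * r_ij + r_spo        [Hz]

where ``r_ij`` in [0, 1] is the receptor's response intensity for the
odorant (DoOR-style), ``k_j`` in [0, 1] an abstract concentration, ``r_spo``
the 8 Hz spontaneous rate, and the gain ``c = 192`` puts the strongest
response at 200 Hz.  Spikes are Bernoulli(r·dt) per 1 ms step.

Three stimulus protocols are used, each preceded by a 300 s warm-up of
protocol-1 stimulation during which PN homeostasis settles:

1. the six-odor panel, each odor 1 s on, one odor every 5 s, cycling;
2. a single odorant, 10 s on every 20 s (oscillation experiments);
3. the six-odor panel, 10 s on every 20 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GAIN",
    "DEFAULT_SPONTANEOUS_HZ",
    "SIX_ODORANTS",
    "ORResponseTable",
    "StimulusProtocol",
    "orn_rate",
    "build_protocol",
    "generate_orn_spikes",
    "generate_synthetic_or_table",
]

DEFAULT_GAIN = 192.0
DEFAULT_SPONTANEOUS_HZ = 8.0

#: the six-odor panel used by the cycling protocols
SIX_ODORANTS = (
    "3-octanol",
    "cis-3-hexenol",
    "cyclohexanone",
    "2,3-butanedione",
    "2-hexanol",
    "ethyl butyrate",
)


@dataclass
class ORResponseTable:
    """Response intensities ``r_ij`` of each OR to each odorant, in [0, 1]."""

    r: pd.DataFrame  # index: OR type, columns: odorant
    k: dict[str, float] = field(default_factory=dict)  # concentration per odorant
    c: float = DEFAULT_GAIN
    r_spo: float = DEFAULT_SPONTANEOUS_HZ

    def __post_init__(self) -> None:
        vals = self.r.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("response intensities must lie in [0, 1]")
        for od in self.r.columns:
            self.k.setdefault(od, 1.0)
        if any(not 0 <= v <= 1 for v in self.k.values()):
            raise ValueError("concentrations k_j must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path, **kw) -> "ORResponseTable":
        return cls(pd.read_csv(path, index_col=0), **kw)

    def to_csv(self, path) -> None:
        self.r.to_csv(path)


def orn_rate(or_type: str, odorant: str | None, table: ORResponseTable) -> float:
    """Firing rate (Hz) of an ORN for the active odorant (None → spontaneous)."""
    if odorant is None:
        return table.r_spo
    r_ij = float(table.r.at[or_type, odorant])
    return table.c * table.k[odorant] * r_ij + table.r_spo


@dataclass
class StimulusProtocol:
    """Odor schedule: (odorant, onset s, duration s) triplets plus warm-up."""

    events: list[tuple[str, float, float]]
    warmup: float = 300.0
    kind: int = 1

    def __post_init__(self) -> None:
        last_end = -np.inf
        prev_onset = -np.inf
        for od, onset, dur in self.events:
            if onset < prev_onset:
                raise ValueError("onsets must be nondecreasing")
            if onset < last_end:
                raise ValueError("odor windows must not overlap")
            prev_onset = onset
            last_end = onset + dur
        self.horizon = last_end if self.events else self.warmup

    def active_odorant(self, t: float) -> str | None:
        for od, onset, dur in self.events:
            if onset <= t < onset + dur:
                return od
            if onset > t:
                break
        return None

    def odorant_per_step(self, n_steps: int, dt: float) -> np.ndarray:
        """Active odorant index per step (-1 = none), odorants in panel order."""
        odorants = sorted({od for od, _, _ in self.events})
        idx = {od: i for i, od in enumerate(odorants)}
        out = np.full(n_steps, -1, dtype=np.int64)
        for od, onset, dur in self.events:
            i0 = int(round(onset / dt))
            i1 = int(round((onset + dur) / dt))
            out[i0: min(i1, n_steps)] = idx[od]
        return out


def build_protocol(
    kind: int,
    odorants,
    warmup: float = 300.0,
    n_cycles: int = 1,
    order: list[list[str]] | None = None,
    warmup_panel=None,
) -> StimulusProtocol:
    """Build one of the three stimulus schedules.

    kind 1 — each odorant of the panel for 1 s, one presentation every 5 s;
    kind 2 — a single odorant for 10 s every 20 s;
    kind 3 — the panel, 10 s on, every 20 s.  The schedule is preceded by
    ``warmup`` seconds of kind-1 cycling over the panel (homeostatic
    settling).  ``n_cycles`` repeats the post-warmup panel; ``order``
    optionally fixes the odorant order per cycle (kind 1/3).
    """
    odorants = list(odorants)
    if kind not in (1, 2, 3):
        raise ValueError("protocol kind must be 1, 2 or 3")
    if kind == 2 and len(odorants) != 1:
        raise ValueError("protocol kind 2 takes exactly one odorant")
    on, period = (1.0, 5.0) if kind == 1 else (10.0, 20.0)

    events: list[tuple[str, float, float]] = []
    t = 0.0
    # warm-up is always kind-1 cycling; by default over the same panel, but
    # single-odorant (kind 2) runs warm up on the full panel when given one
    panel_w = list(warmup_panel) if warmup_panel is not None else odorants
    while t + 1.0 <= warmup:
        od = panel_w[int(t // 5.0) % len(panel_w)]
        events.append((od, t, 1.0))
        t += 5.0
    t = warmup
    for cyc in range(n_cycles):
        panel = order[cyc] if order is not None else odorants
        if sorted(panel) != sorted(odorants):
            raise ValueError("cycle order must be a permutation of the panel")
        for od in panel:
            events.append((od, t, on))
            t += period
    return StimulusProtocol(events=events, warmup=warmup, kind=kind)


def generate_orn_spikes(
    protocol: StimulusProtocol,
    table: ORResponseTable,
    or_types: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> np.ndarray:
    """Bernoulli(r·dt) spike raster, ORNs by steps, over [t_start, t_stop).

    ``or_types`` maps each ORN to its receptor.  Between presentations every
    ORN fires at the spontaneous rate.  Probabilities are clipped at 1 (a
    clip can only occur for r·dt > 1, i.e. r > 1000 Hz at the 1 ms step).
    """
    if t_stop is None:
        t_stop = protocol.horizon
    n_steps = int(round((t_stop - t_start) / dt))
    rates = rate_matrix(protocol, table, or_types, dt, t_start, n_steps)
    p = np.clip(rates * dt, 0.0, 1.0)
    return rng.random((len(or_types), n_steps)) < p


def rate_matrix(protocol, table, or_types, dt, t_start, n_steps) -> np.ndarray:
    """Per-ORN, per-step firing rate (Hz) under the protocol schedule."""
    or_types = np.asarray(or_types)
    rates = np.full((len(or_types), n_steps), table.r_spo)
    uniq, inv = np.unique(or_types, return_inverse=True)
    for od, onset, dur in protocol.events:
        i0 = int(round((onset - t_start) / dt))
        i1 = int(round((onset + dur - t_start) / dt))
        i0, i1 = max(i0, 0), min(i1, n_steps)
        if i1 <= i0:
            continue
        per_or = table.c * table.k[od] * table.r.loc[uniq, od].to_numpy(float) + table.r_spo
        rates[:, i0:i1] = per_or[inv][:, None]
    return rates


def generate_synthetic_or_table(
    n_or: int,
    odorants,
    sparsity: float = 0.25,
    rng: np.random.Generator | None = None,
    strong_lo: float = 0.6,
    weak_hi: float = 0.08,
) -> ORResponseTable:
    """DoOR-like sparse tuning: each odorant strongly drives a distinct OR subset.

    A fraction ``sparsity`` of ORs per odorant respond strongly (uniform in
    [``strong_lo``, 1]); the rest respond weakly (uniform in [0,
    ``weak_hi``]).  Strong sets are drawn independently per odorant, so they
    are distinct with overwhelming probability, giving each odorant a
    distinct sparse representation downstream.
    """
    if n_or < 1:
        raise ValueError("need at least one OR")
    rng = np.random.default_rng() if rng is None else rng
    odorants = list(odorants)
    cols = {}
    n_strong = int(round(sparsity * n_or))
    for od in odorants:
        col = rng.uniform(0.0, weak_hi, size=n_or) * (sparsity > 0)
        strong = rng.choice(n_or, size=n_strong, replace=False)
        col[strong] = rng.uniform(strong_lo, 1.0, size=n_strong)
        if sparsity >= 1.0:
            col = np.ones(n_or)
        elif sparsity <= 0.0:
            col = np.zeros(n_or)
        cols[od] = col
    r = pd.DataFrame(cols, index=[f"OR{i:02d}" for i in range(n_or)])
    return ORResponseTable(r=r)
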