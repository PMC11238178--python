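"""Shared fixtures.

The expensive fixtures (full-size network, homeostatic warm-up) are
session-scoped and shared across the oscillation and learning acceptance
tests; everything else is generated per test at small scale.
"""

from __future__ import annotations

import numpy as np
import pytest

import pqnfly as pf
from pqnfly.engine import SimulationEngine
from pqnfly.stimulus import SIX_ODORANTS, build_protocol
from pqnfly.topology import SynthTopologyConfig

#: warm-up used by the network-level tests; shorter than the 300 s of the
#: full protocol but past the point where the homeostatic gain settles
WARMUP_S = 60.0


@pytest.fixture(scope="session")
def full_network():
    """Full-size synthetic circuit with default parameters."""
    return pf.build_default_network(SynthTopologyConfig(), seed=11)


@pytest.fixture(scope="session")
def warmed_engine(full_network):
    """Engine warmed under protocol-1 cycling, plus its checkpoint."""
    proto = build_protocol(1, SIX_ODORANTS, warmup=WARMUP_S, n_cycles=0)
    eng = SimulationEngine(full_network, seed=5)
    eng.run(WARMUP_S, proto)
    return eng, eng.checkpoint()


@pytest.fixture()
def tiny_cfg():
    return SynthTopologyConfig(n_orn=60, n_pn=10, n_ln=8, n_kc=30, n_glomeruli=6)


@pytest.fixture()
def tiny_network(tiny_cfg):
    return pf.build_default_network(tiny_cfg, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
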