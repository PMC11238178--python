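"""Recording and table input/output.

Recordings go to HDF5 (rasters, LFPs, traces, with dt/seed provenance) or
to flat CSV summaries; weight matrices round-trip as edge-list CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .engine import SimulationRecording
from .synapses import WeightMatrix

__all__ = [
    "recording_to_hdf5",
    "recording_from_hdf5",
    "spikes_to_csv",
    "weights_to_edge_csv",
    "weights_from_edge_csv",
]


def recording_to_hdf5(rec: SimulationRecording, path) -> None:
    """Write a recording (spikes, LFPs, traces) to an HDF5 file."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["dt"] = rec.dt
        fh.attrs["t_start"] = rec.t_start
        fh.attrs["n_steps"] = rec.n_steps
        if rec.seed is not None:
            fh.attrs["seed"] = rec.seed
        fh.create_dataset("spikes/t", data=rec.spike_t)
        fh.create_dataset("spikes/neuron", data=rec.spike_neuron)
        for group, series in rec.lfp.items():
            fh.create_dataset(f"lfp/{group}", data=series)
        for cls, arr in rec.v_traces.items():
            fh.create_dataset(f"v/{cls}", data=arr)
        for cls, arr in rec.vs_traces.items():
            fh.create_dataset(f"v_s/{cls}", data=arr)
        for cls, arr in rec.s_traces.items():
            fh.create_dataset(f"s_mean/{cls}", data=arr)
        if rec.u_mean is not None:
            fh.create_dataset("u_mean", data=rec.u_mean)


def recording_from_hdf5(path) -> SimulationRecording:
    import h5py

    with h5py.File(path, "r") as fh:
        rec = SimulationRecording(
            dt=float(fh.attrs["dt"]),
            t_start=float(fh.attrs["t_start"]),
            n_steps=int(fh.attrs["n_steps"]),
            seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
        )
        rec.spike_t = fh["spikes/t"][:]
        rec.spike_neuron = fh["spikes/neuron"][:]
        for key, target in (("lfp", rec.lfp), ("v", rec.v_traces),
                            ("v_s", rec.vs_traces), ("s_mean", rec.s_traces)):
            if key in fh:
                for name in fh[key]:
                    target[name] = fh[f"{key}/{name}"][:]
        if "u_mean" in fh:
            rec.u_mean = fh["u_mean"][:]
    return rec


def spikes_to_csv(rec: SimulationRecording, path, class_of=None) -> None:
    """Spike events as CSV (t_s, neuron[, class])."""
    df = pd.DataFrame({"t_s": rec.spike_t, "neuron": rec.spike_neuron})
    if class_of is not None:
        df["class"] = np.asarray(class_of)[rec.spike_neuron]
    df.to_csv(path, index=False)


def weights_to_edge_csv(W: WeightMatrix, path) -> None:
    """Weight matrix as an edge list (pre_id, post_id, weight)."""
    coo = W.w.tocoo()
    pd.DataFrame({"pre_id": coo.row, "post_id": coo.col,
                  "weight": coo.data}).to_csv(path, index=False)


def weights_from_edge_csv(path, class_of) -> WeightMatrix:
    edges = pd.read_csv(path)
    n = len(class_of)
    w = sp.csr_matrix(
        (edges["weight"], (edges["pre_id"], edges["post_id"])), shape=(n, n)
    )
    return WeightMatrix(w=w, class_of=np.asarray(class_of, dtype=object))
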