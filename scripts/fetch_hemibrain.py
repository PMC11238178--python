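#!/usr/bin/env python
"""Optional: export neuron and edge tables from the hemibrain v1.2.1 server.

Documents the neuprint queries used to build a connectome-backed network;
requires the `neuprint-python` package and a personal auth token
(https://neuprint.janelia.org).  The packaged tests and the synthetic
generator never need this script — it exists so a connectome-backed run
can be reproduced when network access and credentials are available.

    python scripts/fetch_hemibrain.py --token $NEUPRINT_TOKEN --out-dir data/

writes `neurons.csv` (id, class, glomerulus) and `edges.csv`
(pre_id, post_id, synapse_count) in the layout that
`pqnfly.topology.build_from_connectome` consumes.  Class assignment keys
off hemibrain type names: ORN_* (olfactory receptor neurons, glomerulus in
the type suffix), uPN/mPN types for projection neurons, the local-neuron
types of the antennal lobe, KCa/KCb/KCg for Kenyon cells, APL, MBON14
(α1), MBON11-like α3 types, and bodyId 390003153 for SMP354.
"""

from __future__ import annotations

import argparse


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--token", required=True, help="neuprint auth token")
    ap.add_argument("--server", default="https://neuprint.janelia.org")
    ap.add_argument("--dataset", default="hemibrain:v1.2.1")
    ap.add_argument("--out-dir", default="data")
    args = ap.parse_args()

    try:
        from neuprint import Client, NeuronCriteria, fetch_adjacencies, fetch_neurons
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise SystemExit(
            "neuprint-python is not installed; `pip install neuprint-python` "
            "to use this exporter"
        ) from exc

    import pandas as pd

    client = Client(args.server, dataset=args.dataset, token=args.token)

    type_patterns = {
        "ORN": "ORN_.*",
        "PN": ".*_(ad|l|lv)?PN.*",
        "LN": ".*(lLN|vLN|il3LN|l2LN).*",
        "KC": "KC.*",
        "APL": "APL.*",
        "MBON_a1": "MBON14.*",
        "MBON_a3": "MBON11.*",
    }
    frames = []
    for cls, pattern in type_patterns.items():
        criteria = NeuronCriteria(type=pattern, regex=True)
        neurons, _ = fetch_neurons(criteria, client=client)
        neurons = neurons[["bodyId", "type", "instance"]].copy()
        neurons["class"] = cls
        frames.append(neurons)
    # SMP354: the specific UpWiN-cluster neuron, addressed by body id
    smp, _ = fetch_neurons(NeuronCriteria(bodyId=390003153), client=client)
    smp = smp[["bodyId", "type", "instance"]].copy()
    smp["class"] = "SMP354"
    frames.append(smp)

    table = pd.concat(frames, ignore_index=True)
    table["glomerulus"] = table["type"].str.extract(r"ORN_([A-Za-z0-9]+)")
    table = table.rename(columns={"bodyId": "id"})[["id", "class", "glomerulus"]]

    _, conn = fetch_adjacencies(
        sources=table["id"].tolist(), targets=table["id"].tolist(), client=client
    )
    edges = conn.rename(columns={
        "bodyId_pre": "pre_id", "bodyId_post": "post_id", "weight": "synapse_count",
    })[["pre_id", "post_id", "synapse_count"]]

    import pathlib

    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "neurons.csv", index=False)
    edges.to_csv(out / "edges.csv", index=False)
    print(f"wrote {len(table)} neurons, {len(edges)} edges to {out}/")


if __name__ == "__main__":
    main()
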