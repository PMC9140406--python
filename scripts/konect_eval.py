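#!/usr/bin/env python
"""Evaluate on real KONECT affiliation datasets (requires a download).

The five small bipartite datasets this tool targets are distributed by
the KONECT project as tar.bz2 archives containing an ``out.<name>``
edge-list file.  Download and unpack one (network access is required;
none of the package's tests depend on this script), then run e.g.:

    python scripts/konect_eval.py out.brunson_club-membership \
        --k 1 --seeds 0,1,2

Reports mean test RMSE/MAE over the seeds for qualitative comparison
with published results on these datasets.
"""

from __future__ import annotations

import argparse

import numpy as np

from dlplink import TrainConfig, read_edge_list, run_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("edge_list", help="path to an unpacked KONECT out.* file")
    parser.add_argument("--k", type=int, default=1)
    parser.add_argument("--seeds", default="0,1,2")
    parser.add_argument("--epochs", type=int, default=80)
    args = parser.parse_args()

    net = read_edge_list(args.edge_list)
    print(f"{args.edge_list}: |U|={net.n_u} |V|={net.n_v} edges={net.n_edges}")
    config = TrainConfig(epochs=args.epochs)
    maes, rmses = [], []
    for seed in (int(s) for s in args.seeds.split(",")):
        res = run_experiment(net, args.k, config, seed=seed)
        print(f"  seed {seed}: rmse={res.rmse:.4f} mae={res.mae:.4f} n={res.n_samples}")
        rmses.append(res.rmse)
        maes.append(res.mae)
    print(f"mean over seeds: rmse={np.mean(rmses):.4f} mae={np.mean(maes):.4f}")


if __name__ == "__main__":
    main()
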