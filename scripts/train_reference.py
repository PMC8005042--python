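#!/usr/bin/env python
"""Train the multi-GNN regressors on a user-supplied inhibitor dataset.

Intended for the curated DHODH inhibitor compounds (CSV with columns
``id,smiles,ic50_nM`` or ``id,smiles,pic50``), which are not distributed with
this package. For each requested architecture the dataset is split 8:2,
trained under the standard protocol for several seeds, and the seed-averaged
train/test RMSE and R^2 are reported.

Usage:
    python scripts/train_reference.py --data compounds.csv [--seeds 3]
        [--architectures GIAN GIAT SGCA] [--out metrics.json]
"""

from __future__ import annotations

import argparse
import json

import numpy as np

from multignn.featurization import read_compounds_csv
from multignn.models import ModelConfig
from multignn.training import TrainConfig, fit


def run(data_path, seeds: int = 3, architectures=("GIAN", "GIAT", "SGCA"),
        max_epochs: int = 1000, patience: int = 60) -> dict:
    dataset = read_compounds_csv(data_path)
    report: dict[str, dict] = {"n_compounds": len(dataset), "models": {}}
    for arch in architectures:
        runs = []
        for seed in range(seeds):
            _, metrics = fit(dataset,
                             ModelConfig(architecture=arch, seed=seed),
                             TrainConfig(seed=seed, max_epochs=max_epochs,
                                         patience=patience))
            runs.append(metrics)
        report["models"][arch] = {
            key: float(np.mean([r[key] for r in runs]))
            for key in ("rmse_train", "rmse_test", "r2_train", "r2_test")
        } | {"seeds": seeds, "epochs_run": [r["epochs_run"] for r in runs]}
    return report


def main(argv=None) -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", required=True,
                        help="compounds CSV (id,smiles,ic50_nM or pic50)")
    parser.add_argument("--seeds", type=int, default=3)
    parser.add_argument("--architectures", nargs="+",
                        default=["GIAN", "GIAT", "SGCA"])
    parser.add_argument("--max-epochs", type=int, default=1000)
    parser.add_argument("--patience", type=int, default=60)
    parser.add_argument("--out", default=None, help="write metrics JSON here")
    args = parser.parse_args(argv)
    report = run(args.data, seeds=args.seeds,
                 architectures=args.architectures,
                 max_epochs=args.max_epochs, patience=args.patience)
    print(json.dumps(report, indent=2))
    if args.out:
        with open(args.out, "w") as fh:
            json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
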