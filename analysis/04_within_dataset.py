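#!/usr/bin/env python
"""Within-dataset evaluation: grouped 10-fold CV on each source alone.

Trains and tests the class-weighted SVM and ANN separately on each
synthetic source (standard, non-normalized features, mirroring the
within-source design where normalization brought no gain), using that
source's own selected feature subset.  Writes results/within_dataset.csv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from wristfall import evaluation as ev  # noqa: E402

SEED = 0


def selected_for(name: str) -> list[str]:
    path = ROOT / "results" / "selection" / f"{name}_selected.txt"
    return path.read_text().strip().splitlines()


def main() -> None:
    warnings.filterwarnings("ignore")
    feats = pd.read_csv(ROOT / "scratch" / "features.csv")
    rows = []
    for dataset in sorted(feats["dataset"].unique()):
        cfg = ev.ExperimentConfig(k=10, seed=SEED,
                                  selected_features=selected_for(dataset))
        for model in ("svm", "ann"):
            rep = ev.run_within_dataset(feats, dataset, model, cfg)
            agg = rep.aggregates
            row = {"dataset": dataset, "model": model}
            for m in ("recall", "specificity", "auc_roc", "f1"):
                row[f"{m}_pct"] = round(100 * agg.loc[m, "mean"], 2)
                row[f"{m}_std"] = round(100 * agg.loc[m, "std"], 2)
            rows.append(row)
            print(f"{dataset:8s} {model}: "
                  + "  ".join(f"{m}={row[f'{m}_pct']:.2f}±"
                              f"{row[f'{m}_std']:.2f}"
                              for m in ("recall", "specificity",
                                        "auc_roc", "f1")))
    out = ROOT / "results" / "within_dataset.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
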