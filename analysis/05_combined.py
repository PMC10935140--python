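#!/usr/bin/env python
"""Combined-corpus evaluation, with and without [-1, 1] normalization.

Grouped 10-fold CV of the weighted SVM and ANN on all three sources
pooled, contrasting the standard feature matrix against the per-dataset
normalized one (same seed, hence identical fold assignments).  Writes
results/combined.csv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from wristfall import evaluation as ev  # noqa: E402

SEED = 0


def main() -> None:
    warnings.filterwarnings("ignore")
    selected = (ROOT / "results" / "selection" / "combined_selected.txt"
                ).read_text().strip().splitlines()
    cfg = ev.ExperimentConfig(k=10, seed=SEED, selected_features=selected)
    rows = []
    for tag, path in (("standard", "features.csv"),
                      ("normalized", "features_normalized.csv")):
        feats = pd.read_csv(ROOT / "scratch" / path)
        for model in ("svm", "ann"):
            rep = ev.run_combined(feats, model, cfg,
                                  normalization_mode=tag)
            agg = rep.aggregates
            row = {"variant": tag, "model": model}
            for m in ("recall", "specificity", "auc_roc", "f1"):
                row[f"{m}_pct"] = round(100 * agg.loc[m, "mean"], 2)
                row[f"{m}_std"] = round(100 * agg.loc[m, "std"], 2)
            rows.append(row)
            print(f"{tag:10s} {model}: "
                  + "  ".join(f"{m}={row[f'{m}_pct']:.2f}±"
                              f"{row[f'{m}_std']:.2f}"
                              for m in ("recall", "specificity",
                                        "auc_roc", "f1")))
    out = ROOT / "results" / "combined.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
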