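#!/usr/bin/env python
"""Cross-dataset generalization: train on one source, test on the rest.

For each source, selects features on that source alone, trains the
weighted SVM and ANN on all of it, and evaluates once on the pooled
held-out sources — for both the standard and normalized feature variants.
Writes the generalization matrix to results/generalization.csv.
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
    rows = []
    for tag, path in (("standard", "features.csv"),
                      ("normalized", "features_normalized.csv")):
        feats = pd.read_csv(ROOT / "scratch" / path)
        names = sorted(feats["dataset"].unique())
        for train in names:
            selected = (ROOT / "results" / "selection" /
                        f"{train}_selected.txt"
                        ).read_text().strip().splitlines()
            cfg = ev.ExperimentConfig(seed=SEED,
                                      selected_features=selected)
            rest = [d for d in names if d != train]
            for model in ("svm", "ann"):
                rep = ev.run_cross_dataset(feats, train, rest, model, cfg,
                                           normalization_mode=tag)
                fm = rep.fold_metrics.iloc[0]
                row = {"variant": tag, "train": train, "model": model}
                for m in ("recall", "specificity", "auc_roc", "f1"):
                    row[f"{m}_pct"] = round(100 * fm[m], 3)
                rows.append(row)
                print(f"{tag:10s} train={train:8s} {model}: "
                      + "  ".join(f"{m}={row[f'{m}_pct']:.2f}"
                                  for m in ("recall", "specificity",
                                            "auc_roc", "f1")))
    out = ROOT / "results" / "generalization.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
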