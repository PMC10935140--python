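#!/usr/bin/env python
"""Acceleration-magnitude threshold baseline vs the learned detectors.

Evaluates the classic fixed-threshold rule (window is a fall iff its peak
acceleration norm reaches 2.5 g) on the raw harmonized corpus and compares
its balanced operating point against the cross-validated learned models
from the combined experiment.  Writes results/baseline_comparison.csv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from wristfall import evaluation as ev, pipeline  # noqa: E402
from wristfall.harmonize import read_manifest  # noqa: E402

CORPUS_DIR = ROOT / "scratch" / "corpus"


def main() -> None:
    warnings.filterwarnings("ignore")
    corpus = pipeline.harmonize_and_featurize(
        read_manifest(CORPUS_DIR / "manifest.csv"), CORPUS_DIR)
    rows = []
    for threshold in (1.8, 2.5, 3.0):
        out = ev.run_threshold_baseline(corpus.recordings,
                                        threshold=threshold)
        rows.append({"detector": f"threshold_{threshold:.1f}g",
                     "recall_pct": round(100 * out["recall"], 2),
                     "specificity_pct": round(100 * out["specificity"], 2),
                     "min_sesp_pct": round(100 * out["min_sesp"], 2),
                     "max_sesp_pct": round(100 * out["max_sesp"], 2),
                     "auc_roc_pct": round(100 * out["auc_roc"], 2)})
        print(rows[-1])
    combined = pd.read_csv(ROOT / "results" / "combined.csv")
    learned = combined[combined["variant"] == "standard"]
    print("learned models on the same corpus (combined CV):")
    print(learned[["model", "recall_pct", "specificity_pct",
                   "auc_roc_pct"]].to_string(index=False))
    out_path = ROOT / "results" / "baseline_comparison.csv"
    pd.DataFrame(rows).to_csv(out_path, index=False)
    print(f"wrote {out_path}")


if __name__ == "__main__":
    main()
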