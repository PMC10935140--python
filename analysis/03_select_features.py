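#!/usr/bin/env python
"""Two-stage random-forest feature selection on every training matrix.

Runs Gini ranking + one-at-a-time exclusion on each single source and on
the combined corpus (standard variant; the experiments reuse the same
subsets for the normalized variant so the comparison isolates scaling).
Writes one SelectionReport JSON and one plain-text selected-feature list
per matrix under results/selection/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from wristfall import selection as sel  # noqa: E402
from wristfall.features import FEATURE_COLUMNS  # noqa: E402

SEED = 0
OUT = ROOT / "results" / "selection"


def main() -> None:
    feats = pd.read_csv(ROOT / "scratch" / "features.csv")
    OUT.mkdir(parents=True, exist_ok=True)
    matrices = {"combined": feats}
    for name, group in feats.groupby("dataset"):
        matrices[name] = group.reset_index(drop=True)
    for name, frame in matrices.items():
        report = sel.select_features(
            frame[list(FEATURE_COLUMNS)], frame["label"].to_numpy(),
            groups=list(zip(frame["dataset"], frame["subject"])),
            seed=SEED)
        report.to_json(OUT / f"{name}.json")
        report.write_selected(OUT / f"{name}_selected.txt")
        top = ", ".join(f for f, _ in report.gini_ranking[:5])
        print(f"{name}: kept {len(report.selected)}/78 features "
              f"(top ranked: {top})")


if __name__ == "__main__":
    main()
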