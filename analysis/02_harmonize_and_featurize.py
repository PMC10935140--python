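#!/usr/bin/env python
"""Harmonize the raw corpus and extract the window feature matrix.

Reads scratch/corpus/ (raw per-source dialects), unifies units to g and
rad/s, resamples everything to 18 Hz, drops files containing non-finite
values, and extracts 2 s / 50%-overlap windows with 78 features each.
Two variants are written: the standard matrix (scratch/features.csv) and
the per-dataset [-1, 1]-normalized matrix (scratch/features_normalized.csv).
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from wristfall import pipeline  # noqa: E402
from wristfall.harmonize import read_manifest  # noqa: E402

CORPUS_DIR = ROOT / "scratch" / "corpus"


def main() -> None:
    manifest = read_manifest(CORPUS_DIR / "manifest.csv")
    for tag, mode in (("features", "off"),
                      ("features_normalized", "per_dataset")):
        corpus = pipeline.harmonize_and_featurize(manifest, CORPUS_DIR,
                                                  normalization=mode)
        out = ROOT / "scratch" / f"{tag}.csv"
        corpus.features.to_csv(out, index=False)
        labels = corpus.features["label"]
        print(f"{tag}: {len(corpus.features)} windows "
              f"({100 * labels.mean():.2f}% falls) -> {out}")
        if mode != "off":
            corpus.normalization.to_json(
                ROOT / "scratch" / "normalization_params.json")


if __name__ == "__main__":
    main()
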