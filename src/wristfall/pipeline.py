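"""End-to-end orchestration: generate -> harmonize -> featurize.

Thin glue used by the analysis scripts, the test suite and the acceptance
harness so every entry point exercises the same code path: write the
synthetic corpus to disk in its raw per-source dialects, harmonize it back
through the full file round trip (unit conversion, resampling, NaN-file
removal, optional normalization), and extract the window feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import harmonize as _harmonize
from . import synthetic_data as _synth
from .features import WindowSpec, extract_corpus_features


@dataclass
class Corpus:
    """A harmonized corpus plus its window feature matrix."""

    manifest: pd.DataFrame
    recordings: list[_harmonize.ImuRecording]
    features: pd.DataFrame
    normalization: _harmonize.NormalizationParams
    base_dir: Path | None = None


def build_corpus(out_dir: Path | str,
                 config: _synth.GeneratorConfig | None = None,
                 seed: int = 0, normalization: str = "off",
                 spec: WindowSpec | None = None) -> Corpus:
    """Generate the synthetic corpus on disk and run it through the full
    harmonization + feature-extraction path."""
    config = config or _synth.default_config(seed=seed)
    manifest = _synth.generate_dataset(config, out_dir)
    return harmonize_and_featurize(manifest, out_dir,
                                   normalization=normalization, spec=spec)


def harmonize_and_featurize(manifest: pd.DataFrame, base_dir: Path | str,
                            normalization: str = "off",
                            spec: WindowSpec | None = None) -> Corpus:
    recordings, params = _harmonize.harmonize_corpus(
        manifest, base_dir, normalization=normalization)
    features = extract_corpus_features(recordings, spec or WindowSpec())
    return Corpus(manifest=manifest, recordings=recordings,
                  features=features, normalization=params,
                  base_dir=Path(base_dir))
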