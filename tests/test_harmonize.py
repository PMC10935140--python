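"""Harmonization: filename codec, units, resampling, NaN policy, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from wristfall import harmonize as hz


def _recording(rate=18.0, duration=10.0, channel_fn=None, labels=None,
               dataset="D", subject=1):
    n = int(duration * rate)
    t = np.arange(n) / rate
    values = channel_fn(t) if channel_fn else np.ones(n)
    acc = np.column_stack([values, 2 * values, -values])
    gyr = np.column_stack([0.5 * values, values, 0.1 * values])
    lab = labels if labels is not None else np.zeros(n, dtype=int)
    return hz.ImuRecording(dataset=dataset, subject=subject, activity=1,
                           trial=1, sample_rate=rate, time=t, acc=acc,
                           gyr=gyr, labels=lab)


# --- filename codec --------------------------------------------------------

def test_parse_filename_example():
    assert hz.parse_filename("UMA_Subject03_Activity14_Trial02") == \
        ("UMA", 3, 14, 2)


@given(st.text(alphabet=st.characters(whitelist_categories=("Lu", "Ll"),
                                      max_codepoint=127), min_size=1,
               max_size=12),
       st.integers(0, 99), st.integers(0, 99), st.integers(0, 99))
def test_filename_roundtrip(dataset, subject, activity, trial):
    name = hz.format_filename(dataset, subject, activity, trial)
    assert hz.parse_filename(name) == (dataset, subject, activity, trial)


@pytest.mark.parametrize("bad", ["UMA_Subj3_Act14", "Subject01_Trial02",
                                 "UMA_Subject3_Activity14_Trial02", ""])
def test_parse_filename_rejects_malformed(bad):
    with pytest.raises(hz.FilenameError):
        hz.parse_filename(bad)


# --- unit conversion -------------------------------------------------------

@pytest.mark.parametrize("value,quantity,units,expected", [
    (9.80665, "acceleration", "m/s2", 1.0),
    (180.0, "angular_velocity", "deg/s", np.pi),
    (0.5, "acceleration", "g", 0.5),
    (2.0, "angular_velocity", "rad/s", 2.0),
])
def test_convert_units_examples(value, quantity, units, expected):
    assert hz.convert_units(value, quantity, units) == \
        pytest.approx(expected, rel=1e-12)


def test_convert_units_rejects_unknown():
    with pytest.raises(ValueError):
        hz.convert_units(1.0, "acceleration", "furlongs")
    with pytest.raises(ValueError):
        hz.convert_units(1.0, "temperature", "K")


@given(st.floats(-1e4, 1e4, allow_nan=False),
       st.sampled_from([("acceleration", "m/s2"),
                        ("angular_velocity", "deg/s")]))
def test_unit_roundtrip(value, qu):
    quantity, units = qu
    canonical = hz.convert_units(value, quantity, units)
    back = hz.convert_units_back(canonical, quantity, units)
    assert back == pytest.approx(value, rel=1e-12, abs=1e-12)


# --- resampling ------------------------------------------------------------

def test_resample_identity_at_target_rate():
    rec = _recording(rate=18.0)
    out = hz.resample_recording(rec, 18.0)
    np.testing.assert_array_equal(out.acc, rec.acc)
    np.testing.assert_array_equal(out.labels, rec.labels)


def test_resample_grid_length_50hz_10s():
    # exactly 10 s span at 50 Hz -> floor(10 * 18) + 1 samples at 18 Hz
    rec = _recording(rate=50.0, duration=10.02)  # 501 samples, span 10 s
    assert rec.time[-1] == pytest.approx(10.0)
    out = hz.resample_recording(rec, 18.0)
    assert out.n_samples == 181


def test_resample_constant_channel_exact():
    rec = _recording(rate=50.0, channel_fn=lambda t: np.full_like(t, 3.3))
    out = hz.resample_recording(rec, 18.0)
    np.testing.assert_allclose(out.acc[:, 0], 3.3, rtol=1e-12)


def test_resample_affine_signal_exact():
    rec = _recording(rate=20.0, channel_fn=lambda t: 0.7 + 2.1 * t)
    out = hz.resample_recording(rec, 18.0)
    np.testing.assert_allclose(out.acc[:, 0], 0.7 + 2.1 * out.time,
                               rtol=1e-12)


def test_resample_preserves_duration_within_one_period():
    for rate in (20.0, 50.0):
        rec = _recording(rate=rate, duration=15.0)
        out = hz.resample_recording(rec, 18.0)
        assert abs(out.time[-1] - rec.time[-1]) <= 1.0 / 18.0


def test_resample_labels_nearest():
    n = 100
    labels = np.zeros(n, dtype=int)
    labels[40:60] = 1
    rec = _recording(rate=50.0, duration=2.0, labels=labels)
    out = hz.resample_recording(rec, 18.0)
    for t, lab in zip(out.time, out.labels):
        assert lab == labels[min(round(t * 50), n - 1)]
    assert out.labels.sum() > 0


def test_resample_rejects_bad_target():
    with pytest.raises(ValueError):
        hz.resample_recording(_recording(), target_rate=0.0)


# --- NaN-file removal ------------------------------------------------------

def _write_corpus(tmp_path, n_files=10, poison=None):
    rows = []
    for i in range(n_files):
        rec = _recording(subject=i + 1)
        name = hz.format_filename("D", i + 1, 1, 1) + ".csv"
        hz.write_trial_csv(rec, tmp_path / name)
        rows.append({"dataset": "D", "subject": i + 1, "activity": 1,
                     "trial": 1, "path": name, "sample_rate_hz": 18.0,
                     "acc_units": "g", "gyr_units": "rad/s",
                     "is_fall_activity": 0})
    if poison is not None:
        path, column = poison
        df = pd.read_csv(tmp_path / path)
        df.loc[3, column] = np.nan
        df.to_csv(tmp_path / path, index=False)
    return pd.DataFrame(rows)


def test_drop_invalid_removes_nan_file(tmp_path):
    manifest = _write_corpus(tmp_path,
                             poison=("D_Subject04_Activity01_Trial01.csv",
                                     "acc_y"))
    kept = hz.drop_invalid(manifest, tmp_path)
    assert len(kept) == 9
    assert 4 not in set(kept["subject"])


def test_drop_invalid_noop_when_clean(tmp_path):
    manifest = _write_corpus(tmp_path)
    kept = hz.drop_invalid(manifest, tmp_path)
    pd.testing.assert_frame_equal(kept, manifest)


def test_drop_invalid_counts_label_column(tmp_path):
    manifest = _write_corpus(tmp_path,
                             poison=("D_Subject02_Activity01_Trial01.csv",
                                     "label"))
    assert len(hz.drop_invalid(manifest, tmp_path)) == 9


def test_drop_invalid_missing_file(tmp_path):
    manifest = _write_corpus(tmp_path)
    (tmp_path / "D_Subject01_Activity01_Trial01.csv").unlink()
    assert len(hz.drop_invalid(manifest, tmp_path)) == 9


# --- normalization ---------------------------------------------------------

def test_normalize_affine_endpoints():
    values = np.linspace(-2.0, 2.0, 36)
    rec = _recording(channel_fn=lambda t: values, duration=2.0)
    normed, params = hz.normalize_dataset([rec], mode="per_dataset")
    # [-2, 2] g maps affinely onto [-1, 1]: -2 -> -1, 0 -> 0, +2 -> +1
    np.testing.assert_allclose(normed[0].acc[:, 0], values / 2.0,
                               atol=1e-12)


def test_normalize_per_dataset_hits_unit_range(small_corpus):
    normed, _ = hz.normalize_dataset(small_corpus.recordings,
                                     mode="per_dataset")
    by_dataset = {}
    for rec in normed:
        by_dataset.setdefault(rec.dataset, []).append(rec.channels)
    for name, chunks in by_dataset.items():
        stacked = np.vstack(chunks)
        np.testing.assert_allclose(stacked.min(axis=0), -1.0, atol=1e-12)
        np.testing.assert_allclose(stacked.max(axis=0), 1.0, atol=1e-12)


def test_normalize_constant_channel_maps_to_zero():
    rec = _recording(channel_fn=lambda t: np.full_like(t, 5.0))
    normed, _ = hz.normalize_dataset([rec], mode="per_dataset")
    np.testing.assert_allclose(normed[0].channels, 0.0)


def test_normalize_idempotent():
    rng = np.random.default_rng(0)
    rec = _recording(channel_fn=lambda t: rng.normal(size=t.size))
    once, _ = hz.normalize_dataset([rec], mode="per_dataset")
    twice, _ = hz.normalize_dataset(once, mode="per_dataset")
    np.testing.assert_allclose(twice[0].channels, once[0].channels,
                               atol=1e-12)


def test_normalize_fit_on_train_applies_train_range():
    train = _recording(channel_fn=lambda t: np.linspace(0, 2, t.size))
    test = _recording(channel_fn=lambda t: np.full_like(t, 4.0),
                      dataset="other")
    scaled, params = hz.normalize_dataset([test], mode="fit_on_train",
                                          fit_recordings=[train])
    # 4.0 is outside the fitted [0, 2] range -> maps beyond +1
    assert scaled[0].acc[:, 0].max() > 1.0
    assert params.mode == "fit_on_train"


def test_normalize_rejects_empty():
    with pytest.raises(ValueError):
        hz.normalize_dataset([], mode="per_dataset")
    with pytest.raises(ValueError):
        hz.fit_normalization([_recording()], mode="bogus")


def test_normalization_params_json_roundtrip(tmp_path):
    _, params = hz.normalize_dataset([_recording()], mode="per_dataset")
    params.to_json(tmp_path / "norm.json")
    back = hz.NormalizationParams.from_json(tmp_path / "norm.json")
    assert back.mode == params.mode
    for key in params.ranges:
        np.testing.assert_allclose(back.ranges[key][0],
                                   params.ranges[key][0])
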