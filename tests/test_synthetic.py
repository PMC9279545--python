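"""Tests for the synthetic EEG generator and the dataset readers."""

import numpy as np
import pytest
from scipy.signal import periodogram

from ledpatnet.datasets import read_dreamer, read_gameemo, write_dreamer, write_gameemo
from ledpatnet.synthetic import (
    BANDS,
    CHANNELS,
    SyntheticSpec,
    generate_dataset,
    generate_signals,
)

SMALL = dict(n_subjects=2, signal_length=6000, frame_length=1500)


class TestGenerator:
    def test_default_structure_counts(self):
        spec = SyntheticSpec(n_subjects=1, n_channels=3)
        data = generate_dataset(spec)
        assert set(data) == set(CHANNELS[:3])
        # 1 subject x 4 classes x floor(38252/7650) = 5 frames
        assert all(len(frames) == 4 * 5 for frames in data.values())
        labels = {f.label for f in data["AF3"]}
        assert labels == set(spec.classes)
        assert all(len(f) == 7650 for f in data["AF3"])

    def test_seed_reproducibility(self):
        spec = SyntheticSpec(seed=5, **SMALL)
        a = generate_dataset(spec)
        b = generate_dataset(spec)
        for ch in a:
            for fa, fb in zip(a[ch], b[ch]):
                np.testing.assert_array_equal(fa.samples, fb.samples)

    def test_channel_subset_draws_are_consistent(self):
        spec = SyntheticSpec(seed=5, **SMALL)
        full = generate_dataset(spec)
        only = generate_dataset(spec, channels=("F3",))
        for fa, fb in zip(full["F3"], only["F3"]):
            np.testing.assert_array_equal(fa.samples, fb.samples)

    def test_noiseless_band_powers_match_profiles(self):
        spec = SyntheticSpec(
            n_subjects=1, n_channels=1, noise_sd=0.0, signal_length=38_252, seed=3
        )
        signals = generate_signals(spec)
        for cls, profile in spec.band_profiles.items():
            sig = signals[0][cls]["AF3"]
            # Hann window keeps leakage negligible; bands partition [0, 45]
            f, pxx = periodogram(sig, fs=spec.rate, window="hann")
            df = f[1] - f[0]
            measured = []
            for lo, hi in BANDS.values():
                sel = (f >= lo) & (f < hi)
                measured.append(np.sum(pxx[sel]) * df)
            measured = np.array(measured) / sum(measured)
            expected = np.array(profile) / sum(profile)
            np.testing.assert_allclose(measured, expected, atol=0.03)

    def test_degenerate_identical_profiles_warn(self, caplog):
        with caplog.at_level("WARNING"):
            SyntheticSpec(
                band_profiles={"a": (1, 1, 1, 1, 1), "b": (1, 1, 1, 1, 1)}, **SMALL
            )
        assert "identical band profiles" in caplog.text

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_channels=0),
            dict(ar_coefficient=1.0),
            dict(band_profiles={"only": (1, 1, 1, 1, 1)}),
            dict(band_profiles={"a": (1, 1, 1), "b": (2, 1, 1)}),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            SyntheticSpec(**bad)


class TestGameemoReader:
    def test_round_trip_against_generator(self, tmp_path):
        spec = SyntheticSpec(seed=9, n_channels=3, **SMALL)
        signals = generate_signals(spec)
        write_gameemo(signals, tmp_path)
        data = read_gameemo(tmp_path, frame_length=spec.frame_length)
        direct = generate_dataset(spec)
        assert set(data) == set(CHANNELS[:3])
        for ch in data:
            assert len(data[ch]) == len(direct[ch])
            got = sorted(data[ch], key=lambda f: (str(f.label), f.samples[0]))
            want = sorted(direct[ch], key=lambda f: (str(f.label), f.samples[0]))
            for fa, fb in zip(got, want):
                assert fa.label == fb.label
                np.testing.assert_allclose(fa.samples, fb.samples)

    def test_mini_csv_framing(self, tmp_path, rng):
        df = {ch: rng.normal(size=15_300) for ch in ("AF3", "F7", "O1")}
        import pandas as pd

        pd.DataFrame(df).to_csv(tmp_path / "S01G2AllChannels.csv", index=False)
        data = read_gameemo(tmp_path, frame_length=7650)
        assert set(data) == {"AF3", "F7", "O1"}
        assert all(len(frames) == 2 for frames in data.values())
        assert data["AF3"][0].label == "calm"

    def test_per_channel_file_layout(self, tmp_path, rng):
        import pandas as pd

        pd.DataFrame({"value": rng.normal(size=200)}).to_csv(
            tmp_path / "S01G4_FC6.csv", index=False
        )
        data = read_gameemo(tmp_path, frame_length=100)
        assert list(data) == ["FC6"]
        assert data["FC6"][0].label == "funny"

    def test_malformed_header_names_columns(self, tmp_path, rng):
        import pandas as pd

        pd.DataFrame({"foo": [1.0], "bar": [2.0]}).to_csv(
            tmp_path / "S01G1.csv", index=False
        )
        with pytest.raises(ValueError, match="foo"):
            read_gameemo(tmp_path)

    def test_missing_files_explicit_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_gameemo(tmp_path / "empty")


class TestDreamerReader:
    @pytest.fixture
    def mat_path(self, tmp_path, rng):
        trials = [rng.normal(size=(400, 14)), rng.normal(size=(350, 14))]
        scores = {"arousal": [4, 2], "dominance": [1, 5], "valence": [3, 3]}
        path = tmp_path / "synthetic_dreamer.mat"
        write_dreamer(path, trials, scores)
        return path

    def test_two_trials_per_channel_with_labels(self, mat_path):
        data = read_dreamer(mat_path, "arousal", threshold=3)
        assert set(data) == set(CHANNELS)
        assert [f.label for f in data["AF3"]] == ["high", "low"]
        assert [len(f) for f in data["AF3"]] == [400, 350]

    def test_threshold_at_max_rating_gives_all_low(self, mat_path):
        data = read_dreamer(mat_path, "dominance", threshold=6)
        assert {f.label for ch in data.values() for f in ch} == {"low"}

    def test_case_spelling_normalization(self, mat_path):
        a = read_dreamer(mat_path, "valence", threshold=3)
        b = read_dreamer(mat_path, "Valance", threshold=3)
        assert [f.label for f in a["T8"]] == [f.label for f in b["T8"]]

    def test_unknown_case_rejected(self, mat_path):
        with pytest.raises(ValueError, match="case"):
            read_dreamer(mat_path, "happiness", threshold=3)
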