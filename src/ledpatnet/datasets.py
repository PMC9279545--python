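"""Readers (and fixture writers) for the two public EEG emotion corpora.

GAMEEMO-style data are per-subject, per-game CSV files with one column per
channel ("all channels" layout) or one single-column file per channel; the
game number encodes the emotion class. DREAMER-style data are a single MAT
container holding per-trial 14-channel EEG plus per-trial self-ratings of
arousal, dominance and valence, binarized here against a caller-supplied
threshold (the corpus itself prescribes none).

The writer halves exist so the readers are testable offline: they emit the
same on-disk layouts from synthetic recordings.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
from numpy.typing import NDArray

from .fusion import DEFAULT_FRAME_LENGTH, EEGFrame, segment_frames
from .synthetic import CHANNELS

__all__ = ["read_gameemo", "write_gameemo", "read_dreamer", "write_dreamer"]

#: Game number -> emotion class, following the corpus' G1..G4 coding.
GAME_LABELS = {1: "boring", 2: "calm", 3: "horror", 4: "funny"}

_CASES = {
    "arousal": "ScoreArousal",
    "dominance": "ScoreDominance",
    "valence": "ScoreValence",
    "valance": "ScoreValence",  # the common alternate spelling
}


def _game_label(path: Path) -> str:
    m = re.search(r"G(\d)", path.stem)
    if not m or int(m.group(1)) not in GAME_LABELS:
        raise ValueError(
            f"cannot infer the game class from file name {path.name!r}; "
            "expected a 'G1'..'G4' token"
        )
    return GAME_LABELS[int(m.group(1))]


def read_gameemo(
    directory: str | Path,
    frame_length: int = DEFAULT_FRAME_LENGTH,
    rate: float = 128.0,
) -> dict[str, list[EEGFrame]]:
    """Load a GAMEEMO-style directory into per-channel frame collections.

    Both published layouts are accepted: CSVs with one column per channel
    (column names drawn from the 14-channel montage) or single-column CSVs
    named after their channel. Class labels come from the ``G<n>`` token in
    each file name. Recordings are segmented at ``frame_length``.
    """
    directory = Path(directory)
    files = sorted(directory.rglob("*.csv"))
    if not files:
        raise FileNotFoundError(
            f"no CSV files under {directory}; expected per-subject per-game "
            "channel files"
        )
    dataset: dict[str, list[EEGFrame]] = {}
    for path in files:
        label = _game_label(path)
        df = pd.read_csv(path)
        known = [c for c in df.columns if c.strip() in CHANNELS]
        if known:
            channel_series = {c.strip(): df[c] for c in known}
        elif len(df.columns) == 1:
            stem_channels = [c for c in CHANNELS if c in path.stem]
            if not stem_channels:
                raise ValueError(
                    f"{path.name}: single-column file but no channel name "
                    f"in the file name; expected one of {CHANNELS}"
                )
            channel_series = {stem_channels[0]: df[df.columns[0]]}
        else:
            raise ValueError(
                f"{path.name}: no recognizable channel columns among "
                f"{list(df.columns)}; expected names from {CHANNELS}"
            )
        for channel, series in channel_series.items():
            frames = segment_frames(
                series.to_numpy(dtype=float),
                frame_length,
                channel=channel,
                rate=rate,
                label=label,
            )
            dataset.setdefault(channel, []).extend(frames)
    return dataset


def write_gameemo(
    signals: dict[int, dict[str, dict[str, NDArray[np.float64]]]],
    directory: str | Path,
) -> list[Path]:
    """Write ``signals[subject][class][channel]`` in the all-channels CSV layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    game_of = {v: k for k, v in GAME_LABELS.items()}
    written = []
    for subject in sorted(signals):
        for cls, per_channel in signals[subject].items():
            path = directory / f"S{subject + 1:02d}G{game_of[cls]}AllChannels.csv"
            pd.DataFrame(per_channel).to_csv(path, index=False)
            written.append(path)
    return written


def _attr(obj, name):
    # tolerate both mat_struct attribute access and record-array field access
    if hasattr(obj, name):
        return getattr(obj, name)
    return obj[name]


def read_dreamer(
    mat_path: str | Path,
    case: str,
    threshold: float,
    rate: float = 128.0,
) -> dict[str, list[EEGFrame]]:
    """Load DREAMER-style trials with binary low/high labels for one case.

    ``case`` is one of arousal / dominance / valence (the spelling
    "valance" is also accepted). A trial whose self-rating is at least
    ``threshold`` is labelled ``"high"``, otherwise ``"low"``. Trials keep
    their native (variable) lengths; no segmentation is applied.
    """
    key = case.strip().lower()
    if key not in _CASES:
        raise ValueError(
            f"unknown case {case!r}; expected one of arousal, dominance, valence"
        )
    field = _CASES[key]
    mat = sio.loadmat(str(mat_path), squeeze_me=True, struct_as_record=False)
    if "DREAMER" not in mat:
        raise ValueError(f"{mat_path}: no DREAMER structure found")
    data = np.atleast_1d(_attr(mat["DREAMER"], "Data"))
    dataset: dict[str, list[EEGFrame]] = {ch: [] for ch in CHANNELS}
    for participant in data:
        eeg = _attr(participant, "EEG")
        stimuli = np.atleast_1d(_attr(eeg, "stimuli"))
        scores = np.atleast_1d(_attr(participant, field)).astype(float)
        if stimuli.size != scores.size:
            raise ValueError(
                f"{mat_path}: {stimuli.size} trials but {scores.size} "
                f"{field} ratings"
            )
        for trial, score in zip(stimuli, scores):
            trial = np.asarray(trial, dtype=float)
            if trial.ndim != 2 or trial.shape[1] != len(CHANNELS):
                raise ValueError(
                    f"{mat_path}: each trial must be samples x {len(CHANNELS)} "
                    f"channels, got shape {trial.shape}"
                )
            label = "high" if score >= threshold else "low"
            for c, channel in enumerate(CHANNELS):
                dataset[channel].append(
                    EEGFrame(trial[:, c], channel=channel, rate=rate, label=label)
                )
    return dataset


def write_dreamer(
    mat_path: str | Path,
    trials: list[NDArray[np.float64]],
    scores: dict[str, list[float]],
) -> None:
    """Write trials (each samples x 14) and per-trial ratings as a DREAMER MAT.

    ``scores`` maps case names (arousal/dominance/valence) to one rating
    per trial. Produces a single-participant container in the published
    nesting (synthetic stand-in for the real corpus; reader fixture only).
    """
    stimuli = np.empty((len(trials), 1), dtype=object)
    for i, trial in enumerate(trials):
        stimuli[i, 0] = np.asarray(trial, dtype=float)
    participant = {
        "EEG": {"stimuli": stimuli},
        "ScoreArousal": np.asarray(scores["arousal"], dtype=float).reshape(-1, 1),
        "ScoreDominance": np.asarray(scores["dominance"], dtype=float).reshape(-1, 1),
        "ScoreValence": np.asarray(scores["valence"], dtype=float).reshape(-1, 1),
    }
    data = np.empty((1, 1), dtype=object)
    data[0, 0] = participant
    sio.savemat(str(mat_path), {"DREAMER": {"Data": data}})
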