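"""Multilevel fused feature generation.

Per signal, three descriptors are concatenated into a 540-vector:
512 textural features (S-box pattern histograms), 14 statistical moments of
the signal, and 14 statistical moments of the 512 textural features. A
frame is expanded into 19 signals — the raw frame plus its 18 TQWT
sub-bands at the default (Q=2, r=3, J=17) — so the final per-frame vector
has 19 x 540 = 10,260 features, block ``t`` (1-based) occupying columns
``(t-1)*540 .. t*540-1``. Block 1 is the raw frame; block ``h+1`` is
sub-band ``h`` in band order (details finest to coarsest, low-pass last).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .ledpattern import SBox, led_pattern
from .statmoments import MOMENT_NAMES, stat_moments
from .tqwt import TqwtParams, tqwt_decompose

__all__ = [
    "EEGFrame",
    "FeatureMatrix",
    "segment_frames",
    "fused_features",
    "ledpatnet19_features",
    "FUSED_LENGTH",
    "DEFAULT_FRAME_LENGTH",
]

logger = logging.getLogger(__name__)

#: Features per signal: 512 textural + 14 moments + 14 moments-of-textural.
FUSED_LENGTH = 540
#: Non-overlapping segment length used for long recordings (about one minute
#: at 128 Hz).
DEFAULT_FRAME_LENGTH = 7650


@dataclass(frozen=True)
class EEGFrame:
    """One fixed-length segment of a single EEG channel."""

    samples: NDArray[np.float64]
    channel: str = "AF3"
    rate: float = 128.0
    label: int | str = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64).ravel()
        if arr.size == 0:
            raise ValueError("a frame must contain at least one sample")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class FeatureMatrix:
    """Observations x features matrix with labels and per-column provenance.

    Provenance rows carry the source-signal index (0 = raw frame,
    1..J+1 = sub-bands), the feature kind (``textural``,
    ``statistical-of-signal`` or ``statistical-of-textural``) and the
    within-kind index; column names follow ``s{signal}_{kind}_{index}``.
    """

    X: NDArray[np.float64]
    y: NDArray
    provenance: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (observations x features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must hold one label per observation")
        if self.provenance is None:
            self.provenance = default_provenance(self.X.shape[1])
        if len(self.provenance) != self.X.shape[1]:
            raise ValueError("provenance must describe every column exactly once")

    @property
    def n_observations(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [
            f"s{r.signal}_{r.kind}_{r.index}"
            for r in self.provenance.itertuples(index=False)
        ]

    def select(self, columns: Sequence[int]) -> "FeatureMatrix":
        cols = np.asarray(columns, dtype=np.intp)
        return FeatureMatrix(
            self.X[:, cols], self.y, self.provenance.iloc[cols].reset_index(drop=True)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, "label", self.y)
        return df

    def save(self, path: str) -> None:
        """Persist as CSV with a provenance sidecar (``<path>.provenance.csv``)."""
        self.to_frame().to_csv(path, index=False)
        self.provenance.to_csv(f"{path}.provenance.csv", index=False)

    @classmethod
    def load(cls, path: str) -> "FeatureMatrix":
        df = pd.read_csv(path)
        prov = pd.read_csv(f"{path}.provenance.csv")
        return cls(df.drop(columns="label").to_numpy(), df["label"].to_numpy(), prov)


def _fused_provenance(signal_index: int) -> list[tuple[int, str, int]]:
    rows = [(signal_index, "textural", i) for i in range(512)]
    rows += [(signal_index, "statistical-of-signal", i) for i in range(14)]
    rows += [(signal_index, "statistical-of-textural", i) for i in range(14)]
    return rows


def default_provenance(n_features: int, n_signals: int | None = None) -> pd.DataFrame:
    """Provenance table for ``n_signals`` fused blocks (inferred if omitted)."""
    if n_signals is None:
        n_signals = n_features // FUSED_LENGTH if n_features % FUSED_LENGTH == 0 else 0
    if n_signals and n_signals * FUSED_LENGTH == n_features:
        rows: list[tuple[int, str, int]] = []
        for s in range(n_signals):
            rows.extend(_fused_provenance(s))
    else:  # generic columns (e.g. an already-selected matrix)
        rows = [(0, "feature", i) for i in range(n_features)]
    return pd.DataFrame(rows, columns=["signal", "kind", "index"])


def segment_frames(
    signal: ArrayLike,
    frame_length: int = DEFAULT_FRAME_LENGTH,
    channel: str = "AF3",
    rate: float = 128.0,
    label: int | str = 0,
) -> list[EEGFrame]:
    """Split a recording into consecutive non-overlapping frames.

    Trailing samples that do not fill a whole frame are discarded. A
    recording shorter than one frame yields an empty list and a warning.
    """
    if frame_length < 16:
        raise ValueError("frame_length must be at least 16")
    x = np.asarray(signal, dtype=np.float64).ravel()
    n_frames = x.size // frame_length
    if n_frames == 0:
        logger.warning(
            "signal of length %d is shorter than one frame (%d); nothing to segment",
            x.size,
            frame_length,
        )
        return []
    return [
        EEGFrame(x[i * frame_length : (i + 1) * frame_length], channel, rate, label)
        for i in range(n_frames)
    ]


def fused_features(signal: ArrayLike, sbox: SBox | None = None) -> NDArray[np.float64]:
    """540-feature vector of one signal: textural, moments, moments-of-textural."""
    textural = led_pattern(signal, sbox).concatenated.astype(np.float64)
    return np.concatenate(
        [textural, stat_moments(signal).values, stat_moments(textural).values]
    )


def ledpatnet19_features(
    frame: EEGFrame | ArrayLike,
    params: TqwtParams | None = None,
    sbox: SBox | None = None,
) -> NDArray[np.float64]:
    """Full multilevel feature vector of one frame (10,260 at the defaults).

    The raw frame's fused block comes first, followed by the fused block of
    each sub-band in band order.
    """
    params = params or TqwtParams()
    samples = frame.samples if isinstance(frame, EEGFrame) else np.asarray(frame, float)
    subbands = tqwt_decompose(samples, params)
    blocks = [fused_features(samples, sbox)]
    blocks.extend(fused_features(band, sbox) for band in subbands)
    return np.concatenate(blocks)


def feature_matrix_from_frames(
    frames: Sequence[EEGFrame],
    params: TqwtParams | None = None,
    sbox: SBox | None = None,
) -> FeatureMatrix:
    """Stack :func:`ledpatnet19_features` over frames into a FeatureMatrix."""
    params = params or TqwtParams()
    X = np.stack([ledpatnet19_features(f, params, sbox) for f in frames])
    y = np.asarray([f.label for f in frames])
    return FeatureMatrix(X, y, default_provenance(X.shape[1], params.levels + 2))
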