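"""S-box driven nonlinear textural descriptor for 1-D signals (Led-Pattern).

The descriptor slides a 16-sample overlapping window over the signal. Inside
each window, sample ``k`` is compared against the sample sitting at the
position a 4-bit cipher S-box assigns to index ``k``; the comparison is a
two-argument signum (ties count as 1). The 16 resulting bits split into a
left and a right byte, and the two byte streams are histogrammed into
256 bins each, giving a fixed 512-dimensional feature vector regardless of
signal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "SBox",
    "LedPatternFeatures",
    "led_sbox",
    "extract_bits",
    "encode_codes",
    "led_pattern",
    "BLOCK_LENGTH",
]

#: Window length; equals the size of a 4-bit S-box lookup table.
BLOCK_LENGTH = 16

# 4-bit S-box of the LED lightweight block cipher (shared with PRESENT).
_LED_SBOX = (12, 5, 6, 11, 9, 0, 10, 13, 3, 14, 15, 8, 4, 7, 1, 2)

_POW2 = 1 << np.arange(8)  # bit 1 is the least significant bit


@dataclass(frozen=True)
class SBox:
    """A bijective 4-bit substitution table.

    ``values[k]`` is the (0-based) window position that position ``k`` is
    compared against during bit generation.
    """

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = tuple(int(v) for v in self.values)
        if len(vals) != 16 or sorted(vals) != list(range(16)):
            raise ValueError(
                "an S-box must be a permutation of 0..15; got %r" % (self.values,)
            )
        object.__setattr__(self, "values", vals)

    def inverse(self) -> "SBox":
        inv = [0] * 16
        for i, v in enumerate(self.values):
            inv[v] = i
        return SBox(tuple(inv))

    def as_array(self) -> NDArray[np.intp]:
        return np.asarray(self.values, dtype=np.intp)


def led_sbox() -> SBox:
    """The LED cipher's published 4-bit S-box, used as the default pattern."""
    return SBox(_LED_SBOX)


@dataclass(frozen=True)
class LedPatternFeatures:
    """Histogram pair produced by :func:`led_pattern`.

    Each histogram has 256 bins (one per 8-bit code) and sums to ``L - 15``
    for an input of length ``L``.
    """

    hist_left: NDArray[np.int64]
    hist_right: NDArray[np.int64]
    concatenated: NDArray[np.int64] = field(init=False)

    def __post_init__(self) -> None:
        left = np.asarray(self.hist_left, dtype=np.int64)
        right = np.asarray(self.hist_right, dtype=np.int64)
        if left.shape != (256,) or right.shape != (256,):
            raise ValueError("each code histogram must have exactly 256 bins")
        object.__setattr__(self, "hist_left", left)
        object.__setattr__(self, "hist_right", right)
        object.__setattr__(self, "concatenated", np.concatenate([left, right]))


def _as_block(block: ArrayLike) -> NDArray[np.float64]:
    arr = np.asarray(block, dtype=np.float64)
    if arr.ndim != 1 or arr.size != BLOCK_LENGTH:
        raise ValueError(
            f"a pattern block must hold exactly {BLOCK_LENGTH} values, "
            f"got shape {arr.shape}"
        )
    return arr


def extract_bits(block: ArrayLike, sbox: SBox | None = None) -> NDArray[np.uint8]:
    """Generate the 16 comparison bits for one window.

    Bit ``k`` (0-based) is 1 iff ``block[k] - block[sbox[k]] >= 0``; a zero
    difference deliberately lands on the 1 branch, so a constant window maps
    to all-ones.
    """
    arr = _as_block(block)
    table = (sbox or led_sbox()).as_array()
    return (arr - arr[table] >= 0).astype(np.uint8)


def encode_codes(bits: ArrayLike) -> tuple[int, int]:
    """Pack 16 bits into the (left, right) byte pair.

    The first eight bits form the left code, the last eight the right code;
    in both, the earliest bit is the least-significant one.
    """
    arr = np.asarray(bits)
    if arr.shape != (16,) or not np.isin(arr, (0, 1)).all():
        raise ValueError("expected 16 binary values")
    arr = arr.astype(np.int64)
    return int(arr[:8] @ _POW2), int(arr[8:] @ _POW2)


def led_pattern(signal: ArrayLike, sbox: SBox | None = None) -> LedPatternFeatures:
    """Compute the 512-feature textural descriptor of a 1-D signal.

    Parameters
    ----------
    signal
        Real-valued sequence of length ``L >= 16``.
    sbox
        Substitution table guiding the comparisons; defaults to the LED
        cipher S-box.

    Returns
    -------
    LedPatternFeatures
        Left/right code histograms (256 bins each) and their concatenation.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if x.size < BLOCK_LENGTH:
        raise ValueError(
            f"signal too short for the textural descriptor: length {x.size} "
            f"< minimum {BLOCK_LENGTH}"
        )
    table = (sbox or led_sbox()).as_array()

    windows = np.lib.stride_tricks.sliding_window_view(x, BLOCK_LENGTH)
    bits = (windows - windows[:, table]) >= 0  # (L-15, 16) boolean
    left_codes = bits[:, :8] @ _POW2
    right_codes = bits[:, 8:] @ _POW2
    return LedPatternFeatures(
        hist_left=np.bincount(left_codes, minlength=256),
        hist_right=np.bincount(right_codes, minlength=256),
    )
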