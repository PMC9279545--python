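"""Tunable Q-factor wavelet transform (TQWT), analysis and synthesis.

The transform is an oversampled two-channel filter bank iterated ``J``
times. Each level splits the current low-pass signal with a DFT-domain
pair of filters whose pass-bands are set by the scaling factors

    beta = 2 / (Q + 1)        (high-pass band fraction)
    alpha = 1 - beta / r      (low-pass band fraction)

with ``alpha + beta > 1`` (oversampled). Transition bands use the
Daubechies-style power-complementary function
``theta(w) = 0.5 * (1 + cos w) * sqrt(2 - cos w)``, which makes the filter
bank perfectly reconstructing. The output is ``J`` high-pass detail bands,
finest first, followed by the final low-pass band — ``J + 1`` sub-bands in
all. The pipeline default (Q=2, r=3, J=17) therefore yields 18 sub-bands.

Band lengths follow the band-limits: level-``j`` outputs keep
``~alpha**j * N`` (low-pass) and ``~beta * alpha**(j-1) * N`` (high-pass)
DFT samples, rounded to even integers against the *original* length so the
synthesis side can recompute them exactly.

Odd-length inputs are zero-padded by one sample before analysis; the pad is
recorded on the :class:`SubbandSet` and stripped on reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["TqwtParams", "SubbandSet", "tqwt_decompose", "tqwt_reconstruct", "max_levels"]

#: Minimum sample count allowed for the coarsest low-pass band.
MIN_COARSE_LENGTH = 8


@dataclass(frozen=True)
class TqwtParams:
    """Q-factor, redundancy and depth of the iterated filter bank."""

    q_factor: float = 2.0
    redundancy: float = 3.0
    levels: int = 17

    def __post_init__(self) -> None:
        if self.q_factor < 1:
            raise ValueError("q_factor must be >= 1")
        if self.redundancy <= 1:
            raise ValueError("redundancy must be > 1")
        if self.levels < 1:
            raise ValueError("levels must be a positive integer")

    @property
    def beta(self) -> float:
        return 2.0 / (self.q_factor + 1.0)

    @property
    def alpha(self) -> float:
        return 1.0 - self.beta / self.redundancy


@dataclass(frozen=True)
class SubbandSet:
    """Ordered TQWT sub-bands plus the parameters that produced them.

    ``bands[0] .. bands[J-1]`` are detail bands from finest to coarsest;
    ``bands[J]`` is the final low-pass band.
    """

    bands: tuple[NDArray[np.float64], ...]
    params: TqwtParams
    original_length: int
    padded: bool = False

    def __post_init__(self) -> None:
        if len(self.bands) != self.params.levels + 1:
            raise ValueError(
                f"expected {self.params.levels + 1} sub-bands, got {len(self.bands)}"
            )

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)


def _even_round(x: float) -> int:
    return 2 * round(x / 2.0)


def _band_sizes(n: int, params: TqwtParams, j: int) -> tuple[int, int, int]:
    """(current low-pass length, next low-pass length, detail length) at level j."""
    a, b = params.alpha, params.beta
    n_prev = n if j == 1 else _even_round(a ** (j - 1) * n)
    n0 = _even_round(a**j * n)
    n1 = min(_even_round(b * a ** (j - 1) * n), n_prev)
    return n_prev, n0, n1


def _transition(t: int) -> NDArray[np.float64]:
    v = np.arange(1, t + 1) * (np.pi / (t + 1))
    return 0.5 * (1.0 + np.cos(v)) * np.sqrt(2.0 - np.cos(v))


def _afb(X: NDArray[np.complex128], n0: int, n1: int) -> tuple[NDArray[np.complex128], NDArray[np.complex128]]:
    """One analysis split of a length-N DFT into low (n0) and high (n1) parts."""
    n = X.size
    p = (n - n1) // 2
    t = (n0 + n1 - n) // 2 - 1
    s = (n - n0) // 2
    if t < 0 or p < 0 or s < 0:
        raise ValueError("filter-bank sizes are infeasible at this level")
    g = _transition(t)

    V0 = np.zeros(n0, dtype=np.complex128)
    V0[0] = X[0]
    if p:
        k = np.arange(1, p + 1)
        V0[k] = X[k]
        V0[n0 - k] = X[n - k]
    if t:
        m = np.arange(1, t + 1)
        V0[p + m] = X[p + m] * g
        V0[n0 - p - m] = X[n - p - m] * g
    V0[n0 // 2] = 0.0

    V1 = np.zeros(n1, dtype=np.complex128)
    if t:
        m = np.arange(1, t + 1)
        gr = g[::-1]
        V1[m] = X[p + m] * gr
        V1[n1 - m] = X[n - p - m] * gr
    if s:
        k = np.arange(1, s + 1)
        V1[t + k] = X[p + t + k]
        V1[n1 - t - k] = X[n - p - t - k]
    V1[n1 // 2] = X[n // 2]
    return V0, V1


def _sfb(V0: NDArray[np.complex128], V1: NDArray[np.complex128], n: int) -> NDArray[np.complex128]:
    """Inverse of :func:`_afb`: merge low/high DFTs back into a length-n DFT."""
    n0, n1 = V0.size, V1.size
    p = (n - n1) // 2
    t = (n0 + n1 - n) // 2 - 1
    s = (n - n0) // 2
    g = _transition(t)

    Y = np.zeros(n, dtype=np.complex128)
    Y[0] = V0[0]
    if p:
        k = np.arange(1, p + 1)
        Y[k] = V0[k]
        Y[n - k] = V0[n0 - k]
    if t:
        m = np.arange(1, t + 1)
        gr = g[::-1]
        Y[p + m] = V0[p + m] * g + V1[m] * gr
        Y[n - p - m] = V0[n0 - p - m] * g + V1[n1 - m] * gr
    if s:
        k = np.arange(1, s + 1)
        Y[p + t + k] = V1[t + k]
        Y[n - p - t - k] = V1[n1 - t - k]
    Y[n // 2] = V1[n1 // 2]
    return Y


def max_levels(signal_length: int, params: TqwtParams) -> int:
    """Deepest feasible decomposition for a given length.

    The coarsest low-pass band is required to keep at least
    ``MIN_COARSE_LENGTH`` samples, which bounds the depth by
    ``floor(log(beta * N / MIN_COARSE_LENGTH) / log(1 / alpha))``.
    """
    if signal_length <= 0:
        return 0
    arg = params.beta * signal_length / MIN_COARSE_LENGTH
    if arg <= 1.0:
        return 0
    return int(math.floor(math.log(arg) / math.log(1.0 / params.alpha)))


def tqwt_decompose(signal: ArrayLike, params: TqwtParams | None = None) -> SubbandSet:
    """Decompose a real 1-D signal into ``J + 1`` TQWT sub-bands.

    Raises an error naming the maximum feasible depth when ``params.levels``
    exceeds :func:`max_levels` for this signal length.
    """
    params = params or TqwtParams()
    x = np.asarray(signal, dtype=np.float64).ravel()
    original_length = x.size
    padded = bool(original_length % 2)
    if padded:
        x = np.concatenate([x, [0.0]])
    n = x.size

    feasible = max_levels(n, params)
    if params.levels > feasible:
        raise ValueError(
            f"requested {params.levels} levels but a length-{original_length} "
            f"signal supports at most {feasible} with these parameters"
        )

    X = np.fft.fft(x) / math.sqrt(n)
    bands: list[NDArray[np.float64]] = []
    for j in range(1, params.levels + 1):
        _, n0, n1 = _band_sizes(n, params, j)
        X, V1 = _afb(X, n0, n1)
        bands.append(np.fft.ifft(V1).real * math.sqrt(n1))
    bands.append(np.fft.ifft(X).real * math.sqrt(X.size))
    return SubbandSet(tuple(bands), params, original_length, padded)


def tqwt_reconstruct(bands: SubbandSet) -> NDArray[np.float64]:
    """Invert :func:`tqwt_decompose` (perfect reconstruction)."""
    params = bands.params
    n = bands.original_length + (1 if bands.padded else 0)
    for j in range(1, params.levels + 1):
        _, n0, n1 = _band_sizes(n, params, j)
        if bands.bands[j - 1].size != n1:
            raise ValueError(
                f"detail band {j} has length {bands.bands[j - 1].size}, "
                f"expected {n1} for these parameters"
            )
    _, n0_last, _ = _band_sizes(n, params, params.levels)
    low = bands.bands[-1]
    if low.size != n0_last:
        raise ValueError(
            f"low-pass band has length {low.size}, expected {n0_last}"
        )

    X = np.fft.fft(low) / math.sqrt(low.size)
    for j in range(params.levels, 0, -1):
        n_prev, _, n1 = _band_sizes(n, params, j)
        V1 = np.fft.fft(bands.bands[j - 1]) / math.sqrt(n1)
        X = _sfb(X, V1, n_prev)
    x = np.fft.ifft(X).real * math.sqrt(n)
    return x[: bands.original_length]
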