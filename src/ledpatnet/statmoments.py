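"""Fourteen statistical moments of a real-valued 1-D signal.

The vector is ordered: mean, sample standard deviation, sum, entropy-like
statistic, mean absolute first difference, bias-corrected skewness,
bias-corrected kurtosis, lower-middle median, minimum, maximum, energy,
RMS, range, and max-minus-mean.

Two conventions deserve a note:

* The entropy-like statistic normalises each sample by the RMS of the
  signal (``p_i = x_i / rms``) and accumulates ``-p_i * ln(p_i)`` over the
  samples with ``p_i > 0`` only; non-positive ratios contribute nothing,
  since the logarithm is undefined there. This is the largest interpretive
  choice in the module and is isolated in :func:`_entropy_like` so an
  alternative reading can be swapped in.
* The median is element ``ceil(M/2)`` (1-based) of the ascending-sorted
  signal. For even lengths this is the lower-middle element — no
  interpolation — which differs from the conventional sample median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["MomentVector", "stat_moments", "MOMENT_NAMES"]

MOMENT_NAMES = (
    "mean",
    "std",
    "sum",
    "entropy",
    "mean_abs_diff",
    "skewness",
    "kurtosis",
    "median",
    "min",
    "max",
    "energy",
    "rms",
    "range",
    "max_minus_mean",
)


@dataclass(frozen=True)
class MomentVector:
    values: NDArray[np.float64]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.shape != (14,):
            raise ValueError("a moment vector has exactly 14 components")
        object.__setattr__(self, "values", arr)

    def __getitem__(self, key: int | str) -> float:
        if isinstance(key, str):
            key = MOMENT_NAMES.index(key)
        return float(self.values[key])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(MOMENT_NAMES, map(float, self.values)))


def _entropy_like(x: NDArray[np.float64], rms: float) -> float:
    # -sum p ln p over p = x/rms restricted to p > 0; degenerate rms -> 0.
    if rms == 0.0:
        return 0.0
    p = x / rms
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log(p)))


def _corrected_skew_kurt(x: NDArray[np.float64], mean: float) -> tuple[float, float]:
    # Bias-corrected sample skewness/kurtosis; both 0 on zero-variance input.
    m = x.size
    d = x - mean
    m2 = float(np.mean(d * d))
    if m2 == 0.0:
        return 0.0, 0.0
    g1 = float(np.mean(d**3)) / m2**1.5
    g2 = float(np.mean(d**4)) / m2**2
    skew = np.sqrt(m * (m - 1)) / (m - 2) * g1
    kurt = (m - 1) / ((m - 2) * (m - 3)) * ((m + 1) * (g2 - 3.0) + 6.0)
    return float(skew), float(kurt)


def stat_moments(signal: ArrayLike) -> MomentVector:
    """Compute the 14-component statistical moment vector.

    Parameters
    ----------
    signal
        Real sequence of length ``M >= 4`` (the corrected kurtosis needs
        more than three samples).
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    m = x.size
    if m < 4:
        raise ValueError(
            f"signal too short for the moment vector: length {m} < minimum 4"
        )

    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    total = float(np.sum(x))
    energy = float(np.sum(x * x))
    rms = float(np.sqrt(energy / m))
    entropy = _entropy_like(x, rms)
    mad1 = float(np.sum(np.abs(np.diff(x)))) / m
    skew, kurt = _corrected_skew_kurt(x, mean)
    median = float(np.sort(x)[int(np.ceil(m / 2)) - 1])
    lo = float(np.min(x))
    hi = float(np.max(x))

    return MomentVector(
        np.array(
            [
                mean,
                std,
                total,
                entropy,
                mad1,
                skew,
                kurt,
                median,
                lo,
                hi,
                energy,
                rms,
                hi - lo,
                hi - mean,
            ]
        )
    )
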