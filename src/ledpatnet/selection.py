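"""Hybrid ReliefF + iterative chi-square feature selection (RFIChi2).

The selector runs in three stages:

1. **ReliefF weighting** — multi-class ReliefF with k nearest hits/misses
   under Manhattan distance on features scaled to [0, 1]; miss
   contributions are weighted by class prior over one minus the prior of
   the observation's own class. Weights may be negative.
2. **Pruning and ranking** — features with negative weights are removed;
   survivors are ranked by the chi-square statistic of their discretized
   values (equal-width bins) against the class label, ties broken by
   original column index.
3. **Iterative sweep** — for every candidate size ``s`` in an inclusive
   range (default [100, 1000], i.e. 901 candidates) the top-``s`` features
   are scored by the cubic SVM's cross-validated misclassification rate on
   one seeded stratified fold partition shared across all sizes; the
   loss-minimizing size wins, ties going to the smallest (parsimony).

Because the ranked top-``s`` sets are nested, the sweep maintains the
SVM's inner-product matrices incrementally, adding one rank-1 update per
feature instead of recomputing the kernel per candidate size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .classify import fit_predict_from_gram
from .fusion import FeatureMatrix

__all__ = [
    "SelectionResult",
    "relieff_weights",
    "chi2_scores",
    "rfichi2_select",
    "DEFAULT_SIZE_RANGE",
]

logger = logging.getLogger(__name__)

DEFAULT_SIZE_RANGE = (100, 1000)
DEFAULT_K_NEIGHBORS = 10
DEFAULT_CHI2_BINS = 10


@dataclass
class SelectionResult:
    """Audit trail of one RFIChi2 run."""

    relieff_weights: NDArray[np.float64]
    kept_after_relieff: NDArray[np.intp]
    chi2_order: NDArray[np.intp]  # ranked original column indices over survivors
    loss_curve: dict[int, float]
    chosen_size: int
    selected: NDArray[np.intp]
    seed: int = 0

    def save(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "chosen_size": self.chosen_size,
            "selected": self.selected.tolist(),
            "kept_after_relieff": self.kept_after_relieff.tolist(),
            "chi2_order": self.chi2_order.tolist(),
            "relieff_weights": self.relieff_weights.tolist(),
            "loss_curve": {str(k): v for k, v in self.loss_curve.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "SelectionResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            relieff_weights=np.asarray(d["relieff_weights"], dtype=np.float64),
            kept_after_relieff=np.asarray(d["kept_after_relieff"], dtype=np.intp),
            chi2_order=np.asarray(d["chi2_order"], dtype=np.intp),
            loss_curve={int(k): v for k, v in d["loss_curve"].items()},
            chosen_size=int(d["chosen_size"]),
            selected=np.asarray(d["selected"], dtype=np.intp),
            seed=int(d["seed"]),
        )


def _as_xy(features: FeatureMatrix | tuple) -> tuple[NDArray[np.float64], NDArray]:
    if isinstance(features, FeatureMatrix):
        return features.X, features.y
    X, y = features
    return np.asarray(X, dtype=np.float64), np.asarray(y)


def relieff_weights(
    features: FeatureMatrix | tuple,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
) -> NDArray[np.float64]:
    """Multi-class ReliefF weights, one per feature.

    Every observation is used (no subsampling). Features are min-max scaled
    so per-feature value differences lie in [0, 1]; constant features get
    weight 0. Neighbors are weighted uniformly.
    """
    X, y = _as_xy(features)
    n, n_feat = X.shape
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("ReliefF needs at least two classes")

    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    nonconst = rng_ > 0
    Xs = np.zeros_like(X)
    Xs[:, nonconst] = (X[:, nonconst] - lo[nonconst]) / rng_[nonconst]

    priors = np.bincount(y_idx).astype(float) / n
    members = [np.flatnonzero(y_idx == c) for c in range(classes.size)]

    # full pairwise Manhattan distances, chunked over rows to bound memory
    w = np.zeros(n_feat)
    chunk = max(1, int(2e8 // (8 * n * n_feat)))
    for start in range(0, n, chunk):
        rows = np.arange(start, min(start + chunk, n))
        diffs = np.abs(Xs[rows, None, :] - Xs[None, :, :])  # (r, n, f)
        dists = diffs.sum(axis=2)
        for local_i, i in enumerate(rows):
            ci = y_idx[i]
            for c in range(classes.size):
                pool = members[c]
                if c == ci:
                    pool = pool[pool != i]
                if pool.size == 0:
                    continue
                k = min(k_neighbors, pool.size)
                order = np.argsort(dists[local_i, pool], kind="stable")[:k]
                neigh = pool[order]
                mean_diff = diffs[local_i, neigh, :].mean(axis=0)
                if c == ci:
                    w -= mean_diff / n
                else:
                    w += (priors[c] / (1.0 - priors[ci])) * mean_diff / n
    w[~nonconst] = 0.0
    return w


def chi2_scores(
    features: FeatureMatrix | tuple,
    n_bins: int = DEFAULT_CHI2_BINS,
) -> NDArray[np.float64]:
    """Chi-square statistic of each discretized feature against the label.

    Each feature is split into ``n_bins`` equal-width bins over its
    observed range; empty bins drop out of the contingency table (their
    observed and expected counts are both zero). Constant features score 0.
    """
    X, y = _as_xy(features)
    n, n_feat = X.shape
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("chi-square ranking needs at least two classes")

    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    nonconst = rng_ > 0
    bins = np.zeros(X.shape, dtype=np.int64)
    bins[:, nonconst] = np.clip(
        ((X[:, nonconst] - lo[nonconst]) / rng_[nonconst] * n_bins).astype(np.int64),
        0,
        n_bins - 1,
    )

    # observed counts per (feature, bin, class) via one bincount
    flat = (np.arange(n_feat)[None, :] * n_bins + bins) * classes.size + y_idx[:, None]
    obs = np.bincount(flat.ravel(), minlength=n_feat * n_bins * classes.size)
    obs = obs.reshape(n_feat, n_bins, classes.size).astype(float)

    row = obs.sum(axis=2, keepdims=True)  # bin totals
    col = obs.sum(axis=1, keepdims=True)  # class totals (same for all features)
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    scores = contrib.sum(axis=(1, 2))
    scores[~nonconst] = 0.0
    return scores


def _sweep_losses(
    X: NDArray[np.float64],
    y: NDArray,
    order: NDArray[np.intp],
    sizes: NDArray[np.int64],
    folds: int,
    seed: int,
) -> dict[int, float]:
    """Misclassification per candidate size over one shared fold partition.

    Inner-product matrices for the nested top-``s`` feature sets are grown
    one rank-1 update at a time, so each candidate size costs one kernel
    evaluation and one SVM fit per fold rather than a fresh Gram matrix.
    """
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    size_set = set(int(s) for s in sizes)
    errors = {int(s): 0 for s in sizes}
    n = y.shape[0]
    for tr, te in skf.split(X, y):
        scaler = StandardScaler().fit(X[np.ix_(tr, order)])
        Xtr = scaler.transform(X[np.ix_(tr, order)])
        Xte = scaler.transform(X[np.ix_(te, order)])
        ip_tr = np.zeros((tr.size, tr.size))
        ip_te = np.zeros((te.size, tr.size))
        for j in range(sizes.max()):
            ctr = Xtr[:, j]
            ip_tr += np.outer(ctr, ctr)
            ip_te += np.outer(Xte[:, j], ctr)
            s = j + 1
            if s in size_set:
                pred = fit_predict_from_gram(ip_tr, y[tr], ip_te, seed)
                errors[s] += int(np.sum(pred != y[te]))
    return {s: errors[s] / n for s in sorted(errors)}


def rfichi2_select(
    features: FeatureMatrix | tuple,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    folds: int = 10,
    seed: int = 0,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    n_bins: int = DEFAULT_CHI2_BINS,
    size_step: int = 1,
) -> SelectionResult:
    """Run the full RFIChi2 selection on a feature matrix.

    Parameters
    ----------
    features
        FeatureMatrix (or ``(X, y)`` pair) to select from.
    size_range
        Inclusive candidate-size interval; the default (100, 1000) yields
        901 candidates at ``size_step=1``.
    folds, seed
        Cross-validation setting for the loss sweep; one seeded stratified
        partition is shared by every candidate size.
    """
    X, y = _as_xy(features)
    weights = relieff_weights((X, y), k_neighbors=k_neighbors)
    kept = np.flatnonzero(weights >= 0)
    if kept.size == 0:
        raise ValueError("no features survive negative-weight pruning")

    scores = chi2_scores((X[:, kept], y), n_bins=n_bins)
    # rank survivors: score descending, ties by original column index
    rank = np.lexsort((kept, -scores))
    order = kept[rank]

    lo, hi = int(size_range[0]), int(size_range[1])
    if lo > hi:
        raise ValueError("size_range must be (min, max) with min <= max")
    if hi > order.size:
        logger.warning(
            "candidate range [%d, %d] clipped to the %d surviving features",
            lo,
            hi,
            order.size,
        )
        hi = order.size
    if lo > order.size:
        lo = order.size
    sizes = np.arange(lo, hi + 1, size_step, dtype=np.int64)
    if sizes.size == 0:
        raise ValueError(
            f"no candidate sizes: {order.size} survivors vs requested "
            f"range [{size_range[0]}, {size_range[1]}]"
        )

    loss_curve = _sweep_losses(X, y, order, sizes, folds, seed)
    chosen = min(loss_curve, key=lambda s: (loss_curve[s], s))
    return SelectionResult(
        relieff_weights=weights,
        kept_after_relieff=kept,
        chi2_order=order,
        loss_curve=loss_curve,
        chosen_size=int(chosen),
        selected=order[:chosen],
        seed=seed,
    )
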